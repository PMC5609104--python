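# autoradq

Quantitative *in vitro* receptor autoradiography turns film blackening into
maps of neurotransmitter-receptor binding-site densities.  Tissue sections
labeled with tritiated ligands are exposed to film together with standards
of known radioactivity; the gray value of every pixel of the digitized
autoradiograph then codes for a receptor density in fmol/mg protein.
`autoradq` implements the full analysis chain used to compare the receptor
architecture of cortical areas and layers:

1. **Film calibration** — a monotone calibration curve
   `G(R) = offset + gmax·(1 − e^(−rate·R))` is fitted to the co-exposed
   standards by non-linear least squares, and radioactivity `R` (cpm) is
   converted to binding-site density with the saturation correction

   `C_b = R / (E·B·W_b·S_a) · (K_D + L) / L`

   where `E` is the scintillation-counter efficiency, `B` the decays per
   unit of time and radioactivity (Ci/min), `W_b` the protein weight of a
   standard (mg), `S_a` the specific activity of the ligand (Ci/mmol),
   `K_D` its dissociation constant (nM) and `L` the free ligand
   concentration during incubation (nM).

2. **Laminar profiles** — density profiles are sampled along equidistant
   traverses from the pial surface to the layer VI / white-matter border
   (minimum-length construction, non-crossing, oblique sections excluded)
   and integrated into the supragranular (I–III), granular (IV) and
   infragranular (V–VI) strata plus the all-layer mean.  Agranular areas
   (motor cortex 4 and 6, cingulate 24) receive a nominal layer IV as the
   stripe occupying 3% of cortical depth below the lower border of
   layer III.

3. **Receptor fingerprints** — per area, the ordered vector of all
   receptor densities (polar plot); four fingerprints per area (all
   layers, sg, g, ig), absolute or z-scored per receptor.

4. **Statistics** — Ward/Euclidean hierarchical clustering with cophenetic
   diagnostics, k-means cluster-count selection by silhouette, Kruskal
   stress-1 multidimensional scaling, permutation-based discriminant
   tests, per-receptor across-area ANOVA with (unclipped) Bonferroni
   correction and gatekept one-sample t-tests of areal extrema.

Because human autoradiography material cannot be redistributed, the
package ships a **synthetic-data module**: a ground-truth generator
producing the canonical laminar gradient (supragranular > granular >
infragranular, with the documented exceptions of kainate, M2, alpha4beta2,
alpha1 and 5-HT1A) over a 44-area × 15-receptor × 3-brain design, and a
phantom renderer that pushes those densities through the exact inverse of
the densitometric model into 16-bit rasters with standards strips, contour
annotations and known truth.  Every pipeline stage is tested end-to-end
against that truth.

## Worked example

```python
import autoradq as aq

# synthetic survey: 8 areas x 6 receptors x 3 brains, 5% between-brain CV
truth = aq.generate_ground_truth(aq.demo_config(replicate_cv=0.05), seed=7)

# render one autoradiograph phantom and quantify it back
ligand = aq.default_ligands(["GABAA"])["GABAA"]
spec = aq.auto_spec(truth, ligand, "GABAA", noise_sd=1.0, seed=4)
phantom = aq.render_phantom(spec, truth, ligand, receptor="GABAA", brain=1)
measured = aq.quantify_phantom(phantom)
print(measured.head(3).round(1))
```

```
  area receptor  brain  mean_sg  mean_g  mean_ig  mean_all  n_profiles
0   V1    GABAA      1   1728.6  1601.4    756.5    1417.9           5
1  V2v    GABAA      1   2099.8  1945.2    918.9    1722.4           5
2   3b    GABAA      1   1124.0  1041.3    491.9     922.0           5
```

Each row is one cortical area of one brain: the mean GABA-A density
(fmol/mg protein) of its supragranular, granular and infragranular strata
and of the full cortical depth, averaged over all usable traverses of the
phantom.  Recovered values agree with the planted ground truth to well
under 2% at 1 gray-level noise.

The same chain runs from the shell:

```sh
autoradq simulate --scale demo --seed 7 --out truth.csv
autoradq report --seed 7 --out run/
```

`run/` then holds the strata CSV, fingerprint tables, dendrogram Newick
files, MDS coordinates, the ANOVA/extrema/discriminant tables, and a
manifest with seeds and checksums.

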