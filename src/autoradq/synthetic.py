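"""Synthetic ground truth and autoradiograph phantoms.

Human autoradiography material cannot be shared or regenerated at will, so
every stage of the pipeline is exercised on synthetic data with known
ground truth.  Two layers are generated:

* a **ground-truth density table** — (area, receptor, stratum, brain) ->
  density in fmol/mg protein, carrying the laminar structure of the real
  cortex: the canonical supragranular > granular > infragranular gradient
  for most receptors, the infragranular peak of the kainate receptor, and
  the granular peak of alpha4beta2 / M2 in primary sensory areas;

* **autoradiograph phantoms** — 16-bit grayscale rasters in which the
  densities are pushed through the exact inverse of the densitometric
  model (density -> radioactivity -> film gray value), together with a
  co-exposed standards strip, cortical contours, and the true densities
  for round-trip validation.

Between-brain variability is a multiplicative lognormal factor shared by
the three strata of one (brain, area, receptor) cell, reflecting the
observation that proportional relations between areas and layers are
stable across brains; it also preserves the planted laminar orderings
exactly.  Area identity is a per-(area, receptor) multiplicative effect
drawn once from the generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import panel
from .calibration import FilmResponse, LigandParams, density_to_radioactivity
from .profiles import CorticalGeometry


class SyntheticError(ValueError):
    """Raised for invalid generator configurations."""


class PhantomRangeError(ValueError):
    """A density maps outside the representable film range (never clipped)."""


#: saturation fraction above which the film response is considered unusable
_MAX_FILM_FRACTION = 0.995


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruthConfig:
    """Study design of the generator.

    Defaults follow the full survey: 44 areas x 15 receptors x 3 brains,
    between-brain coefficient of variation 0.05 and a lognormal
    per-(area, receptor) effect (sd 0.15 on the log scale) that gives each
    area a stable receptor identity.
    """

    areas: list[panel.AreaSpec] = field(default_factory=panel.default_areas)
    receptors: list[panel.ReceptorSpec] = field(default_factory=panel.default_receptors)
    n_brains: int = 3
    replicate_cv: float = 0.05
    area_effect_sd: float = 0.25

    def __post_init__(self) -> None:
        if len(self.areas) < 2 or len(self.receptors) < 2:
            raise SyntheticError("config must name at least 2 areas and 2 receptors")
        if self.n_brains < 1:
            raise SyntheticError("n_brains must be >= 1")
        if self.replicate_cv < 0 or self.area_effect_sd < 0:
            raise SyntheticError("noise parameters must be >= 0")
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise SyntheticError("duplicate area names")
        rnames = [r.name for r in self.receptors]
        if len(set(rnames)) != len(rnames):
            raise SyntheticError("duplicate receptor names")


def demo_config(**kw) -> GroundTruthConfig:
    """Reduced 8 areas x 6 receptors x 3 brains design for fast tests."""
    kw.setdefault("areas", panel.demo_areas())
    kw.setdefault("receptors", panel.demo_receptors())
    return GroundTruthConfig(**kw)


@dataclass
class GroundTruthTable:
    """Long-form density table with its generating conditions.

    ``data`` columns: area, receptor, stratum (sg/g/ig), brain, density
    (fmol/mg protein).
    """

    data: pd.DataFrame
    config: GroundTruthConfig
    replicate_cv: float
    n_brains: int
    seed: int

    def density(self, area: str, receptor: str, stratum: str, brain: int) -> float:
        d = self.data
        row = d[(d.area == area) & (d.receptor == receptor)
                & (d.stratum == stratum) & (d.brain == brain)]
        if len(row) != 1:
            raise KeyError((area, receptor, stratum, brain))
        return float(row.density.iloc[0])

    def validate_invariants(self) -> None:
        """Check positivity and the planted laminar orderings; raise on violation."""
        if np.any(self.data.density <= 0):
            raise SyntheticError("non-positive density in ground truth")
        wide = self.data.pivot_table(index=["area", "receptor", "brain"],
                                     columns="stratum", values="density")
        by_receptor = {r.name: r for r in self.config.receptors}
        sensory = {a.name for a in self.config.areas if a.primary_sensory}
        for (area, receptor, _brain), row in wide.iterrows():
            spec = by_receptor[receptor]
            if spec.laminar_type == panel.CANONICAL:
                if not (row.sg > row.g > row.ig):
                    raise SyntheticError(f"canonical ordering violated in {area}/{receptor}")
            elif spec.laminar_type == panel.INFRAGRANULAR_PEAK:
                if not (row.ig > row.sg and row.ig > row.g):
                    raise SyntheticError(f"infragranular peak violated in {area}/{receptor}")
            elif spec.laminar_type == panel.GRANULAR_PEAK and area in sensory:
                if not (row.g > row.sg and row.g > row.ig):
                    raise SyntheticError(f"granular peak violated in {area}/{receptor}")


def generate_ground_truth(config: GroundTruthConfig, seed: int) -> GroundTruthTable:
    """Draw a ground-truth density table; identical seeds give identical tables."""
    rng = np.random.default_rng(seed)
    n_a, n_r, n_b = len(config.areas), len(config.receptors), config.n_brains

    sd = config.area_effect_sd
    if sd > 0:
        area_factor = rng.lognormal(mean=-sd * sd / 2.0, sigma=sd, size=(n_a, n_r))
    else:
        area_factor = np.ones((n_a, n_r))
    cv = config.replicate_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        brain_factor = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma,
                                     size=(n_b, n_a, n_r))
    else:
        brain_factor = np.ones((n_b, n_a, n_r))

    records = []
    for ia, area in enumerate(config.areas):
        for ir, rec in enumerate(config.receptors):
            base = rec.densities(area.primary_sensory)
            for ib in range(n_b):
                factor = area_factor[ia, ir] * brain_factor[ib, ia, ir]
                for stratum in panel.STRATA:
                    records.append((area.name, rec.name, stratum, ib + 1,
                                    base[stratum] * factor))
    data = pd.DataFrame.from_records(
        records, columns=["area", "receptor", "stratum", "brain", "density"])
    table = GroundTruthTable(data=data, config=config,
                             replicate_cv=cv, n_brains=n_b, seed=seed)
    table.validate_invariants()
    return table


def strata_table_from_truth(truth: GroundTruthTable) -> pd.DataFrame:
    """Analytic strata table: ground-truth densities plus thickness-weighted all-layer mean.

    Output columns: area, receptor, brain, mean_sg, mean_g, mean_ig,
    mean_all, n_profiles — the same shape the imaging pipeline produces, so
    downstream statistics run identically on either source.
    """
    bounds = {a.name: a.strata_bounds() for a in truth.config.areas}
    wide = truth.data.pivot_table(index=["area", "receptor", "brain"],
                                  columns="stratum", values="density").reset_index()
    f1 = wide.area.map(lambda a: bounds[a][0])
    f2 = wide.area.map(lambda a: bounds[a][1])
    out = pd.DataFrame({
        "area": wide.area, "receptor": wide.receptor, "brain": wide.brain,
        "mean_sg": wide.sg, "mean_g": wide.g, "mean_ig": wide.ig,
        "mean_all": f1 * wide.sg + (f2 - f1) * wide.g + (1.0 - f2) * wide.ig,
        "n_profiles": 1,
    })
    return out.sort_values(["area", "receptor", "brain"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Phantom rendering
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Rendering recipe for one synthetic autoradiograph.

    ``ribbon_curvature`` is the reciprocal of the pial arc radius in 1/px
    (0 renders a flat ribbon).  ``standards_levels`` are the known
    radioactivity concentrations (cpm-equivalent) of the co-exposed scale,
    strictly increasing, at least 4 levels.  ``noise_sd`` is additive
    Gaussian noise on gray values (DN of the 16-bit raster); an optional
    Poisson term on radioactivity models emulsion grain.
    """

    image_size: tuple[int, int] = (320, 560)
    cortical_thickness_px: int = 120
    ribbon_curvature: float = 0.0
    standards_levels: tuple[float, ...] = ()
    film_params: FilmResponse = field(
        default_factory=lambda: FilmResponse(offset=2000.0, gmax=50000.0, rate=1.0))
    noise_sd: float = 0.0
    poisson_scale: float = 0.0
    seed: int = 0
    margin_px: int = 20
    standards_width_px: int = 36

    def __post_init__(self) -> None:
        levels = np.asarray(self.standards_levels, dtype=float)
        if len(levels) < 4 or np.any(np.diff(levels) <= 0):
            raise SyntheticError("standards_levels must be >= 4 strictly increasing values")
        if self.cortical_thickness_px <= 0:
            raise SyntheticError("cortical_thickness_px must be > 0")
        if self.noise_sd < 0 or self.poisson_scale < 0:
            raise SyntheticError("noise parameters must be >= 0")


def auto_spec(truth: GroundTruthTable, ligand: LigandParams,
              receptor: str, **kw) -> PhantomSpec:
    """PhantomSpec with a film rate and standards scaled to the truth's densities.

    The film rate is chosen so the maximum rendered density sits at ~80% of
    film saturation; standards span 0 .. 1.1x the maximum radioactivity in
    8 steps, mimicking a step-wise increasing calibration scale.
    """
    dmax = float(truth.data[truth.data.receptor == receptor].density.max())
    r_max = density_to_radioactivity(dmax, ligand)
    rate = -np.log(1.0 - 0.8) / r_max
    film = FilmResponse(offset=2000.0, gmax=50000.0, rate=rate)
    top = 1.1 * r_max
    levels = tuple(np.linspace(0.0, top, 8))
    kw.setdefault("film_params", film)
    kw.setdefault("standards_levels", levels)
    return PhantomSpec(**kw)


@dataclass
class Phantom:
    """Rendered synthetic autoradiograph with everything needed to score it."""

    image: np.ndarray                      # uint16 raster
    standards_rois: list[tuple[tuple, float]]   # ((r0,r1,c0,c1), known R)
    pial_contour: np.ndarray
    wm_contour: np.ndarray
    area_geometries: dict[str, CorticalGeometry]
    truth: pd.DataFrame                    # rendered subset, long form
    spec: PhantomSpec
    ligand: LigandParams
    receptor: str
    brain: int

    @property
    def film(self) -> FilmResponse:
        return self.spec.film_params


def _ribbon_fields(spec: PhantomSpec):
    """Per-pixel depth fraction and arc coordinate of the cortical ribbon.

    Returns (depth, arc, arc_total, contour_fn) where contour_fn(depth
    fraction) yields the polyline at that depth.
    """
    rows, cols = spec.image_size
    t = float(spec.cortical_thickness_px)
    x0 = spec.margin_px + spec.standards_width_px + 24.0
    x1 = cols - spec.margin_px
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)

    if spec.ribbon_curvature == 0.0:
        y_pial = rows * 0.30
        depth = (yy - y_pial) / t
        arc = xx - x0
        arc_total = x1 - x0
        inside_arc = (xx >= x0) & (xx <= x1)

        def contour(fd: float) -> np.ndarray:
            xs = np.linspace(x0, x1, 256)
            return np.column_stack([xs, np.full_like(xs, y_pial + fd * t)])
    else:
        r_pial = 1.0 / spec.ribbon_curvature
        cx, cy = cols / 2.0, rows * 0.30 + r_pial
        r = np.hypot(xx - cx, yy - cy)
        depth = (r_pial - r) / t          # depth grows toward the centre
        theta = np.arctan2(xx - cx, cy - yy)   # 0 at the top of the arc
        arc_half = min((x1 - x0) / 2.0, 0.95 * np.pi * r_pial / 2)
        arc = (theta + arc_half / r_pial) * r_pial
        arc_total = 2.0 * arc_half
        inside_arc = np.abs(theta) <= arc_half / r_pial

        def contour(fd: float) -> np.ndarray:
            ang = np.linspace(-arc_half / r_pial, arc_half / r_pial, 256)
            rr = r_pial - fd * t
            return np.column_stack([cx + rr * np.sin(ang), cy - rr * np.cos(ang)])

    arc = np.where(inside_arc, arc, np.nan)
    return depth, arc, arc_total, contour


def render_phantom(spec: PhantomSpec, truth: GroundTruthTable,
                   ligand: LigandParams, receptor: str | None = None,
                   brain: int = 1,
                   areas: Sequence[str] | None = None) -> Phantom:
    """Render the ground truth of one (receptor, brain) into a phantom raster.

    Areas occupy consecutive segments of equal arc length along the ribbon.
    Per pixel: density -> radioactivity (exact inverse of the Eq.-1 style
    conversion) -> film gray value, plus optional noise; the standards
    strip runs through the same film response.  Densities too close to film
    saturation raise :class:`PhantomRangeError` instead of being clipped.
    """
    if receptor is None:
        receptor = truth.data.receptor.iloc[0]
    sub = truth.data[(truth.data.receptor == receptor) & (truth.data.brain == brain)]
    if sub.empty:
        raise SyntheticError(f"truth has no rows for receptor={receptor!r}, brain={brain}")
    if areas is None:
        areas = [a.name for a in truth.config.areas
                 if a.name in set(sub.area)]
    area_specs = {a.name: a for a in truth.config.areas}
    missing = [a for a in areas if a not in set(sub.area)]
    if missing:
        raise SyntheticError(f"truth does not cover rendered areas {missing}")

    film = spec.film_params
    rng = np.random.default_rng(spec.seed)

    # density lookup per (area index, stratum index)
    dens = np.zeros((len(areas), 3))
    for i, area in enumerate(areas):
        for j, stratum in enumerate(panel.STRATA):
            row = sub[(sub.area == area) & (sub.stratum == stratum)]
            dens[i, j] = float(row.density.iloc[0])

    R_all = density_to_radioactivity(dens, ligand)
    frac = 1.0 - np.exp(-film.rate * R_all)
    if np.any(frac > _MAX_FILM_FRACTION):
        bad = np.argwhere(frac > _MAX_FILM_FRACTION)
        cells = [(areas[i], panel.STRATA[j], dens[i, j]) for i, j in bad]
        raise PhantomRangeError(
            f"densities map beyond {100*_MAX_FILM_FRACTION:.1f}% film saturation: {cells}")
    levels = np.asarray(spec.standards_levels, dtype=float)
    if np.any(1.0 - np.exp(-film.rate * levels) > _MAX_FILM_FRACTION):
        raise PhantomRangeError("standards levels saturate the film response")

    depth, arc, arc_total, contour = _ribbon_fields(spec)
    seg = arc_total / len(areas)
    # a 2-px apron beyond the contours keeps bilinear sampling at the exact
    # pial / white-matter endpoints free of background contamination
    apron = 2.0 / spec.cortical_thickness_px
    in_ribbon = (depth >= -apron) & (depth < 1.0 + apron) & np.isfinite(arc) \
        & (arc >= 0.0) & (arc <= arc_total)

    area_idx = np.clip((np.nan_to_num(arc) // seg).astype(int), 0, len(areas) - 1)
    f1 = np.array([area_specs[a].strata_bounds()[0] for a in areas])[area_idx]
    f2 = np.array([area_specs[a].strata_bounds()[1] for a in areas])[area_idx]

    # antialias the sector borders: mix radioactivity by the overlap of each
    # pixel's depth extent (one pixel = 1/thickness in depth) with the sectors
    h = 0.5 / spec.cortical_thickness_px
    w_sg = np.clip((f1 - (depth - h)) / (2 * h), 0.0, 1.0)
    w_ig = np.clip(((depth + h) - f2) / (2 * h), 0.0, 1.0)
    w_g = np.clip(1.0 - w_sg - w_ig, 0.0, 1.0)

    R_img = np.zeros(spec.image_size, dtype=float)
    m = in_ribbon
    R_img[m] = (w_sg[m] * R_all[area_idx[m], 0]
                + w_g[m] * R_all[area_idx[m], 1]
                + w_ig[m] * R_all[area_idx[m], 2])

    # standards strip down the left margin
    rois: list[tuple[tuple, float]] = []
    n_lv = len(levels)
    rows = spec.image_size[0]
    pad = 4
    h = max(8, (rows - 2 * spec.margin_px) // n_lv - pad)
    c0, c1 = spec.margin_px, spec.margin_px + spec.standards_width_px
    for k, level in enumerate(levels):
        r0 = spec.margin_px + k * (h + pad)
        roi = (r0, r0 + h, c0, c1)
        R_img[r0:r0 + h, c0:c1] = level
        rois.append((roi, float(level)))

    if spec.poisson_scale > 0:
        pos = R_img > 0
        R_img[pos] = rng.poisson(R_img[pos] * spec.poisson_scale) / spec.poisson_scale

    gray = film(R_img)
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)
    if gray.min() < 0 or gray.max() > 65535:
        raise PhantomRangeError("gray values leave the 16-bit raster range")
    image = np.round(gray).astype(np.uint16)

    inset = 3.0  # px shaved off segment ends so sampling never mixes areas
    geoms = {}
    for i, area in enumerate(areas):
        a_spec = area_specs[area]
        s0, s1 = i * seg + inset, (i + 1) * seg - inset
        pial_full, wm_full = contour(0.0), contour(1.0)
        sl = _clip_polyline(pial_full, s0, s1)
        wl = _clip_polyline(wm_full, s0 / arc_total * _polyline_length(wm_full),
                            s1 / arc_total * _polyline_length(wm_full))
        geoms[area] = CorticalGeometry(
            pial=sl, wm=wl, border_fractions=a_spec.border_fractions,
            agranular=a_spec.agranular,
            layer3_lower_fraction=a_spec.layer3_lower_fraction, area=area)

    return Phantom(image=image, standards_rois=rois,
                   pial_contour=contour(0.0), wm_contour=contour(1.0),
                   area_geometries=geoms,
                   truth=sub[sub.area.isin(areas)].reset_index(drop=True),
                   spec=spec, ligand=ligand, receptor=receptor, brain=brain)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _clip_polyline(points: np.ndarray, s0: float, s1: float,
                   n: int = 96) -> np.ndarray:
    from .profiles import resample_polyline
    return resample_polyline(points, np.linspace(s0, s1, n))
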