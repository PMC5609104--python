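"""Traverse extraction, profile sampling and strata integration."""

import numpy as np
import pytest
from shapely.geometry import LineString

from autoradq.calibration import DensityImage
from autoradq.profiles import (
    CorticalGeometry,
    GeometryError,
    Profile,
    ProfileError,
    StrataDensities,
    Traverse,
    aggregate_area,
    extract_traverses,
    partition_strata,
    sample_profile,
)


def _flat_geometry(width=200.0, thickness=60.0, y0=10.0, **kw):
    xs = np.linspace(0.0, width, 64)
    pial = np.column_stack([xs, np.full_like(xs, y0)])
    wm = np.column_stack([xs, np.full_like(xs, y0 + thickness)])
    return CorticalGeometry(pial=pial, wm=wm, **kw)


class TestExtractTraverses:
    def test_flat_contours_give_perpendicular_traverses(self):
        geom = _flat_geometry(thickness=60.0)
        traverses = extract_traverses(geom, spacing=20.0)
        for tr in traverses:
            assert tr.length == pytest.approx(60.0, abs=1e-6)
            assert tr.start[0] == pytest.approx(tr.end[0], abs=0.3)

    def test_concentric_arcs_give_radial_traverses(self):
        theta = np.linspace(-0.6, 0.6, 256)
        cx, cy, r_out, r_in = 0.0, 0.0, 300.0, 240.0
        pial = np.column_stack([cx + r_out * np.sin(theta), cy - r_out * np.cos(theta)])
        wm = np.column_stack([cx + r_in * np.sin(theta), cy - r_in * np.cos(theta)])
        geom = CorticalGeometry(pial=pial, wm=wm)
        traverses = extract_traverses(geom, spacing=15.0)
        for tr in traverses:
            assert tr.length == pytest.approx(r_out - r_in, abs=1.0)
            # radial: start and end are collinear with the arc centre
            a = np.asarray(tr.start) - [cx, cy]
            b = np.asarray(tr.end) - [cx, cy]
            cross = abs(a[0] * b[1] - a[1] * b[0]) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cross < 0.02

    def test_no_two_traverses_cross(self):
        # strongly slanted wm invites crossing nearest-point matches
        xs = np.linspace(0.0, 200.0, 64)
        pial = np.column_stack([xs, np.zeros_like(xs)])
        wm = np.column_stack([xs + 40.0, np.full_like(xs, 50.0) + 0.4 * xs])
        geom = CorticalGeometry(pial=pial, wm=wm)
        traverses = extract_traverses(geom, spacing=10.0, oblique_ratio=None)
        segments = [LineString([t.start, t.end]) for t in traverses]
        for i in range(len(segments)):
            for j in range(i + 1, len(segments)):
                assert not segments[i].crosses(segments[j])

    def test_crossing_contours_rejected(self):
        xs = np.linspace(0.0, 100.0, 32)
        pial = np.column_stack([xs, np.full_like(xs, 10.0)])
        wm = np.column_stack([xs, 20.0 - 0.3 * xs])  # crosses the pial line
        with pytest.raises(GeometryError, match="intersect"):
            extract_traverses(CorticalGeometry(pial=pial, wm=wm), spacing=10.0)

    def test_spacing_larger_than_contour_rejected(self):
        with pytest.raises(GeometryError, match="spacing"):
            extract_traverses(_flat_geometry(width=50.0), spacing=100.0)

    def test_oblique_traverses_excluded(self):
        # make the wm dip away at one end: long traverses there get dropped
        xs = np.linspace(0.0, 200.0, 128)
        pial = np.column_stack([xs, np.zeros_like(xs)])
        wm_y = np.where(xs < 150.0, 40.0, 40.0 + (xs - 150.0) * 3.0)
        wm = np.column_stack([xs, wm_y])
        geom = CorticalGeometry(pial=pial, wm=wm)
        kept = extract_traverses(geom, spacing=10.0, oblique_ratio=1.5)
        lengths = np.array([t.length for t in kept])
        assert lengths.max() <= 1.5 * np.median(lengths)

    def test_streamline_method_on_flat_geometry(self):
        geom = _flat_geometry(width=100.0, thickness=40.0)
        traverses = extract_traverses(geom, spacing=25.0, method="streamline")
        for tr in traverses:
            assert tr.length == pytest.approx(40.0, abs=2.0)


class TestSampleProfile:
    def test_constant_image_gives_constant_profile(self):
        dimg = DensityImage(values=np.full((50, 50), 42.0))
        tr = Traverse(start=(10.0, 5.0), end=(10.0, 45.0), anchor_s=0.0)
        p = sample_profile(dimg, tr, n_bins=21)
        np.testing.assert_allclose(p.values, 42.0)

    def test_step_ribbon_steps_at_half_depth(self):
        values = np.where(np.arange(100)[:, None] < 50, 100.0, 20.0) * np.ones((1, 40))
        dimg = DensityImage(values=values)
        tr = Traverse(start=(20.0, 0.0), end=(20.0, 99.0), anchor_s=0.0)
        p = sample_profile(dimg, tr, n_bins=101)
        depths = p.depths_percent
        assert np.all(p.values[depths < 48.0] == 100.0)
        assert np.all(p.values[depths > 52.0] == 20.0)

    def test_single_bin_is_traverse_mean(self):
        values = np.tile(np.linspace(0.0, 100.0, 101)[:, None], (1, 20))
        dimg = DensityImage(values=values)
        tr = Traverse(start=(10.0, 0.0), end=(10.0, 100.0), anchor_s=0.0)
        p = sample_profile(dimg, tr, n_bins=1)
        assert p.values[0] == pytest.approx(50.0, rel=0.02)

    def test_out_of_bounds_traverse_rejected(self):
        dimg = DensityImage(values=np.zeros((10, 10)))
        tr = Traverse(start=(5.0, 0.0), end=(5.0, 20.0), anchor_s=0.0)
        with pytest.raises(ProfileError, match="bounds"):
            sample_profile(dimg, tr)

    def test_fully_masked_traverse_rejected(self):
        dimg = DensityImage(values=np.full((20, 20), np.nan))
        tr = Traverse(start=(5.0, 1.0), end=(5.0, 18.0), anchor_s=0.0)
        with pytest.raises(ProfileError, match="masked"):
            sample_profile(dimg, tr)

    def test_masked_pixels_yield_masked_samples(self):
        values = np.full((40, 10), 7.0)
        values[20, :] = np.nan
        dimg = DensityImage(values=values)
        tr = Traverse(start=(5.0, 0.0), end=(5.0, 39.0), anchor_s=0.0)
        p = sample_profile(dimg, tr, n_bins=40)
        assert np.isnan(p.values).any()
        assert np.nansum(p.values > 0)


class TestPartitionStrata:
    def test_constant_profile_all_means_equal(self):
        geom = _flat_geometry(border_fractions=(0.5, 0.7))
        p = Profile(np.full(101, 80.0))
        s = partition_strata(p, geom)
        for value in (s.mean_sg, s.mean_g, s.mean_ig, s.mean_all):
            assert value == pytest.approx(80.0, rel=1e-12)

    def test_linear_profile_integrates_exactly(self):
        """f(depth)=depth is integrated exactly by the trapezoidal rule."""
        geom = _flat_geometry(border_fractions=(0.5, 0.7))
        p = Profile(np.linspace(0.0, 1.0, 101))
        s = partition_strata(p, geom)
        assert s.mean_sg == pytest.approx(0.25, abs=1e-12)
        assert s.mean_g == pytest.approx(0.60, abs=1e-12)
        assert s.mean_ig == pytest.approx(0.85, abs=1e-12)
        assert s.mean_all == pytest.approx(0.50, abs=1e-12)

    def test_piecewise_constant_sector_means(self):
        geom = _flat_geometry(border_fractions=(0.5, 0.7))
        depths = np.linspace(0.0, 1.0, 2001)
        values = np.where(depths < 0.5, 100.0, np.where(depths < 0.7, 50.0, 25.0))
        s = partition_strata(Profile(values), geom)
        assert s.mean_all == pytest.approx(0.5 * 100 + 0.2 * 50 + 0.3 * 25, rel=2e-3)
        assert s.mean_sg == pytest.approx(100.0, rel=2e-3)
        assert s.mean_g == pytest.approx(50.0, rel=4e-3)
        assert s.mean_ig == pytest.approx(25.0, rel=2e-3)

    def test_agranular_granular_sector_is_3pct_below_layer3(self):
        geom = _flat_geometry(agranular=True, layer3_lower_fraction=0.55)
        assert geom.strata_bounds() == pytest.approx((0.55, 0.58), abs=1e-12)
        # a linear profile recovers the sector bounds from its means exactly
        s = partition_strata(Profile(np.linspace(0.0, 1.0, 101)), geom)
        assert s.mean_g == pytest.approx((0.55 + 0.58) / 2, abs=1e-12)
        layer3 = 2 * s.mean_sg                      # sector [0, l3) of f(d)=d
        assert layer3 == pytest.approx(0.55, abs=1e-12)
        stripe_width = 2 * (s.mean_g - layer3)      # sector [l3, l3+w)
        assert stripe_width == pytest.approx(0.03, abs=1e-12)

    def test_thickness_weighted_identity(self, rng):
        geom = _flat_geometry(border_fractions=(0.42, 0.63))
        values = rng.uniform(10.0, 500.0, size=101)
        s = partition_strata(Profile(values), geom)
        f1, f2 = 0.42, 0.63
        combined = f1 * s.mean_sg + (f2 - f1) * s.mean_g + (1 - f2) * s.mean_ig
        assert s.mean_all == pytest.approx(combined, rel=1e-9)

    def test_invalid_border_fractions_rejected(self):
        with pytest.raises(GeometryError):
            _flat_geometry(border_fractions=(0.7, 0.5))
        with pytest.raises(GeometryError):
            _flat_geometry(agranular=True, layer3_lower_fraction=0.99)


class TestAggregateArea:
    def _sd(self, sg, g, ig, mean_all=None, borders=(0.5, 0.7)):
        f1, f2 = borders
        if mean_all is None:
            mean_all = f1 * sg + (f2 - f1) * g + (1 - f2) * ig
        return StrataDensities(sg, g, ig, mean_all, 1, borders)

    def test_single_profile_is_identity(self):
        s = self._sd(10.0, 20.0, 30.0)
        agg = aggregate_area([s])
        assert (agg.mean_sg, agg.mean_g, agg.mean_ig) == (10.0, 20.0, 30.0)

    def test_two_profiles_arithmetic_mean(self):
        agg = aggregate_area([self._sd(10.0, 20.0, 30.0), self._sd(30.0, 40.0, 50.0)])
        assert (agg.mean_sg, agg.mean_g, agg.mean_ig) == (20.0, 30.0, 40.0)
        assert agg.n_profiles == 2

    def test_aggregation_preserves_thickness_identity(self, rng):
        profiles = [self._sd(*rng.uniform(10, 100, size=3)) for _ in range(7)]
        agg = aggregate_area(profiles)
        f1, f2 = 0.5, 0.7
        combined = f1 * agg.mean_sg + (f2 - f1) * agg.mean_g + (1 - f2) * agg.mean_ig
        assert agg.mean_all == pytest.approx(combined, rel=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ProfileError):
            aggregate_area([])


class TestOrientationRobustness:
    def test_rotated_phantom_recovers_same_strata(self, flat_phantom):
        import autoradq as aq

        base = aq.quantify_phantom(flat_phantom)

        # rotate the density field and the geometry by 90 degrees
        from autoradq.calibration import fit_calibration, measure_standards, quantify_image
        from autoradq.profiles import aggregate_area, extract_traverses, partition_strata, sample_profile

        image = flat_phantom.image.astype(float)
        standards = measure_standards(image,
                                      [roi for roi, _ in flat_phantom.standards_rois],
                                      [lvl for _, lvl in flat_phantom.standards_rois])
        cal = fit_calibration(standards)
        dimg = quantify_image(image, cal, flat_phantom.ligand)
        rot = DensityImage(values=np.ascontiguousarray(np.rot90(dimg.values)))
        n_cols = dimg.values.shape[1]

        rows = []
        for area, geom in flat_phantom.area_geometries.items():
            def rot_pts(pts):
                # np.rot90: out[r, c] = in[c, N-1-r]  =>  (x, y) -> (y, N-1-x)
                return np.column_stack([pts[:, 1], n_cols - 1 - pts[:, 0]])
            g2 = CorticalGeometry(pial=rot_pts(geom.pial), wm=rot_pts(geom.wm),
                                  border_fractions=geom.border_fractions,
                                  agranular=geom.agranular,
                                  layer3_lower_fraction=geom.layer3_lower_fraction)
            traverses = extract_traverses(g2, spacing=12.0)
            strata = [partition_strata(sample_profile(rot, t, n_bins=101), g2)
                      for t in traverses]
            agg = aggregate_area(strata)
            rows.append({"area": area, **agg.as_dict()})
        import pandas as pd
        rotated = pd.DataFrame(rows)
        m = base.merge(rotated, on="area", suffixes=("", "_rot"))
        for col in ("mean_sg", "mean_g", "mean_ig", "mean_all"):
            rel = np.abs(m[col] - m[col + "_rot"]) / m[col]
            assert rel.max() < 0.01, col
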