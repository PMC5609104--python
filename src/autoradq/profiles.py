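"""Cortical traverses, laminar density profiles and strata integration.

A profile quantifies receptor density along a pial -> white-matter traverse
through the cortical ribbon, on a cortical-depth axis normalized to
0% (pial surface) .. 100% (layer VI / white matter border).  Each profile is
cut into the supragranular (layers I-III), granular (layer IV) and
infragranular (layers V-VI) strata at cytoarchitectonically defined depth
fractions, and integrated (trapezoidal rule on the piecewise-linear
profile) into per-stratum mean densities plus the all-layer mean.

Agranular areas (motor cortex 4 and 6, cingulate 24) lack a visible
layer IV; their granular sector is defined as the stripe occupying 3% of
the total cortical depth below the lower border of layer III.

Traverses are anchored equidistantly along the pial contour and connected
to the white-matter contour by the shortest non-crossing link (a
minimum-length construction); a Laplace-like streamline alternative is
available for strongly curved ribbons.  Traverses through obliquely cut
cortex are excluded by a length-ratio criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString

from .calibration import DensityImage

GRANULAR_STRIPE_FRACTION = 0.03  # nominal layer IV depth share in agranular areas


class GeometryError(ValueError):
    """Raised for inconsistent contours or border fractions."""


class ProfileError(ValueError):
    """Raised for unusable profiles (fully masked, empty input)."""


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

@dataclass
class CorticalGeometry:
    """Pial and white-matter contours of one area plus its laminar borders.

    Contours are (N, 2) float arrays of (x, y) pixel coordinates, oriented
    consistently (both running the same way along the ribbon).
    """

    pial: np.ndarray
    wm: np.ndarray
    border_fractions: tuple[float, float] = (0.55, 0.70)
    agranular: bool = False
    layer3_lower_fraction: float = 0.55
    area: str = ""

    def __post_init__(self) -> None:
        self.pial = np.asarray(self.pial, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        for name, c in (("pial", self.pial), ("wm", self.wm)):
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise GeometryError(f"{name} contour must be an (N>=2, 2) array")
        if self.agranular:
            f = self.layer3_lower_fraction
            if not (0.0 < f and f + GRANULAR_STRIPE_FRACTION < 1.0):
                raise GeometryError("layer3_lower_fraction out of range")
        else:
            f1, f2 = self.border_fractions
            if not (0.0 < f1 < f2 < 1.0):
                raise GeometryError("border fractions must satisfy 0 < f1 < f2 < 1")

    def strata_bounds(self) -> tuple[float, float]:
        """Depth fractions (f1, f2) of the sg/g and g/ig borders."""
        if self.agranular:
            f = self.layer3_lower_fraction
            return (f, f + GRANULAR_STRIPE_FRACTION)
        return self.border_fractions


def _arclengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points at arc-length positions ``s`` along a polyline."""
    arcs = _arclengths(points)
    x = np.interp(s, arcs, points[:, 0])
    y = np.interp(s, arcs, points[:, 1])
    return np.column_stack([x, y])


# --------------------------------------------------------------------------
# Traverses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Traverse:
    """Straight pial -> white-matter segment with its anchor arc position."""

    start: tuple[float, float]   # on the pial contour
    end: tuple[float, float]     # on the wm contour
    anchor_s: float              # arc-length of the anchor along the pial contour

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0],
                              self.end[1] - self.start[1]))

    def points(self, n: int) -> np.ndarray:
        t = np.linspace(0.0, 1.0, n)[:, None]
        p0 = np.asarray(self.start)[None, :]
        p1 = np.asarray(self.end)[None, :]
        return p0 + t * (p1 - p0)


def extract_traverses(geom: CorticalGeometry, spacing: float,
                      oblique_ratio: float = 1.5,
                      method: str = "nearest") -> list[Traverse]:
    """Equidistant traverses from the pial to the white-matter contour.

    Anchors are placed every ``spacing`` px along the pial contour.  Each
    anchor connects to the white-matter contour by its nearest point
    (minimum length); matched arc positions are forced non-decreasing so no
    two traverses cross.  Traverses longer than ``oblique_ratio`` times the
    median length are discarded as obliquely sectioned cortex.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be > 0")
    pial_ls, wm_ls = LineString(geom.pial), LineString(geom.wm)
    if pial_ls.intersects(wm_ls):
        raise GeometryError("pial and white-matter contours intersect")
    pial_len = _arclengths(geom.pial)[-1]
    if spacing > pial_len:
        raise GeometryError(
            f"spacing {spacing} exceeds pial contour length {pial_len:.1f}")

    n_anchor = int(np.floor(pial_len / spacing)) + 1
    anchor_s = np.arange(n_anchor) * spacing
    anchors = resample_polyline(geom.pial, anchor_s)

    if method == "nearest":
        step = max(min(1.0, spacing / 4.0), pial_len / 20000.0)
        wm_s = np.arange(0.0, _arclengths(geom.wm)[-1] + step / 2, step)
        wm_pts = resample_polyline(geom.wm, wm_s)
        d2 = ((anchors[:, None, :] - wm_pts[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        # non-crossing: monotone wm arc positions for consistently
        # oriented contours
        idx = np.maximum.accumulate(idx)
        ends = wm_pts[idx]
    elif method == "streamline":
        ends = np.array([_streamline_end(a, pial_ls, wm_ls) for a in anchors])
    else:
        raise GeometryError(f"unknown traverse method {method!r}")

    traverses = [Traverse(tuple(a), tuple(e), float(s))
                 for a, e, s in zip(anchors, ends, anchor_s)]
    if oblique_ratio is not None and len(traverses) >= 3:
        lengths = np.array([t.length for t in traverses])
        keep = lengths <= oblique_ratio * np.median(lengths)
        traverses = [t for t, k in zip(traverses, keep) if k]
    if not traverses:
        raise GeometryError("no traverse survived the oblique-section exclusion")
    return traverses


def _streamline_end(anchor: np.ndarray, pial_ls: LineString,
                    wm_ls: LineString, step: float = 1.0,
                    max_steps: int = 10000) -> np.ndarray:
    """Follow the gradient of the normalized-distance depth field to the wm.

    phi(x) = d_pial(x) / (d_pial(x) + d_wm(x)) rises from 0 at the pial to 1
    at the white-matter contour; its streamlines stay orthogonal to the
    level sets, which approximates curvature-following traverses.
    """
    from shapely.geometry import Point

    def phi(p):
        dp = pial_ls.distance(Point(p))
        dw = wm_ls.distance(Point(p))
        return dp / (dp + dw) if (dp + dw) > 0 else 0.0

    p = np.asarray(anchor, dtype=float)
    h = step
    for _ in range(max_steps):
        if wm_ls.distance(Point(p)) <= step:
            break
        gx = (phi(p + [h, 0]) - phi(p - [h, 0])) / (2 * h)
        gy = (phi(p + [0, h]) - phi(p - [0, h])) / (2 * h)
        g = np.hypot(gx, gy)
        if g == 0:
            break
        p = p + step * np.array([gx, gy]) / g
    from shapely.ops import nearest_points
    return np.asarray(nearest_points(wm_ls, Point(p))[0].coords[0])


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------

@dataclass
class Profile:
    """Densities at equidistant normalized cortical depths (0..100%)."""

    values: np.ndarray
    n_bins: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_bins == 0:
            self.n_bins = len(self.values)
        if len(self.values) != self.n_bins:
            raise ProfileError("values length does not match n_bins")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ProfileError("profile densities must be >= 0")

    @property
    def depths_percent(self) -> np.ndarray:
        if self.n_bins == 1:
            return np.array([50.0])
        return np.linspace(0.0, 100.0, self.n_bins)


def sample_profile(dimg: DensityImage, tr: Traverse, n_bins: int = 101) -> Profile:
    """Bilinear sampling of a density raster along a traverse.

    ``n_bins`` equidistant depths from the pial (0%) to the white-matter
    (100%) endpoint.  Masked (NaN) pixels yield NaN samples, which later
    integration skips.  ``n_bins = 1`` degenerates to the traverse mean.
    """
    if n_bins < 1:
        raise ProfileError("n_bins must be >= 1")
    values = dimg.values
    dense = n_bins if n_bins > 1 else max(16, int(np.ceil(tr.length)) * 2)
    pts = tr.points(dense)
    rows, cols = pts[:, 1], pts[:, 0]
    eps = 1e-9
    if (rows.min() < -eps or cols.min() < -eps
            or rows.max() > values.shape[0] - 1 + eps
            or cols.max() > values.shape[1] - 1 + eps):
        raise ProfileError("traverse leaves the image bounds")
    sampled = map_coordinates(np.nan_to_num(values), [rows, cols], order=1,
                              mode="nearest")
    # a sample whose bilinear stencil touches any masked pixel is masked
    touched = map_coordinates(np.isnan(values).astype(float), [rows, cols],
                              order=1, mode="nearest") > 0
    sampled = np.where(touched, np.nan, sampled)
    if np.all(np.isnan(sampled)):
        raise ProfileError("traverse is fully masked")
    if n_bins == 1:
        return Profile(np.array([float(np.nanmean(sampled))]), n_bins=1)
    return Profile(sampled, n_bins=n_bins)


# --------------------------------------------------------------------------
# Strata integration
# --------------------------------------------------------------------------

@dataclass
class StrataDensities:
    """Per-stratum mean densities of one profile or one area aggregate.

    Satisfies the thickness-weighted identity
    ``mean_all = f1*mean_sg + (f2-f1)*mean_g + (1-f2)*mean_ig``
    by construction (all four means are integrals of the same
    piecewise-linear profile).
    """

    mean_sg: float
    mean_g: float
    mean_ig: float
    mean_all: float
    n_profiles: int = 1
    borders: tuple[float, float] = (0.55, 0.70)

    def as_dict(self) -> dict:
        return {"mean_sg": self.mean_sg, "mean_g": self.mean_g,
                "mean_ig": self.mean_ig, "mean_all": self.mean_all,
                "n_profiles": self.n_profiles}


def _sector_integral(depths: np.ndarray, values: np.ndarray,
                     a: float, b: float) -> float:
    """Trapezoidal integral of the piecewise-linear profile over [a, b]."""
    nodes = np.concatenate([[a], depths[(depths > a) & (depths < b)], [b]])
    vals = np.interp(nodes, depths, values)
    return float(np.trapezoid(vals, nodes))


def partition_strata(p: Profile, geom: CorticalGeometry) -> StrataDensities:
    """Cut a profile into sg / g / ig sectors and integrate each sector.

    Sector means are the profile integral over the sector divided by its
    width; the granular sector is [f1, f2) for granular areas and the 3%
    stripe below the lower border of layer III for agranular areas.  NaN
    samples (masked pixels) are dropped before interpolation.
    """
    f1, f2 = geom.strata_bounds()
    if p.n_bins < 2:
        v = float(p.values[0])
        return StrataDensities(v, v, v, v, 1, (f1, f2))
    depths = np.linspace(0.0, 1.0, p.n_bins)
    finite = np.isfinite(p.values)
    if finite.sum() < 2:
        raise ProfileError("profile has fewer than 2 usable samples")
    d, v = depths[finite], p.values[finite]

    sectors = {}
    for name, (a, b) in {"sg": (0.0, f1), "g": (f1, f2), "ig": (f2, 1.0)}.items():
        sectors[name] = _sector_integral(d, v, a, b) / (b - a)
    mean_all = _sector_integral(d, v, 0.0, 1.0)
    return StrataDensities(sectors["sg"], sectors["g"], sectors["ig"],
                           mean_all, 1, (f1, f2))


def aggregate_area(results: Sequence[StrataDensities]) -> StrataDensities:
    """Unweighted mean across profiles of one area (and section)."""
    results = list(results)
    if not results:
        raise ProfileError("cannot aggregate an empty list of profiles")
    borders = results[0].borders
    if any(not np.allclose(r.borders, borders) for r in results):
        raise ProfileError("cannot aggregate profiles with different strata borders")
    n = sum(r.n_profiles for r in results)
    return StrataDensities(
        mean_sg=float(np.mean([r.mean_sg for r in results])),
        mean_g=float(np.mean([r.mean_g for r in results])),
        mean_ig=float(np.mean([r.mean_ig for r in results])),
        mean_all=float(np.mean([r.mean_all for r in results])),
        n_profiles=n, borders=borders)
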