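"""Film calibration and densitometric conversion.

Quantitative in vitro receptor autoradiography encodes binding-site density
in film blackening: the gray value of each pixel of a digitized
autoradiograph codes for a radioactivity concentration, which in turn codes
for a receptor density per unit protein.  The conversion runs in two steps:

1. A calibration curve is fitted by non-linear least squares to co-exposed
   standards of known radioactivity, defining gray value -> radioactivity
   (cpm).
2. Radioactivity is converted to binding-site density C_b (fmol/mg protein)
   correcting for the experimental conditions of the binding assay::

       C_b = R / (E * B * W_b * S_a) * (K_D + L) / L

   with E the scintillation-counter efficiency, B the decays per unit time
   and radioactivity (Ci/min), W_b the protein weight of a standard (mg),
   S_a the specific activity of the ligand (Ci/mmol), K_D the dissociation
   constant (nM) and L the free ligand concentration during incubation (nM).

The default calibration family is a saturating exponential
``G = offset + gmax * (1 - exp(-rate * R))``, which captures film
saturation and is invertible in closed form; a cubic polynomial in
``log1p(R)`` is available as a second family to probe model mismatch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or non-monotone fits."""


# --------------------------------------------------------------------------
# Ligand parameters and Eq.-1 style conversion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandParams:
    """Binding-assay constants of one tritiated ligand.

    All six constants must be strictly positive.  ``saturation_factor``
    is (K_D + L)/L, the correction from bound-at-L to bound-at-saturation.
    """

    E: float    # scintillation counter efficiency (dimensionless)
    B: float    # decays per unit time and radioactivity (Ci/min)
    Wb: float   # protein weight of a standard (mg)
    Sa: float   # specific activity (Ci/mmol)
    KD: float   # dissociation constant (nM)
    L: float    # free ligand concentration during incubation (nM)
    receptor: str = ""

    def __post_init__(self) -> None:
        for name in ("E", "B", "Wb", "Sa", "KD", "L"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise CalibrationError(
                    f"ligand parameter {name} must be strictly positive, got {value!r}"
                )

    @property
    def scale_factor(self) -> float:
        return self.E * self.B * self.Wb * self.Sa

    @property
    def saturation_factor(self) -> float:
        return (self.KD + self.L) / self.L

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LigandParams":
        return cls(**d)


def radioactivity_to_density(R, ligand: LigandParams):
    """Convert radioactivity (cpm) to binding-site density C_b (fmol/mg protein).

    ``C_b = R/(E*B*Wb*Sa) * (KD+L)/L``.  NaN propagates (masked pixels);
    finite negative radioactivity is rejected.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R[np.isfinite(R)] < 0):
        raise CalibrationError("radioactivity must be >= 0")
    out = R / ligand.scale_factor * ligand.saturation_factor
    return out if out.ndim else float(out)


def density_to_radioactivity(Cb, ligand: LigandParams):
    """Exact inverse of :func:`radioactivity_to_density` (used by the phantom renderer)."""
    Cb = np.asarray(Cb, dtype=float)
    if np.any(Cb[np.isfinite(Cb)] < 0):
        raise CalibrationError("density must be >= 0")
    out = Cb * ligand.scale_factor / ligand.saturation_factor
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Film response families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilmResponse:
    """Saturating film response ``G(R) = offset + gmax*(1 - exp(-rate*R))``.

    Strictly increasing in R for gmax, rate > 0; inverse in closed form.
    """

    offset: float
    gmax: float
    rate: float

    def __post_init__(self) -> None:
        if self.gmax <= 0 or self.rate <= 0:
            raise CalibrationError("film response requires gmax > 0 and rate > 0")

    def __call__(self, R):
        R = np.asarray(R, dtype=float)
        out = self.offset + self.gmax * (-np.expm1(-self.rate * R))
        return out if out.ndim else float(out)

    def inverse(self, gray):
        """Gray -> R; values outside (offset, offset+gmax) come back NaN."""
        gray = np.asarray(gray, dtype=float)
        frac = (gray - self.offset) / self.gmax
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where((frac >= 0) & (frac < 1.0),
                           -np.log1p(-np.clip(frac, 0.0, 1.0 - 1e-15)) / self.rate,
                           np.nan)
        return out if out.ndim else float(out)

    def params(self) -> dict:
        return {"family": "saturating", "offset": self.offset,
                "gmax": self.gmax, "rate": self.rate}


class PolyLogResponse:
    """Monotone piecewise-cubic (PCHIP) in log1p(R) through the standards.

    Second calibration family; shape-preserving, so it stays strictly
    monotone whenever the standards are.  Used to probe mismatch between
    the fitted parametric family and the true film behaviour.
    """

    family = "polylog"

    def __init__(self, R_nodes: Sequence[float], G_nodes: Sequence[float]):
        from scipy.interpolate import PchipInterpolator

        self.R_nodes = np.asarray(R_nodes, dtype=float)
        self.G_nodes = np.asarray(G_nodes, dtype=float)
        if np.any(np.diff(self.R_nodes) <= 0) or np.any(np.diff(self.G_nodes) <= 0):
            raise CalibrationError(
                "polylog film response requires strictly increasing standards")
        x = np.log1p(self.R_nodes)
        self._fwd = PchipInterpolator(x, self.G_nodes, extrapolate=False)
        self._inv = PchipInterpolator(self.G_nodes, x, extrapolate=False)

    def __call__(self, R):
        R = np.asarray(R, dtype=float)
        out = self._fwd(np.log1p(R))
        return out if out.ndim else float(out)

    def inverse(self, gray):
        gray = np.asarray(gray, dtype=float)
        out = np.expm1(self._inv(gray))
        return out if out.ndim else float(out)

    def params(self) -> dict:
        return {"family": "polylog", "R_nodes": self.R_nodes.tolist(),
                "G_nodes": self.G_nodes.tolist()}


# --------------------------------------------------------------------------
# Standards and calibration fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardMeasurement:
    """One co-exposed standard: known radioactivity and its observed mean gray."""

    known_R: float
    mean_gray: float
    roi: tuple | None = None   # (row0, row1, col0, col1) in pixel coords

    def __post_init__(self) -> None:
        if self.known_R < 0:
            raise CalibrationError("standard radioactivity must be >= 0")


def measure_standards(image: np.ndarray,
                      rois: Sequence[tuple],
                      levels: Sequence[float]) -> list[StandardMeasurement]:
    """Mean gray value per standards ROI, paired with its known level."""
    if len(rois) != len(levels):
        raise CalibrationError("rois and levels differ in length")
    out = []
    img = np.asarray(image, dtype=float)
    for (r0, r1, c0, c1), level in zip(rois, levels):
        patch = img[r0:r1, c0:c1]
        if patch.size == 0:
            raise CalibrationError(f"empty standards ROI {(r0, r1, c0, c1)}")
        out.append(StandardMeasurement(float(level), float(np.nanmean(patch)),
                                       (r0, r1, c0, c1)))
    return out


@dataclass
class FilmCalibration:
    """Fitted gray -> radioactivity relationship with residual diagnostics."""

    film: FilmResponse | PolyLogResponse
    standards: list[StandardMeasurement]
    residuals: np.ndarray = field(repr=False)
    valid_gray_range: tuple[float, float] = (0.0, 0.0)

    @property
    def rss(self) -> float:
        return float(np.sum(np.square(self.residuals)))

    def to_json(self) -> str:
        return json.dumps({
            "film": self.film.params(),
            "standards": [{"known_R": s.known_R, "mean_gray": s.mean_gray,
                           "roi": s.roi} for s in self.standards],
            "residuals": np.asarray(self.residuals).tolist(),
            "valid_gray_range": list(self.valid_gray_range),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FilmCalibration":
        d = json.loads(text)
        fp = d["film"]
        if fp["family"] == "saturating":
            film = FilmResponse(fp["offset"], fp["gmax"], fp["rate"])
        else:
            film = PolyLogResponse(fp["R_nodes"], fp["G_nodes"])
        standards = [StandardMeasurement(s["known_R"], s["mean_gray"],
                                         tuple(s["roi"]) if s["roi"] else None)
                     for s in d["standards"]]
        return cls(film=film, standards=standards,
                   residuals=np.asarray(d["residuals"], dtype=float),
                   valid_gray_range=tuple(d["valid_gray_range"]))


def fit_calibration(standards: Sequence[StandardMeasurement],
                    family: str = "saturating") -> FilmCalibration:
    """Non-linear least-squares fit of the film response to co-exposed standards.

    Requires at least 4 standards with distinct known radioactivities.
    The fitted curve must be strictly monotone over the standards' span;
    non-monotone fits are refused rather than returned.
    """
    standards = list(standards)
    R = np.array([s.known_R for s in standards], dtype=float)
    G = np.array([s.mean_gray for s in standards], dtype=float)
    if len(np.unique(R)) < 4:
        raise CalibrationError(
            f"insufficient standards: need >= 4 distinct radioactivity levels, "
            f"got {len(np.unique(R))}")
    if np.allclose(G, G[0]):
        raise CalibrationError("degenerate standards: all mean gray values equal")

    order = np.argsort(R)
    R, G = R[order], G[order]
    standards = [standards[i] for i in order]

    if family == "saturating":
        def model(r, offset, gmax, rate):
            return offset + gmax * (-np.expm1(-rate * r))

        g_span = G.max() - G.min()
        r_scale = np.mean(R[R > 0]) if np.any(R > 0) else 1.0
        p0 = (G.min(), 1.5 * g_span, 1.0 / r_scale)
        try:
            popt, _ = curve_fit(
                model, R, G, p0=p0,
                bounds=([-np.inf, 1e-12, 1e-15], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise CalibrationError(f"calibration fit did not converge: {exc}") from exc
        film: FilmResponse | PolyLogResponse = FilmResponse(*map(float, popt))
    elif family == "polylog":
        film = PolyLogResponse(R, G)
    else:
        raise CalibrationError(f"unknown calibration family {family!r}")

    fitted = film(R)
    if np.any(np.diff(fitted) <= 0):
        raise CalibrationError("fitted calibration is not strictly monotone "
                               "over the standards' range")
    residuals = G - fitted
    lo, hi = float(film(0.0)), float(film(R.max()))
    return FilmCalibration(film=film, standards=standards,
                           residuals=residuals, valid_gray_range=(lo, hi))


def gray_to_radioactivity(cal: FilmCalibration, gray):
    """Apply the fitted inverse curve elementwise.

    Gray values outside ``valid_gray_range`` are masked (NaN) and counted in
    a warning — never silently extrapolated.  NaN in propagates to NaN out.
    """
    gray = np.asarray(gray, dtype=float)
    lo, hi = cal.valid_gray_range
    tol = 1e-9 * max(1.0, abs(hi - lo))
    in_range = (gray >= lo - tol) & (gray <= hi + tol)
    out = np.full(gray.shape, np.nan)
    out[in_range] = np.clip(cal.film.inverse(np.clip(gray[in_range], lo, hi)),
                            0.0, None)
    n_bad = int(np.sum(~in_range & np.isfinite(gray)))
    if n_bad:
        warnings.warn(f"{n_bad} gray value(s) outside the calibrated range "
                      f"[{lo:.3g}, {hi:.3g}] were masked", stacklevel=2)
    if gray.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# Density images
# --------------------------------------------------------------------------

@dataclass
class DensityImage:
    """Raster of binding-site densities C_b (fmol/mg protein).

    NaN marks masked pixels (out-of-calibration gray values).  ``provenance``
    records the ligand and calibration that produced the raster.
    """

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if np.any(v[np.isfinite(v)] < 0):
            raise CalibrationError("density image contains negative values")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def quantify_image(image: np.ndarray, cal: FilmCalibration,
                   ligand: LigandParams) -> DensityImage:
    """Gray-value raster -> density raster: gray -> R -> C_b per pixel."""
    R = gray_to_radioactivity(cal, np.asarray(image, dtype=float))
    # NaN marks masked pixels; finite R is already >= 0 after the inverse.
    Cb = np.asarray(R, dtype=float) / ligand.scale_factor * ligand.saturation_factor
    return DensityImage(values=Cb, provenance={
        "ligand": ligand.to_dict(),
        "calibration": cal.film.params(),
    })


def specific_binding(total: DensityImage,
                     nonspecific: DensityImage) -> DensityImage:
    """Specific = total - non-specific, floored at zero.

    The number of floored pixels is recorded in the result's provenance
    (key ``n_floored``) so sub-zero subtraction is reported, never hidden.
    """
    if total.values.shape != nonspecific.values.shape:
        raise CalibrationError(
            f"shape mismatch: total {total.values.shape} vs "
            f"non-specific {nonspecific.values.shape}")
    diff = total.values - nonspecific.values
    n_floored = int(np.sum(diff[np.isfinite(diff)] < 0))
    out = np.where(diff < 0, 0.0, diff)
    prov = dict(total.provenance)
    prov["n_floored"] = n_floored
    return DensityImage(values=out, provenance=prov)
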