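"""Multi-receptor fingerprints: construction, size, z-normalization, polar plots.

A receptor fingerprint is the ordered vector of the densities of all
measured receptor types in one cortical area (or one of its strata),
conventionally drawn as a polar plot.  Its *size* summarizes the total
receptor expression — both as the plain sum of densities and as the area
of the polar polygon — while its *shape* expresses the balance between
receptor types.  Comparisons require the same receptor sequence and, for
absolute plots, the same radial scale across all fingerprints.

Four fingerprints are built per area: the all-layer mean and the
supragranular, granular and infragranular strata.  For multivariate
analyses the densities are z-scored per receptor (sample sd, n-1), either
within each stratum collection or pooled across strata — pooling is what
lets strata form their own clusters in a common space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import RECEPTOR_ORDER

STRATUM_LABELS = ("all", "sg", "g", "ig")


class FingerprintError(ValueError):
    """Raised for incomplete tables or invalid fingerprint operations."""


@dataclass(frozen=True)
class Fingerprint:
    area: str
    stratum: str                      # one of all, sg, g, ig
    values: np.ndarray
    receptor_order: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.receptor_order):
            raise FingerprintError("values and receptor_order differ in length")
        if self.stratum not in STRATUM_LABELS:
            raise FingerprintError(f"unknown stratum {self.stratum!r}")
        if not self.normalized and np.any(self.values < 0):
            raise FingerprintError("absolute fingerprint values must be >= 0")


@dataclass(frozen=True)
class FingerprintSize:
    sum_size: float     # fmol/mg protein
    polar_area: float   # (fmol/mg protein)^2


def build_fingerprints(table: pd.DataFrame,
                       receptor_order: Sequence[str] | None = None
                       ) -> list[Fingerprint]:
    """Four fingerprints (all, sg, g, ig) per area from a strata table.

    ``table`` is either long form (columns area, receptor, stratum,
    density with stratum in {all, sg, g, ig}) or the wide strata form
    (area, receptor, mean_sg, mean_g, mean_ig, mean_all) with replicates
    already averaged.  A missing (area, receptor, stratum) cell is an
    error naming the cell.
    """
    if {"mean_sg", "mean_g", "mean_ig", "mean_all"} <= set(table.columns):
        if "brain" in table.columns and table.duplicated(["area", "receptor"]).any():
            raise FingerprintError("average replicates before building fingerprints")
        long = table.melt(id_vars=["area", "receptor"],
                          value_vars=["mean_all", "mean_sg", "mean_g", "mean_ig"],
                          var_name="stratum", value_name="density")
        long["stratum"] = long.stratum.str.removeprefix("mean_")
    else:
        required = {"area", "receptor", "stratum", "density"}
        if not required <= set(table.columns):
            raise FingerprintError(f"table must have columns {sorted(required)}")
        long = table[["area", "receptor", "stratum", "density"]].copy()

    if receptor_order is None:
        present = list(dict.fromkeys(long.receptor))
        receptor_order = tuple(r for r in RECEPTOR_ORDER if r in present) \
            + tuple(r for r in present if r not in RECEPTOR_ORDER)
    receptor_order = tuple(receptor_order)

    pivot = long.pivot_table(index=["area", "stratum"], columns="receptor",
                             values="density", aggfunc="mean")
    fingerprints = []
    for area in dict.fromkeys(long.area):
        for stratum in STRATUM_LABELS:
            for receptor in receptor_order:
                if (area, stratum) not in pivot.index \
                        or receptor not in pivot.columns \
                        or pd.isna(pivot.loc[(area, stratum), receptor]):
                    raise FingerprintError(
                        f"missing density cell (area={area!r}, receptor={receptor!r}, "
                        f"stratum={stratum!r})")
            values = pivot.loc[(area, stratum), list(receptor_order)].to_numpy(float)
            fingerprints.append(Fingerprint(area=area, stratum=stratum,
                                            values=values,
                                            receptor_order=receptor_order))
    return fingerprints


def fingerprint_size(fp: Fingerprint) -> FingerprintSize:
    """Sum of densities and polar-polygon area of one absolute fingerprint.

    With the k receptors on equiangular spokes the polygon area is the
    shoelace sum ``1/2 * sin(2*pi/k) * sum_i r_i * r_{i+1 mod k}``.
    """
    if fp.normalized:
        raise FingerprintError("fingerprint size is defined on absolute densities only")
    r = fp.values
    k = len(r)
    sum_size = float(np.sum(r))
    polar_area = 0.5 * np.sin(2.0 * np.pi / k) * float(np.sum(r * np.roll(r, -1)))
    return FingerprintSize(sum_size=sum_size, polar_area=polar_area)


@dataclass
class NormalizationResult:
    """Z-scored fingerprints plus the affine parameters used per group."""

    fingerprints: list[Fingerprint]
    means: dict                        # group key -> per-receptor mean vector
    sds: dict                          # group key -> per-receptor sd vector
    scope: str = "per-stratum"


def normalize_z(fps: Iterable[Fingerprint],
                scope: str = "per-stratum") -> NormalizationResult:
    """Per-receptor z-scores (sample sd, ddof=1) over the given scope.

    ``per-stratum`` z-scores each stratum's collection separately (used for
    within-stratum area comparisons); ``pooled-strata`` z-scores over the
    union of all supplied fingerprints (required when strata are to be
    compared with one another in one space).  The transform is affine per
    receptor, so area rank orders are preserved.
    """
    fps = list(fps)
    if any(f.normalized for f in fps):
        raise FingerprintError("fingerprints are already normalized")
    if scope not in ("per-stratum", "pooled-strata"):
        raise FingerprintError(f"unknown z-scoring scope {scope!r}")
    orders = {f.receptor_order for f in fps}
    if len(orders) != 1:
        raise FingerprintError("all fingerprints must share one receptor order")
    order = orders.pop()

    def group_key(f: Fingerprint):
        return f.stratum if scope == "per-stratum" else "pooled"

    groups: dict[str, list[Fingerprint]] = {}
    for f in fps:
        groups.setdefault(group_key(f), []).append(f)

    means, sds, out = {}, {}, []
    for key, members in groups.items():
        X = np.array([f.values for f in members])
        if len(members) < 2:
            raise FingerprintError(
                f"need >= 2 observations to z-score group {key!r}")
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise FingerprintError(
                f"zero variance for receptor(s) {[order[i] for i in zero]} "
                f"in group {key!r}")
        means[key], sds[key] = mu, sd
        for f in members:
            out.append(replace(f, values=(f.values - mu) / sd, normalized=True))
    return NormalizationResult(fingerprints=out, means=means, sds=sds, scope=scope)


def denormalize(result: NormalizationResult) -> list[Fingerprint]:
    """Invert :func:`normalize_z` exactly (up to floating point)."""
    out = []
    for f in result.fingerprints:
        key = f.stratum if result.scope == "per-stratum" else "pooled"
        values = f.values * result.sds[key] + result.means[key]
        out.append(replace(f, values=values, normalized=False))
    return out


def collection_matrix(fps: Sequence[Fingerprint]) -> tuple[np.ndarray, list[str]]:
    """Stack fingerprints into an (n, k) matrix with "area|stratum" labels."""
    X = np.array([f.values for f in fps])
    labels = [f"{f.area}|{f.stratum}" for f in fps]
    return X, labels


def fingerprints_to_frame(fps: Sequence[Fingerprint]) -> pd.DataFrame:
    """Wide export: one row per area x stratum, one column per receptor."""
    orders = {f.receptor_order for f in fps}
    if len(orders) != 1:
        raise FingerprintError("all fingerprints must share one receptor order")
    order = orders.pop()
    rows = [{"area": f.area, "stratum": f.stratum, "normalized": f.normalized,
             **dict(zip(order, f.values))} for f in fps]
    return pd.DataFrame(rows)


def plot_fingerprint(fp: Fingerprint, rmax: float | None = None,
                     ax=None, style: dict | None = None):
    """Polar plot of one fingerprint.

    For absolute fingerprints pass the collection-wide ``rmax`` so all
    plots share one radial scale; normalized plots draw a dotted reference
    ring at z = 0 (the across-area average).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    style = dict(style or {})
    k = len(fp.values)
    theta = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    if ax is None:
        fig = plt.figure(figsize=style.pop("figsize", (4, 4)))
        ax = fig.add_subplot(projection="polar")
    closed_t = np.concatenate([theta, theta[:1]])
    closed_r = np.concatenate([fp.values, fp.values[:1]])
    ax.plot(closed_t, closed_r, color=style.pop("color", "tab:blue"))
    ax.fill(closed_t, closed_r, alpha=style.pop("alpha", 0.25))
    ax.set_xticks(theta)
    ax.set_xticklabels(fp.receptor_order, fontsize=6)
    if fp.normalized:
        ax.plot(np.linspace(0, 2 * np.pi, 256),
                np.zeros(256), linestyle=":", color="black", linewidth=0.8)
        lim = max(1.0, float(np.max(np.abs(fp.values)))) * 1.1
        ax.set_ylim(-lim, lim)
    else:
        if rmax is not None:
            ax.set_ylim(0, rmax)
    ax.set_title(f"{fp.area} ({fp.stratum})", fontsize=9)
    return ax.figure


def plot_fingerprints(fps: Sequence[Fingerprint], path_prefix: str,
                      fmt: str = "svg") -> list[str]:
    """One plot per fingerprint with a shared absolute radial scale; returns paths."""
    import matplotlib.pyplot as plt

    absolute = [f for f in fps if not f.normalized]
    rmax = max((float(f.values.max()) for f in absolute), default=None)
    if rmax is not None:
        rmax *= 1.05
    paths = []
    for f in fps:
        fig = plot_fingerprint(f, rmax=None if f.normalized else rmax)
        safe = f"{f.area}_{f.stratum}".replace("/", "-").replace("|", "-")
        path = f"{path_prefix}_{safe}.{fmt}"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
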