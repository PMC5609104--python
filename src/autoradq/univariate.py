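"""Per-receptor ANOVA across areas and gatekept one-sample extrema tests.

For each receptor type, a one-way fixed-effects ANOVA (factor: cortical
area, replicates: brains) asks whether the receptor's density is
homogeneously distributed over the areas; raw p-values are Bonferroni
corrected for the number of receptor types tested.  The adjusted values
are reported *unclipped* (raw p times m, which can exceed 1) so that the
conventional table layout is reproduced; a clipped variant is available.

Only receptors whose ANOVA is significant are carried into the follow-up:
per area, a one-sample t-test of the replicate densities against the
across-area grand mean of that receptor (treated as a fixed expected
value).  These gatekept follow-ups are deliberately not corrected for
multiple testing.  Receptors that fail the gate are recorded as
not-tested rather than non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


LAYER_SETS = ("all", "sg", "g", "ig")
_LAYER_COLUMN = {"all": "mean_all", "sg": "mean_sg", "g": "mean_g", "ig": "mean_ig"}


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


def bonferroni(p: float, m: int, clip: bool = False) -> float:
    """Bonferroni adjustment p*m; unclipped by default (values > 1 allowed)."""
    if not (0.0 <= p <= 1.0):
        raise StatsError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise StatsError("m must be >= 1")
    adj = p * m
    return min(adj, 1.0) if clip else adj


@dataclass
class AnovaTable:
    """Per-receptor one-way ANOVA results for one layer set."""

    table: pd.DataFrame        # index receptor: F, p_raw, p_bonferroni, significant
    layer_set: str
    m: int                     # number of tests used in the correction
    alpha: float = 0.05

    def significant_receptors(self) -> list[str]:
        return list(self.table.index[self.table.significant])


def _layer_values(table: pd.DataFrame, layer_set: str) -> pd.DataFrame:
    if layer_set not in LAYER_SETS:
        raise StatsError(f"unknown layer set {layer_set!r}; expected one of {LAYER_SETS}")
    col = _LAYER_COLUMN[layer_set]
    required = {"area", "receptor", "brain", col}
    if not required <= set(table.columns):
        raise StatsError(f"strata table must have columns {sorted(required)}")
    return table[["area", "receptor", "brain", col]].rename(columns={col: "value"})


def anova_by_area(table: pd.DataFrame, layer_set: str = "all",
                  alpha: float = 0.05, m: int | None = None) -> AnovaTable:
    """One-way ANOVA (factor: area) per receptor on replicate brain values.

    ``table`` is the wide strata table (area, receptor, brain, mean_sg,
    mean_g, mean_ig, mean_all).  Every area needs >= 2 replicates.  ``m``
    defaults to the number of receptors in the table (the size of the
    Bonferroni family).
    """
    values = _layer_values(table, layer_set)
    receptors = list(dict.fromkeys(values.receptor))
    areas = list(dict.fromkeys(values.area))
    if len(areas) < 2:
        raise StatsError("need >= 2 areas")
    if m is None:
        m = len(receptors)

    rows = []
    for receptor in receptors:
        sub = values[values.receptor == receptor]
        groups = []
        for area in areas:
            g = sub[sub.area == area].value.to_numpy(float)
            if len(g) < 2:
                raise StatsError(
                    f"area {area!r} has a single replicate for receptor {receptor!r}")
            groups.append(g)
        F, p = stats.f_oneway(*groups)
        adj = bonferroni(float(p), m)
        rows.append({"receptor": receptor, "F": float(F), "p_raw": float(p),
                     "p_bonferroni": adj, "significant": adj <= alpha})
    df = pd.DataFrame(rows).set_index("receptor")
    return AnovaTable(table=df, layer_set=layer_set, m=m, alpha=alpha)


@dataclass
class ExtremaTestTable:
    """Gatekept one-sample t-tests of each area against the grand mean."""

    table: pd.DataFrame        # receptor, area, t, p, significant, degenerate
    not_tested: list[str]      # receptors skipped because their ANOVA failed the gate
    layer_set: str
    alpha: float = 0.05


def extrema_tests(table: pd.DataFrame, anova: AnovaTable,
                  alpha: float = 0.05) -> ExtremaTestTable:
    """Per-area one-sample t-tests against the across-area mean (fixed constant).

    Only receptors significant in ``anova`` are tested; p-values are
    uncorrected by design.  Areas whose replicates have zero variance are
    flagged degenerate (no finite t) instead of producing a number.
    """
    values = _layer_values(table, anova.layer_set)
    significant = set(anova.significant_receptors())
    receptors = list(dict.fromkeys(values.receptor))
    unknown = significant - set(receptors)
    if unknown:
        raise StatsError(f"ANOVA table names receptors missing from data: {sorted(unknown)}")

    rows = []
    not_tested = [r for r in receptors if r not in significant]
    for receptor in sorted(significant, key=receptors.index):
        sub = values[values.receptor == receptor]
        area_means = sub.groupby("area").value.mean()
        grand_mean = float(area_means.mean())
        for area, g in sub.groupby("area"):
            x = g.value.to_numpy(float)
            if np.std(x, ddof=1) == 0:
                rows.append({"receptor": receptor, "area": area,
                             "t": np.nan, "p": np.nan,
                             "significant": False, "degenerate": True,
                             "expected_value": grand_mean})
                continue
            t, p = stats.ttest_1samp(x, popmean=grand_mean)
            rows.append({"receptor": receptor, "area": area,
                         "t": float(t), "p": float(p),
                         "significant": bool(p <= alpha), "degenerate": False,
                         "expected_value": grand_mean})
    columns = ["receptor", "area", "t", "p", "significant", "degenerate",
               "expected_value"]
    df = pd.DataFrame(rows, columns=columns)
    return ExtremaTestTable(table=df, not_tested=not_tested,
                            layer_set=anova.layer_set, alpha=alpha)
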