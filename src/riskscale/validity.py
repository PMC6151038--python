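"""Construct validity: known-group comparisons, convergent correlations,
correction for attenuation, and carry-over assessment.

Known-group validity asks whether groups expected to differ (current vs
never smokers; personal vs general framing among smokers; smokers with vs
without intention to quit) differ in the expected direction.  Comparisons
use the pooled-variance Student t-test (df = n1 + n2 - 2) with Cohen's d on
the pooled SD, so printed (n, mean, SD) summary triples reproduce the test
exactly.  Convergent validity uses Spearman rank correlations against
auxiliary measures (e.g. a visual-analogue overall risk rating), optionally
disattenuated by the classical correction r / sqrt(rel_a * rel_b).
Carry-over compares measures when an assessment object was rated first
versus after other objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    label1: str
    label2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    df: int
    p: float
    cohen_d: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


@dataclass
class ConvergentResult:
    measure_a: str
    measure_b: str
    r_s: float
    n: int
    r_disattenuated: float | None = None


def known_group_ttest(
    stats1: tuple[int, float, float],
    stats2: tuple[int, float, float],
    label1: str = "group1",
    label2: str = "group2",
) -> GroupComparison:
    """Pooled-variance Student t from (n, mean, sd) summary triples."""
    n1, m1, s1 = stats1
    n2, m2, s2 = stats2
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    sp = np.sqrt(sp2)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = (m1 - m2) / se if se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), df))
    d = abs(m1 - m2) / sp if sp > 0 else 0.0
    return GroupComparison(label1, label2, n1, n2, m1, m2, s1, s2,
                           float(t), int(df), p, float(d))


def ttest_from_samples(x, y, label1="group1", label2="group2") -> GroupComparison:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    return known_group_ttest(
        (x.size, float(x.mean()), float(x.std(ddof=1))),
        (y.size, float(y.mean()), float(y.std(ddof=1))),
        label1, label2,
    )


def spearman_corr(x, y, measure_a="a", measure_b="b") -> ConvergentResult:
    """Spearman rank correlation on complete pairs (average ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return ConvergentResult(measure_a, measure_b, float("nan"), int(x.size))
    r, _ = stats.spearmanr(x, y)
    return ConvergentResult(measure_a, measure_b, float(r), int(x.size))


def disattenuate(r_obs: float, rel_a: float, rel_b: float) -> float:
    """Correction for attenuation: r / sqrt(rel_a * rel_b).

    Reliabilities must be in (0, 1].  A corrected value above 1 indicates
    over-correction (reliability assumptions too low) and is returned with
    a warning rather than truncated.
    """
    if not (0 < rel_a <= 1 and 0 < rel_b <= 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    r = r_obs / np.sqrt(rel_a * rel_b)
    if abs(r) > 1:
        warnings.warn(f"disattenuated correlation {r:.3f} exceeds 1 (over-correction)")
    return float(r)


def carry_over_assessment(
    measures: pd.DataFrame,
    obj: str,
    value_col: str = "theta",
) -> GroupComparison:
    """First-position vs later-position comparison for one assessment object.

    ``measures`` must carry columns ``object``, ``position`` and the value
    column (person measures in logits or 0-100 scores).  Respondents who
    rated the object first form one stratum; those who rated it after at
    least one other object form the other.  Reported as first - subsequent.
    """
    sel = measures[measures["object"] == obj]
    first = sel.loc[sel["position"] == 1, value_col].to_numpy(float)
    later = sel.loc[sel["position"] > 1, value_col].to_numpy(float)
    if first.size < 2 or later.size < 2:
        raise ValueError(f"object {obj}: a position stratum is (nearly) empty")
    return ttest_from_samples(first, later, f"{obj} first", f"{obj} subsequently")


def carry_over_screen(measures: pd.DataFrame, value_col: str = "theta") -> pd.DataFrame:
    """Carry-over t-tests for every object (and framing, if present)."""
    rows = []
    framings = measures["framing"].unique() if "framing" in measures.columns else [None]
    for fr in framings:
        sub = measures if fr is None else measures[measures["framing"] == fr]
        for obj in sub["object"].unique():
            try:
                gc = carry_over_assessment(sub, obj, value_col=value_col)
            except ValueError:
                continue
            rows.append({
                "framing": fr, "object": obj,
                "n_first": gc.n1, "n_later": gc.n2,
                "mean_first": gc.mean1, "mean_later": gc.mean2,
                "t": gc.t, "df": gc.df, "p": gc.p, "cohen_d": gc.cohen_d,
            })
    return pd.DataFrame(rows)
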