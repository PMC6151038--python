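"""Differential item functioning by two-way ANOVA of standardized residuals.

For each item, residuals z_ni are modelled by a fixed-effects two-way ANOVA
with the person factor under investigation (sex, age band, education,
smoking-status group, assessment object, risk framing) and the class
interval along the latent continuum.  A significant factor main effect
indicates uniform DIF (a constant shift in item difficulty between groups);
a significant factor x class-interval interaction indicates non-uniform DIF
(group differences that change along the continuum).  Tests are run at a
test-wise alpha of 5% by default; an optional Bonferroni switch divides
alpha by the number of item x factor tests.  Type-II sums of squares are
used because the person x class grid is near- but not exactly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .diagnostics import ResidualTable

DIF_ALPHA = 0.05
MIN_LEVEL_N = 20


@dataclass
class DIFResult:
    item_id: str
    factor: str
    F_uniform: float
    p_uniform: float
    F_nonuniform: float
    p_nonuniform: float
    flag_uniform: bool
    flag_nonuniform: bool
    levels_used: tuple
    evaluable: bool = True


def dif_anova(
    rt: ResidualTable,
    factor: np.ndarray | pd.Series,
    factor_name: str = "factor",
    alpha: float = DIF_ALPHA,
    min_level_n: int = MIN_LEVEL_N,
) -> list[DIFResult]:
    """Two-way residual ANOVA for every item against one person factor.

    Levels with fewer than ``min_level_n`` persons are dropped with a
    warning; if fewer than two levels remain the item is marked
    not-evaluable.  Returns one DIFResult per item.
    """
    fac = pd.Series(np.asarray(factor, dtype=object), name="fac")
    counts = fac.value_counts()
    levels = tuple(sorted(counts.index[counts >= min_level_n]))
    results: list[DIFResult] = []
    if len(levels) < 2:
        return [DIFResult(iid, factor_name, np.nan, np.nan, np.nan, np.nan,
                          False, False, levels, evaluable=False)
                for iid in rt.item_ids]
    keep = fac.isin(levels).to_numpy()
    ci = rt.class_interval[keep]
    fc = fac[keep].to_numpy()
    for i, iid in enumerate(rt.item_ids):
        z = rt.z[keep, i]
        ok = ~np.isnan(z)
        df = pd.DataFrame({"z": z[ok], "fac": fc[ok], "ci": ci[ok]})
        if df["fac"].nunique() < 2 or df["ci"].nunique() < 2:
            results.append(DIFResult(iid, factor_name, np.nan, np.nan, np.nan,
                                     np.nan, False, False, levels, evaluable=False))
            continue
        model = smf.ols("z ~ C(fac) + C(ci) + C(fac):C(ci)", data=df).fit()
        try:
            table = sm.stats.anova_lm(model, typ=2)
        except (ValueError, np.linalg.LinAlgError):
            results.append(DIFResult(iid, factor_name, np.nan, np.nan, np.nan,
                                     np.nan, False, False, levels, evaluable=False))
            continue
        Fu = float(table.loc["C(fac)", "F"])
        pu = float(table.loc["C(fac)", "PR(>F)"])
        Fn = float(table.loc["C(fac):C(ci)", "F"])
        pn = float(table.loc["C(fac):C(ci)", "PR(>F)"])
        results.append(DIFResult(
            item_id=iid, factor=factor_name,
            F_uniform=Fu, p_uniform=pu, F_nonuniform=Fn, p_nonuniform=pn,
            flag_uniform=pu < alpha, flag_nonuniform=pn < alpha,
            levels_used=levels,
        ))
    return results


def dif_screen(
    rt: ResidualTable,
    row_meta: pd.DataFrame,
    factors: list[str] | None = None,
    alpha: float = DIF_ALPHA,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Run the residual ANOVA across all requested person factors.

    ``factors`` default to every metadata column with >= 2 levels among
    {group, age_band, sex, education, object, framing}.  Returns a tidy
    table (item x factor) with flags, plus the scale-level percentage of
    items flagged on any factor accessible via ``summarize_dif``.
    """
    if factors is None:
        candidates = ["group", "age_band", "sex", "education", "object", "framing"]
        factors = [c for c in candidates
                   if c in row_meta.columns and row_meta[c].nunique() >= 2]
    a = alpha / (len(factors) * len(rt.item_ids)) if bonferroni else alpha
    rows = []
    for f in factors:
        for res in dif_anova(rt, row_meta[f], factor_name=f, alpha=a):
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def summarize_dif(dif_table: pd.DataFrame) -> dict:
    """Scale-level summary: % items with any uniform/non-uniform DIF flag."""
    by_item = dif_table.groupby("item_id").agg(
        any_uniform=("flag_uniform", "any"),
        any_nonuniform=("flag_nonuniform", "any"),
    )
    any_flag = by_item["any_uniform"] | by_item["any_nonuniform"]
    return {
        "pct_items_uniform": float(100.0 * by_item["any_uniform"].mean()),
        "pct_items_nonuniform": float(100.0 * by_item["any_nonuniform"].mean()),
        "pct_items_any": float(100.0 * any_flag.mean()),
    }
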