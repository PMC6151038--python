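"""Classical test theory evaluation of sum scores.

The CTT battery complements the Rasch diagnostics: data quality (item-level
missingness < 10%), scaling assumptions (similar item means/SDs, corrected
item-total correlations >= 0.30), scale-to-sample targeting (floor and
ceiling < 15%, |skewness| <= 1) and internal consistency (Cronbach's alpha
>= 0.80).  Sum scores are computed on complete-item respondents only — no
imputation — and the n actually used is always reported.  External 1..5
scoring is used for sums, so an 18-item scale spans 18-90 and a 6-item
administered addiction set spans 6-30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey_data import AnalysisMatrix

CITC_MIN = 0.30
ALPHA_MIN = 0.80
FLOOR_CEILING_MAX = 15.0
SKEW_BOUND = 1.0


def cronbach_alpha(matrix: np.ndarray) -> float:
    """alpha = k/(k-1) * (1 - sum(var_i)/var_total) on complete rows."""
    m = np.asarray(matrix, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    k = m.shape[1]
    if k < 2 or m.shape[0] < 3:
        raise ValueError("need >= 2 items and >= 3 complete respondents")
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var))


def skewness(scores) -> float:
    """Adjusted Fisher-Pearson standardized third moment (SPSS convention)."""
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 3 or s.std(ddof=1) == 0:
        return float("nan")
    return float(stats.skew(s, bias=False))


@dataclass
class CTTReport:
    item_stats: pd.DataFrame
    scale_stats: dict

    def flags(self) -> dict:
        sc = self.scale_stats
        return {
            "alpha_low": sc["alpha"] < ALPHA_MIN,
            "floor_high": sc["floor_pct"] >= FLOOR_CEILING_MAX,
            "ceiling_high": sc["ceiling_pct"] >= FLOOR_CEILING_MAX,
            "skew_out": abs(sc["skewness"]) > SKEW_BOUND,
            "items_citc_low": self.item_stats.loc[self.item_stats["flag_citc"], "item_id"].tolist(),
            "items_missing_high": self.item_stats.loc[self.item_stats["flag_missing"], "item_id"].tolist(),
        }


def ctt_report(am: AnalysisMatrix) -> CTTReport:
    """Full CTT battery for one analysis matrix (external 1..5 scoring)."""
    ext = np.where(am.data >= 0, am.data + 1.0, np.nan)
    n_rows, k = ext.shape
    if k < 2:
        raise ValueError("need >= 2 items")
    complete = ~np.isnan(ext).any(axis=1)
    comp = ext[complete]
    n_complete = int(complete.sum())
    if n_complete < 2:
        raise ValueError("fewer than 2 complete-item respondents")

    sums = comp.sum(axis=1)
    tmin, tmax = 1.0 * k, 5.0 * k
    citc = np.full(k, np.nan)
    for i in range(k):
        rest = comp.sum(axis=1) - comp[:, i]
        if comp[:, i].std() > 0 and rest.std() > 0:
            citc[i] = np.corrcoef(comp[:, i], rest)[0, 1]

    cc = np.corrcoef(comp.T)
    iu = np.triu_indices(k, 1)
    iic = cc[iu]

    item_stats = pd.DataFrame({
        "item_id": am.item_ids,
        "mean": np.nanmean(ext, axis=0),
        "sd": np.nanstd(ext, axis=0, ddof=1),
        "missing_pct": am.missing_pct(),
        "dk_pct": am.dk_pct(),
        "citc": citc,
    })
    item_stats["flag_citc"] = item_stats["citc"] < CITC_MIN
    item_stats["flag_missing"] = item_stats["missing_pct"] >= 10.0

    scale_stats = {
        "n_items": k,
        "n_rows": n_rows,
        "n_complete": n_complete,
        "range_theoretical": (tmin, tmax),
        "range_observed": (float(sums.min()), float(sums.max())),
        "mean": float(sums.mean()),
        "sd": float(sums.std(ddof=1)),
        "floor_pct": float(100.0 * np.mean(sums == tmin)),
        "ceiling_pct": float(100.0 * np.mean(sums == tmax)),
        "skewness": skewness(sums),
        "alpha": cronbach_alpha(comp) if n_complete >= 3 else float("nan"),
        "mean_iic": float(np.nanmean(iic)),
        "range_iic": (float(np.nanmin(iic)), float(np.nanmax(iic))),
        "dk_pct_range": (float(am.dk_pct().min()), float(am.dk_pct().max())),
    }
    return CTTReport(item_stats=item_stats, scale_stats=scale_stats)
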