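"""Rasch measurement theory diagnostics: residuals, fit, targeting, reliability.

All diagnostics start from the table of standardized person-item residuals

    z_ni = (x_ni - E[x_ni | theta_n]) / sqrt(Var[x_ni | theta_n])

evaluated at the calibrated thresholds and measured person locations.
Persons are ranked by their measure and split into G near-equal "class
intervals" (G = 10 by default, giving the conventional df = 9 item-trait
chi-square).  Because the person measures are themselves estimated from the
responses, the naive residual variance is deflated by roughly
1 - V_ni / I_n (item information share of the person's test information);
the fit statistics below correct for this so they are centred under the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import ItemCalibration, PersonEstimate, pcm_moments

DEFAULT_CLASS_INTERVALS = 10
FIT_RESIDUAL_BOUND = 2.5
RESIDUAL_CORR_ABS = 0.30
N_ADJUST_DEFAULT = 500


@dataclass
class ResidualTable:
    """Standardized residuals with model moments and class intervals."""

    z: np.ndarray          # (n, I), nan where unobserved
    observed: np.ndarray   # x_ni, nan where unobserved
    expected: np.ndarray   # E[x_ni]
    variance: np.ndarray   # Var[x_ni]
    mu3: np.ndarray        # third central moment
    mu4: np.ndarray        # fourth central moment
    deflation: np.ndarray  # 1 - V_ni / I_n   (df-loss correction factor)
    class_interval: np.ndarray  # (n,), 0..G-1
    theta: np.ndarray      # person measures
    item_ids: list[str]


def _class_intervals(theta: np.ndarray, G: int) -> np.ndarray:
    n = theta.shape[0]
    if G > n:
        raise ValueError(f"more class intervals ({G}) than persons ({n})")
    order = np.argsort(theta, kind="stable")  # ties broken by row order
    ci = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, G)):
        ci[chunk] = g
    return ci


def standardized_residuals(
    data: np.ndarray,
    calibrations: list[ItemCalibration],
    persons: list[PersonEstimate],
    G: int = DEFAULT_CLASS_INTERVALS,
) -> ResidualTable:
    """Build the residual table for a persons x items matrix.

    ``data`` uses internal 0..m codes with -1 for missing; residuals are
    defined only where a response was observed.
    """
    data = np.asarray(data)
    n, n_items = data.shape
    theta = np.array([p.theta for p in persons], dtype=float)
    if theta.shape[0] != n:
        raise ValueError("persons do not match matrix rows")

    E = np.full((n, n_items), np.nan)
    V = np.full((n, n_items), np.nan)
    M3 = np.full((n, n_items), np.nan)
    M4 = np.full((n, n_items), np.nan)
    obs = data >= 0
    for i, cal in enumerate(calibrations):
        e, v, m3, m4 = pcm_moments(theta, np.asarray(cal.thresholds, float), order=4)
        E[:, i], V[:, i], M3[:, i], M4[:, i] = e, v, m3, m4
    info = np.where(obs, V, 0.0).sum(axis=1)
    defl = 1.0 - np.where(obs, V, np.nan) / np.maximum(info, 1e-12)[:, None]

    x = np.where(obs, data, np.nan).astype(float)
    z = (x - E) / np.sqrt(np.maximum(V, 1e-12))
    z[~obs] = np.nan
    for arr in (E, V, M3, M4, defl):
        arr[~obs] = np.nan

    return ResidualTable(
        z=z, observed=x, expected=E, variance=V, mu3=M3, mu4=M4,
        deflation=defl, class_interval=_class_intervals(theta, G),
        theta=theta, item_ids=[c.item_id for c in calibrations],
    )


# ---------------------------------------------------------------------------
# Item fit
# ---------------------------------------------------------------------------

def item_fit_residual(rt: ResidualTable, item: int, min_obs: int = 30) -> float:
    """Standardized item fit residual (RUMM-style interpretation).

    The residual sum of squares U_i = sum_n z_ni^2 is compared with its
    model expectation m_i = sum_n (1 - V_ni/I_n) and variance
    v_i = sum_n d_ni^2 (mu4/V^2 - 1), then normalized by the
    Wilson-Hilferty cube-root transform of a chi-square with effective
    df = 2 m^2 / v.  Values within ±2.5 indicate adequate fit; negative
    values indicate over-discrimination (responses more deterministic than
    the model predicts), positive values under-discrimination.

    Returns nan when fewer than ``min_obs`` observations are available.
    """
    z = rt.z[:, item]
    ok = ~np.isnan(z)
    n_obs = int(ok.sum())
    if n_obs < min_obs:
        return float("nan")
    d = rt.deflation[ok, item]
    U = float((z[ok] ** 2).sum())
    m = float(d.sum())
    kurt = rt.mu4[ok, item] / rt.variance[ok, item] ** 2 - 1.0
    v = float((d**2 * kurt).sum())
    if v <= 0 or m <= 0:
        return float("nan")
    nu = 2.0 * m * m / v
    c = 2.0 / (9.0 * nu)
    return float(((U / m) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c))


def item_trait_chi_square(
    rt: ResidualTable,
    item: int,
    n_adjust: int | None = N_ADJUST_DEFAULT,
) -> tuple[float, int, float, float]:
    """Class-interval item-trait chi-square.

    Within each class interval the summed observed-minus-expected score is
    standardized by its (df-corrected) model variance and squared; the sum
    over intervals is chi-square with df = G - 1.  When ``n_adjust`` is set
    and fewer observations than n_adjust are NOT available, the statistic is
    scaled by n_adjust / n before the p-value is computed, mitigating the
    excessive power of very large samples; the raw statistic is returned
    alongside.

    Returns (chi2_raw, df, p_value, chi2_adjusted).
    """
    z_col = rt.observed[:, item] - rt.expected[:, item]
    ok = ~np.isnan(z_col)
    G = int(rt.class_interval.max()) + 1
    chi2 = 0.0
    used = 0
    for g in range(G):
        sel = ok & (rt.class_interval == g)
        if sel.sum() == 0:
            continue  # empty interval: merged by omission, df reduced below
        num = float(z_col[sel].sum())
        den = float((rt.variance[sel, item] * rt.deflation[sel, item]).sum())
        if den <= 0:
            continue
        chi2 += num * num / den
        used += 1
    df = max(used - 1, 1)
    n_obs = int(ok.sum())
    chi2_adj = chi2
    if n_adjust is not None and n_obs > n_adjust:
        chi2_adj = chi2 * n_adjust / n_obs
    p = float(stats.chi2.sf(chi2_adj, df))
    return chi2, df, p, chi2_adj


def threshold_order_check(calibrations: list[ItemCalibration]) -> pd.DataFrame:
    """Strictly increasing thresholds mark working response categories."""
    return pd.DataFrame({
        "item_id": [c.item_id for c in calibrations],
        "ordered": [c.ordered() for c in calibrations],
    })


def targeting_coverage(
    persons: list[PersonEstimate] | np.ndarray,
    calibrations: list[ItemCalibration],
) -> float:
    """Percent of person measures inside the span of the item thresholds.

    One operational reading of scale-to-sample targeting: the share of the
    sample whose measures the item thresholds bracket.  Invariant under a
    common translation of measures and thresholds.
    """
    theta = np.asarray([p.theta for p in persons] if persons and isinstance(persons[0], PersonEstimate) else persons, dtype=float)
    if theta.size == 0 or not calibrations:
        raise ValueError("need at least one person and one item")
    all_tau = np.concatenate([np.asarray(c.thresholds, float) for c in calibrations])
    lo, hi = all_tau.min(), all_tau.max()
    return float(100.0 * np.mean((theta >= lo) & (theta <= hi)))


def residual_correlation_flags(
    rt: ResidualTable,
    abs_critical: float = RESIDUAL_CORR_ABS,
    min_joint: int = 10,
) -> dict:
    """Local-dependence screen on item-pair residual correlations.

    Pearson correlations over pairwise-complete persons.  Rule A flags
    r > 0.30; rule B flags r > mean(all pairwise r) + 0.30 (on independent
    items the mean pairwise residual correlation is slightly negative,
    about -1/(L-1), so the rule-B critical value sits below 0.30).
    """
    if rt.z.shape[1] < 3:
        raise ValueError("need >= 3 items for the local-dependence screen")
    zdf = pd.DataFrame(rt.z, columns=rt.item_ids)
    corr = zdf.corr(min_periods=min_joint)
    iu = np.triu_indices(len(rt.item_ids), k=1)
    vals = corr.to_numpy()[iu]
    excluded = [(rt.item_ids[a], rt.item_ids[b])
                for a, b, v in zip(iu[0], iu[1], vals) if np.isnan(v)]
    finite = vals[~np.isnan(vals)]
    mean_r = float(finite.mean()) if finite.size else float("nan")
    crit_b = mean_r + abs_critical
    pairs = pd.DataFrame({
        "item_a": [rt.item_ids[a] for a in iu[0]],
        "item_b": [rt.item_ids[b] for b in iu[1]],
        "r": vals,
    }).dropna(subset=["r"])
    pairs["flag_abs"] = pairs["r"] > abs_critical
    pairs["flag_rel"] = pairs["r"] > crit_b
    return {
        "pairs": pairs.reset_index(drop=True),
        "mean_r": mean_r,
        "critical_abs": abs_critical,
        "critical_rel": crit_b,
        "excluded_pairs": excluded,
    }


def person_separation_index(persons: list[PersonEstimate]) -> float:
    """PSI = (var(theta_hat) - mean(se^2)) / var(theta_hat), floored at 0.

    Runs from 0 (all error) to 1 (no error).  Computed from WLE measures
    including extreme-score persons (their WLE is finite); persons with
    zero information (infinite se) are excluded.
    """
    th = np.array([p.theta for p in persons if np.isfinite(p.se)])
    se2 = np.array([p.se**2 for p in persons if np.isfinite(p.se)])
    if th.size < 2:
        raise ValueError("need >= 2 persons with finite estimates")
    var = float(th.var(ddof=1))
    if var <= 0:
        return float("nan")
    return max(0.0, (var - float(se2.mean())) / var)


# ---------------------------------------------------------------------------
# Scale-level fit report
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Per-item fit battery plus scale-level summary percentages."""

    items: pd.DataFrame
    G: int
    n_adjust: int | None
    pct_fit_residual_out: float = field(init=False)
    pct_chi2_sig: float = field(init=False)
    pct_disordered: float = field(init=False)

    def __post_init__(self):
        it = self.items
        ev = it["fit_residual"].notna()
        self.pct_fit_residual_out = float(
            100.0 * (it.loc[ev, "fit_residual"].abs() > FIT_RESIDUAL_BOUND).mean()) if ev.any() else float("nan")
        self.pct_chi2_sig = float(100.0 * (it["p_value"] < 0.05).mean())
        self.pct_disordered = float(100.0 * (~it["ordered"]).mean())


def fit_report(
    rt: ResidualTable,
    calibrations: list[ItemCalibration],
    n_adjust: int | None = N_ADJUST_DEFAULT,
    alpha: float = 0.05,
) -> FitReport:
    """Assemble the per-item fit table (fit residual, chi-square, ordering)."""
    G = int(rt.class_interval.max()) + 1
    rows = []
    for i, cal in enumerate(calibrations):
        fr = item_fit_residual(rt, i)
        chi2, df, p, chi2_adj = item_trait_chi_square(rt, i, n_adjust=n_adjust)
        rows.append({
            "item_id": cal.item_id,
            "location": cal.location,
            "se_location": cal.se_location,
            "fit_residual": fr,
            "chi_square": chi2,
            "chi_square_adjusted": chi2_adj,
            "df": df,
            "p_value": p,
            "ordered": cal.ordered(),
            "flag_misfit": bool(abs(fr) > FIT_RESIDUAL_BOUND) if np.isfinite(fr) else False,
            "flag_chi2": p < alpha,
        })
    return FitReport(items=pd.DataFrame(rows), G=G, n_adjust=n_adjust)
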