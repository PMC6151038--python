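"""Iterative item reduction driven by the fit / DIF / dependence flags.

The loop mirrors the evidence-led reduction practice used when forming a
scale from an item pool: calibrate, run the full diagnostic battery, flag
items (misfit beyond ±2.5, significant item-trait chi-square at the
n-adjusted sample, DIF at alpha, local dependence against the mean+0.3
rule), remove the worst offenders, and recalibrate — for at most
``max_iterations`` passes or until nothing is flagged.  Auto mode ranks
flagged items by |fit residual| then DIF F (misfit first, then DIF, then
local dependence) and caps removals per pass; interactive mode lets an
operator choose among the flagged items via a callback.  Every removal is
logged with its reasons, so the trail is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import diagnostics as dg
from .dif import dif_screen
from .pcm import calibrate_items, estimate_persons


@dataclass
class ReductionCriteria:
    max_fit_residual: float = 2.5
    chi2_alpha: float = 0.05
    n_adjust: int | None = 500
    dif_alpha: float = 0.05
    residual_corr_margin: float = 0.30  # rule: r > mean(all r) + margin
    max_removals_per_iteration: int = 6
    max_iterations: int = 3
    G: int = 10


def flag_items(fit: dg.FitReport,
               dif_table: pd.DataFrame | None,
               ld: dict | None,
               criteria: ReductionCriteria) -> pd.DataFrame:
    """Combine the diagnostic batteries into one boolean flag vector per item."""
    out = fit.items[["item_id", "fit_residual", "p_value"]].copy()
    out["misfit"] = fit.items["fit_residual"].abs() > criteria.max_fit_residual
    out["misfit"] &= fit.items["fit_residual"].notna()
    out["chi2"] = fit.items["p_value"] < criteria.chi2_alpha
    out["disordered"] = ~fit.items["ordered"]
    out["dif"] = False
    out["dif_F"] = 0.0
    if dif_table is not None and len(dif_table):
        by_item = dif_table.groupby("item_id").agg(
            dif=("flag_uniform", "any"), dif_nu=("flag_nonuniform", "any"),
            F=("F_uniform", "max"))
        out["dif"] = out["item_id"].map(by_item["dif"] | by_item["dif_nu"]).fillna(False)
        out["dif_F"] = out["item_id"].map(by_item["F"]).fillna(0.0)
    out["local_dependence"] = False
    if ld is not None:
        flagged_pairs = ld["pairs"][ld["pairs"]["flag_rel"]]
        # flag only the worse-fitting member of each dependent pair
        fitmap = dict(zip(out["item_id"], out["fit_residual"].abs().fillna(0.0)))
        for _, row in flagged_pairs.iterrows():
            worse = max((row["item_a"], row["item_b"]), key=lambda i: fitmap.get(i, 0.0))
            out.loc[out["item_id"] == worse, "local_dependence"] = True
    out["any_flag"] = out[["misfit", "chi2", "disordered", "dif", "local_dependence"]].any(axis=1)
    return out


@dataclass
class ReductionTrail:
    iterations: list[dict] = dc_field(default_factory=list)
    retained: list[str] = dc_field(default_factory=list)
    removed: dict = dc_field(default_factory=dict)  # item_id -> reasons

    def to_json(self, path=None) -> str:
        payload = {
            "iterations": [
                {k: (v.to_dict("records") if isinstance(v, pd.DataFrame) else v)
                 for k, v in it.items()} for it in self.iterations
            ],
            "retained": self.retained,
            "removed": self.removed,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _diagnose(data, item_ids, row_meta, criteria, dif_factors):
    cals, _ = calibrate_items(data, item_ids=item_ids)
    persons = estimate_persons(data, cals)
    rt = dg.standardized_residuals(data, cals, persons, G=criteria.G)
    fit = dg.fit_report(rt, cals, n_adjust=criteria.n_adjust,
                        alpha=criteria.chi2_alpha)
    dif_table = None
    if row_meta is not None:
        dif_table = dif_screen(rt, row_meta, factors=dif_factors,
                               alpha=criteria.dif_alpha)
    ld = dg.residual_correlation_flags(rt, abs_critical=criteria.residual_corr_margin) \
        if data.shape[1] >= 3 else None
    return cals, fit, dif_table, ld


def reduce_scale(
    data: np.ndarray,
    item_ids: list[str],
    row_meta: pd.DataFrame | None = None,
    criteria: ReductionCriteria | None = None,
    mode: str = "auto",
    dif_factors: list[str] | None = None,
    choose=None,
) -> ReductionTrail:
    """Run the calibrate-diagnose-flag-remove loop.

    ``mode='auto'`` removes flagged items ranked misfit-first (by
    |fit residual|), then DIF (by F), then local dependence, at most
    ``max_removals_per_iteration`` per pass.  ``mode='interactive'`` calls
    ``choose(flag_table) -> list[item_id]`` each pass.  The loop refuses to
    empty the scale: if every remaining item is flagged it stops and
    reports instead.
    """
    criteria = criteria or ReductionCriteria()
    if mode not in ("auto", "interactive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "interactive" and choose is None:
        raise ValueError("interactive mode needs a choose(flag_table) callback")
    data = np.asarray(data)
    if data.shape[1] < 3:
        raise ValueError("initial scale must have >= 3 items")

    current = list(item_ids)
    trail = ReductionTrail()
    for it_no in range(criteria.max_iterations):
        idx = [item_ids.index(i) for i in current]
        sub = data[:, idx]
        keep_rows = (sub >= 0).any(axis=1)
        meta = row_meta.loc[keep_rows].reset_index(drop=True) if row_meta is not None else None
        cals, fit, dif_table, ld = _diagnose(sub[keep_rows], current, meta,
                                             criteria, dif_factors)
        flags = flag_items(fit, dif_table, ld, criteria)
        snapshot = {
            "iteration": it_no + 1,
            "items": list(current),
            "flags": flags,
            "pct_misfit": float(100 * flags["misfit"].mean()),
            "pct_dif": float(100 * flags["dif"].mean()),
        }
        flagged = flags[flags["any_flag"]]
        if flagged.empty:
            trail.iterations.append({**snapshot, "removed": []})
            break
        if len(flagged) == len(current):
            snapshot["note"] = "all items flagged; stopping without emptying the scale"
            trail.iterations.append({**snapshot, "removed": []})
            break
        if mode == "interactive":
            to_remove = list(choose(flags))
        else:
            ranked = flagged.assign(
                prio=np.select(
                    [flagged["misfit"], flagged["dif"]], [0, 1], default=2),
                mag=flagged["fit_residual"].abs().fillna(0.0) + flagged["dif_F"],
            ).sort_values(["prio", "mag"], ascending=[True, False], kind="stable")
            # dependent items distort each other's fit: never drop both
            # members of a flagged pair in the same pass
            partners: dict[str, set] = {}
            if ld is not None:
                dep = ld["pairs"][ld["pairs"]["flag_rel"] | ld["pairs"]["flag_abs"]]
                for _, pr in dep.iterrows():
                    partners.setdefault(pr["item_a"], set()).add(pr["item_b"])
                    partners.setdefault(pr["item_b"], set()).add(pr["item_a"])
            to_remove = []
            for iid in ranked["item_id"]:
                if len(to_remove) >= criteria.max_removals_per_iteration:
                    break
                if partners.get(iid, set()) & set(to_remove):
                    continue
                to_remove.append(iid)
        to_remove = [i for i in to_remove if i in current]
        if len(current) - len(to_remove) < 2:
            to_remove = to_remove[: len(current) - 2]
        for iid in to_remove:
            row = flags.loc[flags["item_id"] == iid].iloc[0]
            trail.removed[iid] = [c for c in
                                  ("misfit", "chi2", "disordered", "dif", "local_dependence")
                                  if bool(row[c])]
        trail.iterations.append({**snapshot, "removed": to_remove})
        current = [i for i in current if i not in to_remove]
        if not to_remove:
            break
    trail.retained = current
    return trail
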