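"""Raw-score-to-measure conversion and the 0-100 convenience scale.

Raw-score sufficiency of the Rasch model permits a fixed conversion table
for complete data: every raw score r in 0..max maps to the weighted
likelihood (WLE) measure solving the Warm-corrected score equation, with a
standard error from the test information at the estimate.  Logit measures
are then mapped linearly to 0-100: logit 0 (the centred item mean) maps to
50 and the most extreme measures to the scale endpoints.  When the extreme
WLE measures are asymmetric about 0 the map uses the larger magnitude, so
50 stays anchored at logit 0 and the shorter tail does not reach its bound
(flagged in the table metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcm import ItemCalibration, _score_info, _solve_theta


@dataclass
class ConversionTable:
    table: pd.DataFrame  # raw_score, logit, se, score_0_100
    theta_scale: float   # Theta = max |extreme measure|
    symmetric: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def logit_to_0_100(theta, theta_scale: float):
    """Linear map s = 50 + 50*theta/Theta, clamped to [0, 100]."""
    s = 50.0 + 50.0 * np.asarray(theta, dtype=float) / theta_scale
    out = np.clip(s, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def build_conversion_table(calibrations: list[ItemCalibration]) -> ConversionTable:
    """WLE conversion table for a fixed, completely administered item set."""
    taus = [np.asarray(c.thresholds, float) for c in calibrations]
    max_raw = int(sum(t.shape[0] for t in taus))
    logits = np.empty(max_raw + 1)
    ses = np.empty(max_raw + 1)
    for r in range(max_raw + 1):
        th = _solve_theta(r, taus, "WLE")
        _, info = _score_info(th, taus, order=2)
        logits[r] = th
        ses[r] = 1.0 / np.sqrt(info) if info > 0 else np.inf
    if not np.all(np.diff(logits) > 0):
        raise RuntimeError("non-monotone WLE measures: solver failure")
    theta_scale = float(max(abs(logits[0]), abs(logits[-1])))
    scores = logit_to_0_100(logits, theta_scale)
    table = pd.DataFrame({
        "raw_score": np.arange(max_raw + 1),
        "logit": logits,
        "se": ses,
        "score_0_100": scores,
    })
    return ConversionTable(
        table=table,
        theta_scale=theta_scale,
        symmetric=bool(np.isclose(abs(logits[0]), abs(logits[-1]), atol=1e-6)),
    )
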