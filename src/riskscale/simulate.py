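"""Synthetic survey generator emulating the study's data structure.

The generator produces long-format response datasets with the structure the
pipeline assumes: four equally sized smoking-status strata, 18 health-risk
and 7 addiction-risk items (with the cessation-specific applicability
subset), 5-point ratings drawn from the partial credit model, don't-know
responses applied completely at random at a configurable rate, randomized
object presentation sequences, group-level latent mean differences of the
magnitude observed in the field surveys, optional carry-over shifts, and an
auxiliary visual-analogue (VAS) measure with a configurable reliability.

Latent locations are drawn per respondent-object-framing row from a normal
whose mean is the object/framing base mean plus a smoking-group offset;
rows are treated as independent measurements (racked), which is what the
downstream stacked calibration assumes.  Every dataset is emitted together
with a truth record carrying the generating parameters, so recovery can be
scored exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .pcm import DEFAULT_SEED, pcm_category_probs
from .survey_data import (
    FRAMINGS, GROUPS, LONG_COLUMNS, OBJECTS,
    ItemSpec, ResponseDataset, default_instrument, items_for,
)

# Item locations of the calibrated instrument (logits), used as generator truth.
HEALTH_LOCATIONS = {
    "H01": 0.150, "H02": 0.035, "H03": -0.477, "H04": -0.193, "H05": -0.058,
    "H06": -0.015, "H07": 0.176, "H08": -0.051, "H09": 0.049, "H10": 0.135,
    "H11": -0.132, "H12": 0.045, "H13": -0.288, "H14": -0.147, "H15": 0.426,
    "H16": 0.319, "H17": 0.001, "H18": 0.150,
}
ADDICTION_LOCATIONS = {
    "A1": 0.428, "A2": -0.133, "A3": 0.311, "A4": 0.105, "A5": 0.230,
    "A6": 0.097, "A7": -1.038,
}

# Object/framing base means (logits) of the latent risk perception.
BASE_MEANS = {
    ("health", "P"): {"CC": 2.12, "THS": 0.51, "ECIG": -0.15, "NRT": -1.47, "CESS": -0.69},
    ("health", "G"): {"CC": 2.51, "THS": 0.63, "ECIG": -0.17, "NRT": -0.70, "CESS": 0.07},
    ("addiction", "P"): {"CC": 2.91, "THS": 1.23, "ECIG": 0.61, "NRT": -0.30, "CESS": -0.89},
    ("addiction", "G"): {"CC": 3.73, "THS": 1.69, "ECIG": 0.75, "NRT": 0.30, "CESS": -0.04},
}
# Smoking-group offsets about the object mean, per framing (never smokers
# perceive smoking-related risk higher; smokers intending to quit higher
# than those not intending).
GROUP_OFFSETS = {
    "P": {"CS_NIQ": -1.19, "CS_IQ": -0.54, "FS": 0.88, "NS": 0.93},
    "G": {"CS_NIQ": -1.22, "CS_IQ": -0.26, "FS": 0.35, "NS": 1.14},
}

# Equally spaced threshold offsets about the item location.  The ±3.5-logit
# span reproduces effective threshold ranges of about -4.5..+4 together with
# the item locations above.
THRESHOLD_OFFSETS = (-3.5, -3.5 / 3, 3.5 / 3, 3.5)


@dataclass
class DIFInjection:
    """Planted item defect: uniform (threshold shift for a focal level) or
    non-uniform (discrimination != 1 for a focal level; a None level applies
    to everyone, producing plain misfit)."""

    item_id: str
    factor: str | None = None   # metadata column, or None for everyone
    level: object | None = None
    kind: str = "uniform"       # "uniform" | "nonuniform"
    value: float = 0.0          # shift (logits) or discrimination


@dataclass
class GeneratorConfig:
    n_per_group: int = 410
    items: list[ItemSpec] = dc_field(default_factory=default_instrument)
    item_locations: dict = dc_field(
        default_factory=lambda: {**HEALTH_LOCATIONS, **ADDICTION_LOCATIONS})
    threshold_offsets: tuple = THRESHOLD_OFFSETS
    base_means: dict = dc_field(default_factory=lambda: copy.deepcopy(BASE_MEANS))
    group_offsets: dict = dc_field(default_factory=lambda: copy.deepcopy(GROUP_OFFSETS))
    group_sd: float = 2.9
    dk_rate: float | dict = 0.12        # scalar or per-item; in [0.08, 0.15] realistically
    missing_rate: float = 0.001
    objects: tuple = OBJECTS
    framings: tuple = FRAMINGS
    carry_over: dict = dc_field(default_factory=dict)  # object -> shift when position > 1
    dif_injections: list[DIFInjection] = dc_field(default_factory=list)
    vas_reliability: float = 0.6
    vas_true_corr: float = 0.8  # correlation of the VAS true score with theta
    ns_skip_personal: tuple = ("NRT", "CESS")  # objects never smokers skip in P framing
    seed: int = DEFAULT_SEED

    def thresholds_for(self, item_id: str) -> np.ndarray:
        loc = self.item_locations[item_id]
        return loc + np.asarray(self.threshold_offsets, float)

    def validate(self) -> None:
        if not 0 < self.vas_reliability <= 1:
            raise ValueError("vas_reliability must be in (0, 1]")
        if not 0 <= abs(self.vas_true_corr) <= 1:
            raise ValueError("vas_true_corr must be in [-1, 1]")
        if self.group_sd <= 0:
            raise ValueError("group_sd must be positive")
        rates = (self.dk_rate.values() if isinstance(self.dk_rate, dict)
                 else [self.dk_rate])
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("dk rates must be in [0, 1]")
        if np.any(np.diff(self.threshold_offsets) <= 0):
            raise ValueError("threshold offsets must be strictly increasing")
        missing = [it.item_id for it in self.items
                   if it.item_id not in self.item_locations]
        if missing:
            raise ValueError(f"no location configured for items {missing}")


@dataclass
class TruthRecord:
    theta: pd.DataFrame          # respondent_id, group, object, framing, scale, theta
    thresholds: dict             # item_id -> true thresholds (pre-injection)
    injections: list[DIFInjection]
    config: GeneratorConfig


def inject_dif(config: GeneratorConfig, item_id: str, factor: str | None,
               level, kind: str, value: float) -> GeneratorConfig:
    """Return a copy of the config with one planted defect (replacing any
    earlier injection on the same item and factor, with a warning)."""
    if kind not in ("uniform", "nonuniform"):
        raise ValueError(f"unknown injection kind {kind!r}")
    if item_id not in {it.item_id for it in config.items}:
        raise ValueError(f"unknown item {item_id!r}")
    cfg = copy.deepcopy(config)
    prev = [inj for inj in cfg.dif_injections
            if inj.item_id == item_id and inj.factor == factor]
    if prev:
        import warnings
        warnings.warn(f"replacing existing injection on {item_id}/{factor}")
        cfg.dif_injections = [inj for inj in cfg.dif_injections if inj not in prev]
    cfg.dif_injections.append(DIFInjection(item_id, factor, level, kind, value))
    return cfg


def sample_pcm_matrix(theta: np.ndarray, thresholds: list[np.ndarray],
                      rng: np.random.Generator,
                      discrimination: np.ndarray | None = None) -> np.ndarray:
    """Draw a persons x items category matrix from the PCM.

    ``discrimination`` (per item, default all 1) scales the category weights
    as exp(a * sum(theta - tau_k)); a != 1 breaks the Rasch slope and
    produces over- (a > 1) or under-discriminating (a < 1) items.
    """
    theta = np.asarray(theta, float)
    n = theta.shape[0]
    out = np.empty((n, len(thresholds)), dtype=np.int64)
    for i, tau in enumerate(thresholds):
        a = 1.0 if discrimination is None else float(discrimination[i])
        p = pcm_category_probs(a * theta, a * np.asarray(tau, float))
        u = rng.random((n, 1))
        out[:, i] = (p.cumsum(axis=1) < u).sum(axis=1)
    return out


def _row_grid(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Respondent x object x framing rows with groups, sequences, positions."""
    n_resp = cfg.n_per_group * len(GROUPS)
    resp = pd.DataFrame({
        "respondent_id": [f"R{i + 1:05d}" for i in range(n_resp)],
        "group": np.repeat(list(GROUPS), cfg.n_per_group),
        "age_band": rng.choice(["18-30", "31-45", "46+"], size=n_resp, p=[0.31, 0.33, 0.36]),
        "sex": rng.choice(["M", "F"], size=n_resp),
        "education": rng.choice(["HS_or_less", "college_plus"], size=n_resp, p=[0.38, 0.62]),
    })
    n_obj = len(cfg.objects)
    seq = np.array([rng.permutation(n_obj) for _ in range(n_resp)])
    rows = []
    for j, obj in enumerate(cfg.objects):
        for fr in cfg.framings:
            block = resp.copy()
            block["object"] = obj
            block["framing"] = fr
            block["position"] = seq[:, j] + 1
            rows.append(block)
    grid = pd.concat(rows, ignore_index=True)
    if cfg.ns_skip_personal:
        drop = ((grid["group"] == "NS") & (grid["framing"] == "P")
                & grid["object"].isin(cfg.ns_skip_personal))
        grid = grid[~drop].reset_index(drop=True)
    return grid


def generate_survey(cfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> tuple[ResponseDataset, TruthRecord]:
    """Generate one synthetic survey plus its truth record.

    Fully deterministic given the config and seed (``seed`` overrides
    ``cfg.seed``).  Returns the long-format ResponseDataset (with VAS
    measures attached as ``dataset.vas``) and the truth record.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    grid = _row_grid(cfg, rng)
    scales = sorted({it.scale for it in cfg.items})
    thresholds_true = {it.item_id: cfg.thresholds_for(it.item_id) for it in cfg.items}

    long_parts = []
    truth_parts = []
    vas_parts = []
    for scale in scales:
        for fr in cfg.framings:
            base = cfg.base_means.get((scale, fr), {})
            offs = cfg.group_offsets.get(fr, {})
            sub = grid[grid["framing"] == fr].copy()
            mean = (sub["object"].map(lambda o: base.get(o, 0.0)).to_numpy()
                    + sub["group"].map(lambda g: offs.get(g, 0.0)).to_numpy())
            for obj, shift in cfg.carry_over.items():
                mean = mean + np.where(
                    (sub["object"] == obj) & (sub["position"] > 1), shift, 0.0)
            theta = rng.normal(mean, cfg.group_sd)
            sub["scale"] = scale
            sub["theta"] = theta
            truth_parts.append(sub[["respondent_id", "group", "object",
                                    "framing", "position", "scale", "theta"]])

            for obj in cfg.objects:
                items = items_for(cfg.items, scale, obj)
                if not items:
                    continue
                rows = sub[sub["object"] == obj]
                if rows.empty:
                    continue
                th = rows["theta"].to_numpy()

                def _rowwise_probs(theta_v, tau_rows, a=1.0):
                    eta = np.cumsum(np.concatenate(
                        [np.zeros((len(theta_v), 1)),
                         a * (theta_v[:, None] - tau_rows)], axis=1), axis=1)
                    eta -= eta.max(axis=1, keepdims=True)
                    w = np.exp(eta)
                    return w / w.sum(axis=1, keepdims=True)

                mat = np.empty((len(rows), len(items)), dtype=np.int64)
                for k, it in enumerate(items):
                    tau_k = np.tile(thresholds_true[it.item_id], (len(rows), 1))
                    disc, focal = 1.0, None
                    for inj in cfg.dif_injections:
                        if inj.item_id != it.item_id:
                            continue
                        affected = (np.ones(len(rows), bool) if inj.factor is None
                                    else (rows[inj.factor] == inj.level).to_numpy())
                        if inj.kind == "uniform":
                            tau_k[affected] += inj.value
                        else:
                            disc, focal = inj.value, affected
                    p = _rowwise_probs(th, tau_k)
                    if focal is not None and focal.any():
                        p[focal] = _rowwise_probs(th[focal], tau_k[focal], a=disc)
                    u = rng.random((len(rows), 1))
                    mat[:, k] = (p.cumsum(axis=1) < u).sum(axis=1)

                # don't-know and plain-missing masks (MCAR)
                dk_rates = np.array([
                    cfg.dk_rate.get(it.item_id, 0.0) if isinstance(cfg.dk_rate, dict)
                    else cfg.dk_rate for it in items])
                dk_mask = rng.random(mat.shape) < dk_rates[None, :]
                miss_mask = (~dk_mask) & (rng.random(mat.shape) < cfg.missing_rate)

                part = pd.DataFrame({
                    c: np.repeat(rows[c].to_numpy(), len(items))
                    for c in ["respondent_id", "group", "age_band", "sex",
                              "education", "object", "framing", "position"]
                })
                part["item_id"] = np.tile([it.item_id for it in items], len(rows))
                resp = (mat + 1).astype(float)
                resp[dk_mask | miss_mask] = np.nan
                part["response"] = resp.ravel()
                part["dk"] = dk_mask.ravel()
                long_parts.append(part)

            # auxiliary VAS per respondent-object for this scale and framing
            z = (theta - theta.mean()) / max(theta.std(), 1e-12)
            c = cfg.vas_true_corr
            true_score = c * z + np.sqrt(max(1 - c**2, 0.0)) * rng.normal(size=len(z))
            lam = np.sqrt(cfg.vas_reliability)
            vas = lam * true_score + np.sqrt(1 - cfg.vas_reliability) * rng.normal(size=len(z))
            v = sub[["respondent_id", "group", "object", "framing"]].copy()
            v["scale"] = scale
            v["vas"] = 50.0 + 15.0 * vas
            vas_parts.append(v)

    long_df = pd.concat(long_parts, ignore_index=True)
    long_df["response"] = long_df["response"].astype("Int64")
    long_df = long_df[LONG_COLUMNS + ["dk"]]
    ds = ResponseDataset(df=long_df, items=cfg.items)
    ds.vas = pd.concat(vas_parts, ignore_index=True)
    truth = TruthRecord(
        theta=pd.concat(truth_parts, ignore_index=True),
        thresholds=thresholds_true,
        injections=list(cfg.dif_injections),
        config=cfg,
    )
    return ds, truth
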