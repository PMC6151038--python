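"""Data model and IO for multi-object, dual-framing polytomous survey responses.

A response dataset is a long table of 5-point ratings (1..5 externally,
0..4 internally) given by respondents to risk items, repeated over up to
five assessment objects (conventional cigarettes CC, heated tobacco THS,
e-cigarettes ECIG, nicotine replacement NRT, cessation CESS) and two risk
framings (P = personal, G = general).  Respondents may answer "don't know"
(file token ``DK``), which is treated as missing in all model-based
analyses but tallied separately in descriptives; a truly empty cell is
plain missing.

The canonical file format is a long CSV (RFC-4180, UTF-8, header row) with
columns: respondent_id, group, age_band, sex, education, object, framing,
position, item_id, response.  A wide convenience reader accepts one column
per item.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("riskscale")

DK_TOKEN = "DK"
N_CATEGORIES = 5

OBJECTS = ("CC", "THS", "ECIG", "NRT", "CESS")
GROUPS = ("CS_NIQ", "CS_IQ", "FS", "NS")
FRAMINGS = ("P", "G")

LONG_COLUMNS = [
    "respondent_id", "group", "age_band", "sex", "education",
    "object", "framing", "position", "item_id", "response",
]


@dataclass(frozen=True)
class ItemSpec:
    """One rating item: identity, scale membership and applicability."""

    item_id: str
    scale: str  # "health" | "addiction"
    label: str = ""
    n_categories: int = N_CATEGORIES
    applicable_objects: frozenset = frozenset(OBJECTS)

    def applies_to(self, obj: str) -> bool:
        return obj in self.applicable_objects


# Abbreviated item labels of the final instrument.  The health scale has 18
# items applicable to every object.  Of the 7 addiction items, three are
# administered for every object, three quit-phrased ones for every object
# except cessation, and one anxiety item for cessation only — hence a
# 4-item set for CESS and a 6-item set elsewhere.
_HEALTH_LABELS = [
    "Cough lasting for days", "Gum health", "Lung cancer", "Wheezing",
    "Mouth throat cancer", "Aging faster", "Minor illnesses",
    "Respiratory infection", "Serious illness", "Reduced stamina",
    "Emphysema", "Cough in the morning", "Sense of taste", "Heart disease",
    "Earlier death", "Sores mouth throat", "Unfit", "Other cancer",
]
_ADDICTION_ITEMS = [
    # (label, applicability)
    ("Being unable quit", frozenset(OBJECTS) - {"CESS"}),
    ("Feeling addicted", frozenset(OBJECTS)),
    ("To feel better", frozenset(OBJECTS)),
    ("Feeling like have to smoke", frozenset(OBJECTS)),
    ("Cannot stop", frozenset(OBJECTS) - {"CESS"}),
    ("Feeling unable quit", frozenset(OBJECTS) - {"CESS"}),
    ("Anxiety situation people smoke", frozenset({"CESS"})),
]


def default_instrument() -> list[ItemSpec]:
    """The 18-item health + 7-item addiction instrument."""
    items = [
        ItemSpec(item_id=f"H{i + 1:02d}", scale="health", label=lab)
        for i, lab in enumerate(_HEALTH_LABELS)
    ]
    items += [
        ItemSpec(item_id=f"A{i + 1}", scale="addiction", label=lab,
                 applicable_objects=app)
        for i, (lab, app) in enumerate(_ADDICTION_ITEMS)
    ]
    return items


def items_for(items: list[ItemSpec], scale: str, obj: str | None = None) -> list[ItemSpec]:
    """Applicable items of a scale, optionally restricted to one object."""
    sel = [it for it in items if it.scale == scale]
    if obj is not None:
        sel = [it for it in sel if it.applies_to(obj)]
    return sel


@dataclass
class ReadReport:
    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)


@dataclass
class ResponseDataset:
    """Validated long-format survey responses plus the item dictionary.

    ``df`` columns follow LONG_COLUMNS with ``response`` a nullable Int64
    (1..5; NA when missing) and a boolean ``dk`` column marking don't-know.
    """

    df: pd.DataFrame
    items: list[ItemSpec]
    read_report: ReadReport | None = None

    def item_map(self) -> dict[str, ItemSpec]:
        return {it.item_id: it for it in self.items}

    def write_csv(self, path) -> None:
        out = self.df.copy()
        resp = out["response"].astype(object)
        resp[out["dk"]] = DK_TOKEN
        resp[out["response"].isna() & ~out["dk"]] = ""
        out["response"] = resp
        out[LONG_COLUMNS].to_csv(path, index=False)


def _validate_records(df: pd.DataFrame, items: list[ItemSpec]) -> tuple[pd.DataFrame, ReadReport]:
    rep = ReadReport(n_read=len(df))
    imap = {it.item_id: it for it in items}

    bad_obj = ~df["object"].isin(OBJECTS)
    if bad_obj.any():
        raise ValueError(f"unknown object code(s): {sorted(df.loc[bad_obj, 'object'].unique())}")
    bad_fr = ~df["framing"].isin(FRAMINGS)
    if bad_fr.any():
        raise ValueError(f"unknown framing code(s): {sorted(df.loc[bad_fr, 'framing'].unique())}")

    raw = df["response"].astype(object)
    txt = raw.map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip())
    dk = txt.str.upper() == DK_TOKEN
    num = pd.to_numeric(txt.where(~dk, ""), errors="coerce")

    keep = np.ones(len(df), bool)
    malformed = (txt != "") & ~dk & (num.isna() | ~num.isin(range(1, N_CATEGORIES + 1)))
    for row in df.index[malformed]:
        rep.reasons.append(f"row {row}: malformed rating {txt[row]!r}")
    keep &= ~malformed.to_numpy()

    unknown_item = ~df["item_id"].isin(imap)
    for row in df.index[unknown_item]:
        rep.reasons.append(f"row {row}: unknown item_id {df.at[row, 'item_id']!r}")
    keep &= ~unknown_item.to_numpy()

    ok_rows = df.index[keep]
    inapplicable = pd.Series(False, index=df.index)
    inapplicable[ok_rows] = [
        not imap[df.at[r, "item_id"]].applies_to(df.at[r, "object"]) for r in ok_rows
    ]
    for row in df.index[inapplicable]:
        rep.reasons.append(
            f"row {row}: item {df.at[row, 'item_id']} not applicable to object {df.at[row, 'object']}"
        )
    keep &= ~inapplicable.to_numpy()

    out = df.loc[keep].copy()
    out["response"] = num[keep].astype("Int64")
    out["dk"] = dk[keep].to_numpy()
    out["position"] = out["position"].astype(int)

    dupes = out.duplicated(subset=["respondent_id", "object", "framing", "item_id"], keep=False)
    if dupes.any():
        raise ValueError(
            "duplicate (respondent, object, framing, item) records: "
            f"{out.loc[dupes, ['respondent_id', 'object', 'framing', 'item_id']].head().to_dict('records')}"
        )

    rep.n_kept = len(out)
    rep.n_rejected = rep.n_read - rep.n_kept
    if rep.n_rejected:
        logger.warning("rejected %d of %d records", rep.n_rejected, rep.n_read)
    return out.reset_index(drop=True), rep


def read_responses(path, fmt: str = "long", items: list[ItemSpec] | None = None) -> ResponseDataset:
    """Read and validate survey responses from CSV.

    ``fmt='long'`` expects the canonical columns; ``fmt='wide'`` expects the
    metadata columns plus one column per item_id.  Record-level problems
    (malformed ratings, unknown items, inapplicable object/item pairs) are
    rejected and listed in the read report; unknown object or framing codes
    are fatal.
    """
    if items is None:
        items = default_instrument()
    df = pd.read_csv(path, dtype={"respondent_id": str}, keep_default_na=False, na_values=[""])
    if fmt == "wide":
        meta = [c for c in LONG_COLUMNS if c not in ("item_id", "response")]
        item_cols = [c for c in df.columns if c not in meta]
        df = df.melt(id_vars=meta, value_vars=item_cols,
                     var_name="item_id", value_name="response")
    elif fmt != "long":
        raise ValueError(f"unknown format {fmt!r}")
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    clean, rep = _validate_records(df, items)
    return ResponseDataset(df=clean, items=items, read_report=rep)


@dataclass
class AnalysisMatrix:
    """Persons x items matrix (internal 0..m codes, -1 missing) + metadata."""

    data: np.ndarray  # int, (n_rows, n_items), MISSING = -1
    item_ids: list[str]
    row_meta: pd.DataFrame  # respondent_id, group, age_band, sex, education, object, framing, position
    dk_counts: np.ndarray  # per item
    n_dropped_empty: int = 0

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def missing_pct(self) -> np.ndarray:
        """Plain-missing percentage per item (don't-know counted separately)."""
        return 100.0 * ((self.data < 0).sum(axis=0) - self.dk_counts) / max(self.n_rows, 1)

    def dk_pct(self) -> np.ndarray:
        return 100.0 * self.dk_counts / max(self.n_rows, 1)


def to_analysis_matrix(
    ds: ResponseDataset,
    scale: str,
    obj: str | None = None,
    framing: str | None = None,
) -> AnalysisMatrix:
    """Pivot a dataset selection to a persons x items analysis matrix.

    ``obj=None`` / ``framing=None`` stack every object / framing, one row
    per (respondent, object, framing) — repeated assessments enter as
    separate measurement rows, as in a racked repeated-measures analysis.
    Don't-know responses become missing for modelling; rows with every item
    missing are dropped (count logged and recorded).
    """
    sel_items = items_for(ds.items, scale, obj)
    if not sel_items:
        raise ValueError(f"no applicable items for scale={scale!r}, object={obj!r}")
    ids = [it.item_id for it in sel_items]

    df = ds.df[ds.df["item_id"].isin(ids)]
    if obj is not None:
        df = df[df["object"] == obj]
    if framing is not None:
        df = df[df["framing"] == framing]
    if df.empty:
        raise ValueError(
            f"empty selection: scale={scale!r}, object={obj!r}, framing={framing!r}")

    key = ["respondent_id", "object", "framing"]
    wide_val = df.pivot_table(index=key, columns="item_id", values="response",
                              aggfunc="first", observed=True)
    wide_dk = df.assign(dkv=df["dk"].astype(float)).pivot_table(
        index=key, columns="item_id", values="dkv", aggfunc="first", observed=True)
    for c in ids:
        if c not in wide_val.columns:
            wide_val[c] = np.nan
        if c not in wide_dk.columns:
            wide_dk[c] = np.nan
    wide_val = wide_val[ids]
    wide_dk = wide_dk[ids].fillna(0.0).astype(bool)

    vals = wide_val.to_numpy(dtype=float)
    mat = np.where(np.isnan(vals), -1, vals - 1).astype(np.int64)  # 1..5 -> 0..4

    empty = (mat < 0).all(axis=1)
    n_dropped = int(empty.sum())
    if n_dropped:
        logger.info("dropped %d all-missing measurement rows", n_dropped)
    mat = mat[~empty]
    dk_mat = wide_dk.to_numpy()[~empty]

    meta_cols = ["group", "age_band", "sex", "education", "position"]
    meta = (df.drop_duplicates(subset=key)
              .set_index(key)[[c for c in meta_cols if c in df.columns]])
    meta = meta.loc[wide_val.index[~empty]].reset_index()

    return AnalysisMatrix(
        data=mat,
        item_ids=ids,
        row_meta=meta,
        dk_counts=dk_mat.sum(axis=0),
        n_dropped_empty=n_dropped,
    )


def missing_summary(am: AnalysisMatrix) -> pd.DataFrame:
    """Per-item missing% and don't-know% with the <10% data-quality flag."""
    if am.n_rows == 0:
        raise ValueError("empty analysis matrix")
    miss = am.missing_pct()
    dk = am.dk_pct()
    return pd.DataFrame({
        "item_id": am.item_ids,
        "missing_pct": miss,
        "dk_pct": dk,
        "valid_pct": 100.0 - miss - dk,
        "flag_missing": miss >= 10.0,
    })
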