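"""Tri-state signatures, pathology groups, and combination tables.

Each lesion's four z-scores are discretized to LOW / NORMAL / HIGH at a
symmetric threshold (default 2, boundary inclusive on the NORMAL side).
The resulting 3^4 = 81 possible signatures partition into pathology groups:

  Group 1  all contrasts NORMAL (no significant change)
  Group 2  isolated T2 and/or T2* increase (T1, MTR NORMAL)
  Group 3  T1 increase with MTR NORMAL (T2/T2* normal or increased)
  Group 4  T1 increase with MTR decrease (T2/T2* normal or increased)
  OTHER    everything else (any T1/T2/T2* decrease, MTR increase, ...)
"""

from __future__ import annotations

import itertools
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mclesion.core import (
    CONTRASTS,
    LESION_CORTICAL_I,
    LESION_CORTICAL_II,
    LESION_WM,
)
from mclesion.lesions import Lesion, ZScoreVector

LOW, NORMAL, HIGH = "LOW", "NORMAL", "HIGH"
STATES = (LOW, NORMAL, HIGH)
OTHER = "OTHER"

_STATE_CODE = {LOW: "L", NORMAL: "N", HIGH: "H"}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}

#: Compartment columns of the combination table: brain hemispheres
#: (WM, cortical type I, cortical type II) then cerebellum (WM, mixed
#: GM/WM, pure GM).
COUNT_COLUMNS = ("brain_wm", "brain_ct1", "brain_ct2", "cb_wm", "cb_gmwm", "cb_gm")
CORTICAL_COLUMNS = ("brain_ct1", "brain_ct2", "cb_gmwm", "cb_gm")
WM_COLUMNS = ("brain_wm", "cb_wm")

Signature = tuple[str, str, str, str]  # states in CONTRASTS order


def signature(z: ZScoreVector | Mapping[str, float], threshold: float = 2.0) -> Signature:
    """Discretize a z-score vector; |z| == threshold counts as NORMAL."""
    states = []
    for c in CONTRASTS:
        zc = float(z[c])
        if not np.isfinite(zc):
            raise ValueError(f"non-finite z-score for {c}")
        if zc > threshold:
            states.append(HIGH)
        elif zc < -threshold:
            states.append(LOW)
        else:
            states.append(NORMAL)
    return tuple(states)  # type: ignore[return-value]


def signature_code(sig: Signature) -> str:
    """Compact 4-letter code, contrasts in T1, T2, T2*, MTR order."""
    return "".join(_STATE_CODE[s] for s in sig)


def signature_from_code(code: str) -> Signature:
    if len(code) != 4 or any(ch not in _CODE_STATE for ch in code):
        raise ValueError(f"bad signature code {code!r}")
    return tuple(_CODE_STATE[ch] for ch in code)  # type: ignore[return-value]


def all_signatures() -> list[Signature]:
    return [tuple(s) for s in itertools.product(STATES, repeat=4)]  # type: ignore[misc]


def assign_group(sig: Signature) -> int | str:
    """Map a signature to pathology group 1-4 or OTHER.

    Rules are applied in order and are mutually exclusive by construction.
    """
    t1, t2, t2s, mtr = sig
    inflam_ok = t2 in (NORMAL, HIGH) and t2s in (NORMAL, HIGH)
    if t1 == HIGH and mtr == LOW and inflam_ok:
        return 4
    if t1 == HIGH and mtr == NORMAL and inflam_ok:
        return 3
    if t1 == NORMAL and mtr == NORMAL and inflam_ok and (t2 == HIGH or t2s == HIGH):
        return 2
    if sig == (NORMAL, NORMAL, NORMAL, NORMAL):
        return 1
    return OTHER


def _group_key(group: int | str) -> int:
    return 5 if group == OTHER else int(group)


def compartment_column(lobe: str, tissue_type: str) -> str:
    """Combination-table column for a lesion's (lobe, tissue type)."""
    cerebellar = lobe == "cerebellum"
    if tissue_type == LESION_WM:
        return "cb_wm" if cerebellar else "brain_wm"
    if tissue_type == LESION_CORTICAL_I:
        return "cb_gmwm" if cerebellar else "brain_ct1"
    if tissue_type == LESION_CORTICAL_II:
        return "cb_gm" if cerebellar else "brain_ct2"
    raise ValueError(f"unknown tissue type {tissue_type!r}")


def lesion_records(
    subject_id: str,
    lesions: Iterable[Lesion],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """One row per signed lesion: subject, signature code, group, column, volume."""
    rows = []
    for les in lesions:
        if les.zscores is None:
            raise ValueError(f"lesion {les.id} has no z-scores")
        sig = signature(les.zscores, threshold=threshold)
        rows.append({
            "subject": subject_id,
            "lesion_id": les.id,
            "code": signature_code(sig),
            "group": assign_group(sig),
            "column": compartment_column(les.lobe, les.tissue_type),
            "normalized_volume": les.normalized_volume,
        })
    return pd.DataFrame(
        rows, columns=["subject", "lesion_id", "code", "group", "column", "normalized_volume"]
    )


def enumerate_combinations(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled combination table: one row per observed signature.

    Rows are ordered by group (1..4 then OTHER) and then lexicographically
    by signature code; ``ordinal`` is a 1-based display index in that order.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["ordinal", "code", "group", "count", *COUNT_COLUMNS,
                     "total_normalized_volume", "mlv"]
        )
    rows = []
    for code, sub in records.groupby("code"):
        row: dict[str, object] = {
            "code": code,
            "group": assign_group(signature_from_code(code)),
            "count": len(sub),
            "total_normalized_volume": float(sub["normalized_volume"].sum()),
        }
        for col in COUNT_COLUMNS:
            row[col] = int((sub["column"] == col).sum())
        row["mlv"] = row["total_normalized_volume"] / row["count"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["group", "code"], key=lambda s: s.map(_group_key) if s.name == "group" else s
    ).reset_index(drop=True)
    table.insert(0, "ordinal", np.arange(1, len(table) + 1))
    return table[["ordinal", "code", "group", "count", *COUNT_COLUMNS,
                  "total_normalized_volume", "mlv"]]


def mlv(total_normalized_volume: float, count: int) -> float:
    """Mean lesion volume: total normalized volume over lesion count."""
    if count < 1:
        raise ValueError("mlv undefined for an empty combination")
    return total_normalized_volume / count


def subject_predictor_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject MLV per observed signature (missing combinations -> 0).

    Rows: subjects; columns: signature codes observed anywhere in the
    cohort, in the pooled table's deterministic order.
    """
    pooled = enumerate_combinations(records)
    codes = list(pooled["code"])
    subjects = sorted(records["subject"].unique())
    mat = pd.DataFrame(0.0, index=pd.Index(subjects, name="subject"), columns=codes)
    for (subject, code), sub in records.groupby(["subject", "code"]):
        mat.loc[subject, code] = mlv(float(sub["normalized_volume"].sum()), len(sub))
    return mat


# ---------------------------------------------------------------------------
# Count-table summaries
# ---------------------------------------------------------------------------

def load_reference_counts() -> pd.DataFrame:
    """Bundled cross-tabulation of lesion counts by combination ordinal and
    compartment, used by the summary-statistic checks."""
    with resources.files("mclesion.data").joinpath("combination_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="combination")


def count_summary(counts: pd.DataFrame) -> dict[str, float]:
    """Column totals, grand total, and derived percentages of a count table.

    Percentage values are reported on the 0-100 scale; the per-column
    percentage row is rounded to two decimals.
    """
    totals = counts[list(COUNT_COLUMNS)].sum()
    grand = int(totals.sum())
    if grand == 0:
        raise ValueError("empty count table")
    out: dict[str, float] = {f"total_{c}": int(totals[c]) for c in COUNT_COLUMNS}
    out["grand_total"] = grand
    for c in COUNT_COLUMNS:
        out[f"pct_{c}"] = round(100.0 * totals[c] / grand, 2)
    out["cortical_pct"] = 100.0 * sum(totals[c] for c in CORTICAL_COLUMNS) / grand
    out["wm_pct"] = 100.0 * sum(totals[c] for c in WM_COLUMNS) / grand
    return out


def row_summary(counts: pd.DataFrame, combination: int) -> dict[str, float]:
    """Share and cortical/WM split of one combination row of a count table."""
    row = counts.loc[combination, list(COUNT_COLUMNS)]
    row_total = int(row.sum())
    if row_total == 0:
        raise ValueError(f"combination {combination} has no lesions")
    grand = int(counts[list(COUNT_COLUMNS)].to_numpy().sum())
    return {
        "row_total": row_total,
        "share_pct": 100.0 * row_total / grand,
        "cortical_pct": 100.0 * sum(row[c] for c in CORTICAL_COLUMNS) / row_total,
        "wm_pct": 100.0 * sum(row[c] for c in WM_COLUMNS) / row_total,
    }
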