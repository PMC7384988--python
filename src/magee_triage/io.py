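"""CSV input/output for case tables.

One canonical column contract (case-insensitive, order-free headers):

========================  =======================================================
column                    meaning
========================  =======================================================
case_id                   any identifier (optional; row number used if absent)
tumor_size                invasive size in cm
nottingham_score          grading sum 3–9
mitosis_score             mitotic-activity component 1–3
er_h_score, pr_h_score    IHC H-scores 0–300
her2_status               negative / equivocal / positive (or IHC 0/1+/2+/3+
                          with a her2_fish_copies column for 2+ cases)
ki67_index                percent; "15" and "15%" both accepted
age, nodal_status         optional clinical annotations
actual_rs                 assay recurrence score 0–100 (optional)
therapy                   endocrine_only / chemo_endocrine / chemo_only /
                          none / unknown (optional)
followup_months           follow-up in months (optional)
distant_recurrence        true/false (optional)
death                     none / breast_cancer / other (optional)
histologic_type           free-text pass-through (optional)
========================  =======================================================
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .records import CaseRecord, DeathCause, NodalStatus, Therapy
from .scoring import HER2Status, categorize_her2

__all__ = ["SchemaError", "RowError", "read_cases", "write_cases", "CASE_COLUMNS"]

MANDATORY_COLUMNS = (
    "tumor_size",
    "nottingham_score",
    "mitosis_score",
    "er_h_score",
    "pr_h_score",
    "her2_status",
    "ki67_index",
)

CASE_COLUMNS = MANDATORY_COLUMNS + (
    "case_id",
    "age",
    "nodal_status",
    "actual_rs",
    "therapy",
    "followup_months",
    "distant_recurrence",
    "death",
    "histologic_type",
)


class SchemaError(ValueError):
    """The file does not match the column contract."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based data-row line number in the file (header is line 1)
    case_id: object
    message: str


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def _parse_float(v, name: str) -> Optional[float]:
    if _is_missing(v):
        return None
    s = str(v).strip().rstrip("%")
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable {name}: {v!r}") from exc


def _parse_int(v, name: str) -> Optional[int]:
    f = _parse_float(v, name)
    if f is None:
        return None
    if f != int(f):
        raise ValueError(f"{name} must be an integer, got {v!r}")
    return int(f)


def _parse_bool(v, name: str) -> Optional[bool]:
    if _is_missing(v):
        return None
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t", "1.0"}:
        return True
    if s in {"false", "0", "no", "f", "0.0"}:
        return False
    raise ValueError(f"unparseable {name}: {v!r}")


def _parse_her2(value, fish) -> Optional[HER2Status]:
    if _is_missing(value):
        return None
    s = str(value).strip().lower()
    if s in {st.value for st in HER2Status}:
        return HER2Status(s)
    return categorize_her2(s, None if _is_missing(fish) else float(fish))


def read_cases(path: str | Path, on_error: str = "fail") -> tuple[list[CaseRecord], list[RowError]]:
    """Read a case table; returns (records, row_errors).

    Headers are matched case-insensitively and in any order.  A missing
    mandatory column raises :class:`SchemaError` naming it.  Cell-level
    failures follow ``on_error``: ``'fail'`` raises on the first bad row,
    ``'skip'`` collects :class:`RowError` objects (with line numbers) and
    drops the rows.
    """
    if on_error not in {"fail", "skip"}:
        raise ValueError("on_error must be 'fail' or 'skip'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[CaseRecord] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        get = lambda col: row[col] if col in df.columns else None
        cid = get("case_id")
        cid = f"row{idx + 1}" if _is_missing(cid) else str(cid).strip()
        try:
            record = CaseRecord(
                case_id=cid,
                tumor_size=_parse_float(get("tumor_size"), "tumor_size"),
                nottingham_score=_parse_int(get("nottingham_score"), "nottingham_score"),
                mitosis_score=_parse_int(get("mitosis_score"), "mitosis_score"),
                er_h_score=_parse_float(get("er_h_score"), "er_h_score"),
                pr_h_score=_parse_float(get("pr_h_score"), "pr_h_score"),
                her2_status=_parse_her2(get("her2_status"), get("her2_fish_copies")),
                ki67_index=_parse_float(get("ki67_index"), "ki67_index"),
                age=_parse_float(get("age"), "age"),
                nodal_status=None if _is_missing(get("nodal_status"))
                else NodalStatus(str(get("nodal_status")).strip().lower()),
                actual_rs=_parse_float(get("actual_rs"), "actual_rs"),
                therapy=None if _is_missing(get("therapy"))
                else Therapy(str(get("therapy")).strip().lower()),
                followup_months=_parse_float(get("followup_months"), "followup_months"),
                distant_recurrence=_parse_bool(get("distant_recurrence"), "distant_recurrence"),
                death=None if _is_missing(get("death"))
                else DeathCause(str(get("death")).strip().lower()),
                histologic_type=None if _is_missing(get("histologic_type"))
                else str(get("histologic_type")),
            )
        except (ValueError, KeyError) as exc:
            err = RowError(line=int(idx) + 2, case_id=cid, message=str(exc))
            if on_error == "fail":
                raise SchemaError(f"line {err.line} (case {cid!r}): {exc}") from exc
            errors.append(err)
            continue
        records.append(record)
    return records, errors


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    rows = []
    for r in cases:
        rows.append({
            "case_id": r.case_id,
            "tumor_size": r.tumor_size,
            "nottingham_score": r.nottingham_score,
            "mitosis_score": r.mitosis_score,
            "er_h_score": r.er_h_score,
            "pr_h_score": r.pr_h_score,
            "her2_status": r.her2_status.value if r.her2_status else None,
            "ki67_index": r.ki67_index,
            "age": r.age,
            "nodal_status": r.nodal_status.value if r.nodal_status else None,
            "actual_rs": r.actual_rs,
            "therapy": r.therapy.value if r.therapy else None,
            "followup_months": r.followup_months,
            "distant_recurrence": r.distant_recurrence,
            "death": r.death.value if r.death else None,
            "histologic_type": r.histologic_type,
        })
    return pd.DataFrame(rows, columns=list(dict.fromkeys(
        ("case_id",) + MANDATORY_COLUMNS + (
            "age", "nodal_status", "actual_rs", "therapy",
            "followup_months", "distant_recurrence", "death", "histologic_type",
        )
    )))


def write_cases(cases: Sequence[CaseRecord], path: str | Path) -> None:
    """Write a case table in the canonical column contract (RFC-4180 CSV)."""
    cases_to_frame(cases).to_csv(path, index=False)
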