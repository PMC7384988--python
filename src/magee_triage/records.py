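"""Case-level record types shared across the pipeline."""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

from .scoring import HER2Status, PathologyInput

__all__ = ["NodalStatus", "Therapy", "DeathCause", "CaseRecord"]


class NodalStatus(str, enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    ITC = "itc"  # isolated tumor cells
    UNKNOWN = "unknown"


class Therapy(str, enum.Enum):
    ENDOCRINE_ONLY = "endocrine_only"
    CHEMO_ENDOCRINE = "chemo_endocrine"
    CHEMO_ONLY = "chemo_only"
    NONE = "none"
    UNKNOWN = "unknown"


class DeathCause(str, enum.Enum):
    NONE = "none"
    BREAST_CANCER = "breast_cancer"
    OTHER = "other"


@dataclass(frozen=True)
class CaseRecord:
    """One patient/tumor: pathology variables plus clinical annotations.

    ``actual_rs`` is the Oncotype DX recurrence score (0–100) when the
    assay was run; follow-up fields support distant-recurrence-free
    survival analysis.  ``histologic_type`` is an optional pass-through
    annotation not used by any computation.
    """

    case_id: object
    tumor_size: Optional[float] = None
    nottingham_score: Optional[int] = None
    mitosis_score: Optional[int] = None
    er_h_score: Optional[float] = None
    pr_h_score: Optional[float] = None
    her2_status: Optional[HER2Status] = None
    ki67_index: Optional[float] = None
    age: Optional[float] = None
    nodal_status: Optional[NodalStatus] = None
    actual_rs: Optional[float] = None
    therapy: Optional[Therapy] = None
    followup_months: Optional[float] = None
    distant_recurrence: Optional[bool] = None
    death: Optional[DeathCause] = None
    histologic_type: Optional[str] = None

    def __post_init__(self) -> None:
        # pathology ranges are validated by PathologyInput; build it eagerly
        self.pathology_input()
        if self.actual_rs is not None and not 0 <= self.actual_rs <= 100:
            raise ValueError(f"actual_rs must be in [0, 100], got {self.actual_rs}")
        if self.followup_months is not None and self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if (self.distant_recurrence is not None or (self.death not in (None, DeathCause.NONE))) and self.followup_months is None:
            raise ValueError(
                f"case {self.case_id!r}: follow-up time required when outcome fields are present"
            )
        for name, cls in (("nodal_status", NodalStatus), ("therapy", Therapy), ("death", DeathCause)):
            v = getattr(self, name)
            if v is not None and not isinstance(v, cls):
                object.__setattr__(self, name, cls(str(v)))

    def pathology_input(self) -> PathologyInput:
        return PathologyInput(
            tumor_size=self.tumor_size,
            nottingham_score=self.nottingham_score,
            mitosis_score=self.mitosis_score,
            er_h_score=self.er_h_score,
            pr_h_score=self.pr_h_score,
            her2_status=self.her2_status,
            ki67_index=self.ki67_index,
        )

    @property
    def grade(self) -> Optional[int]:
        """Nottingham grade I/II/III from the score (3–5 / 6–7 / 8–9)."""
        if self.nottingham_score is None:
            return None
        return 1 if self.nottingham_score <= 5 else (2 if self.nottingham_score <= 7 else 3)

    @property
    def pr_positive(self) -> Optional[bool]:
        """PR positivity at the conventional H-score >= 10 cutoff."""
        if self.pr_h_score is None:
            return None
        return self.pr_h_score >= 10

    def with_fields(self, **kwargs) -> "CaseRecord":
        return replace(self, **kwargs)
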