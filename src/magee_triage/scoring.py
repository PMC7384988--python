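"""Magee Equation scoring.

The Magee Equations are published linear models that estimate the Oncotype
DX recurrence score from routinely reported pathology and biomarker
variables.  Three equations are in clinical use:

* **ME1** uses tumor size, Nottingham score, ER H-score, PR H-score, HER2
  status and the Ki-67 labeling index;
* **ME2** uses the same variables except Ki-67;
* **ME3** uses only the four biomarker variables (ER, PR, HER2, Ki-67).

Each score is ``intercept + sum(coefficient * variable) + HER2 offset``,
where the offset depends on the HER2 category (negative / equivocal /
positive; the negative offset is 0 by construction).  Scores are clamped
below at 0 — the recurrence-score scale is non-negative — and reported to
one decimal, rounding ties away from zero, matching the display
granularity of the public calculator.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = [
    "HER2Status",
    "PathologyInput",
    "MageeCoefficientSet",
    "MageeScores",
    "UnresolvedHER2Error",
    "categorize_her2",
    "compute_magee_scores",
    "load_coefficients",
    "round_score",
]


class UnresolvedHER2Error(ValueError):
    """HER2 IHC 2+ without in-situ-hybridization copy number: case cannot be scored."""


class HER2Status(str, enum.Enum):
    NEGATIVE = "negative"
    EQUIVOCAL = "equivocal"
    POSITIVE = "positive"


def round_score(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the published calculator).

    Python's builtin ``round`` is banker's rounding; Decimal ROUND_HALF_UP
    rounds ties away from zero, which is what score displays use.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def categorize_her2(ihc_score: str, fish_copies: Optional[float] = None) -> HER2Status:
    """Map a HER2 IHC score (with FISH copy number for 2+ cases) to a category.

    0/1+ are negative and 3+ positive regardless of FISH.  IHC 2+ cases are
    resolved by HER2 copies per cell: <4 negative, 4 to <6 equivocal,
    >=6 positive.  A 2+ case without a copy number cannot be scored.
    """
    ihc = str(ihc_score).strip()
    if ihc in {"0", "1+", "1"}:
        return HER2Status.NEGATIVE
    if ihc in {"3+", "3"}:
        return HER2Status.POSITIVE
    if ihc in {"2+", "2"}:
        if fish_copies is None:
            raise UnresolvedHER2Error(
                "HER2 IHC 2+ requires a FISH copy number to resolve the category"
            )
        copies = float(fish_copies)
        if copies < 4:
            return HER2Status.NEGATIVE
        if copies < 6:
            return HER2Status.EQUIVOCAL
        return HER2Status.POSITIVE
    raise ValueError(f"invalid HER2 IHC score {ihc_score!r}; expected 0, 1+, 2+ or 3+")


@dataclass(frozen=True)
class PathologyInput:
    """Pathology variables needed to compute Magee Equation scores.

    Optional fields left ``None`` mark a variable as unavailable; equations
    that require it are then flagged unavailable rather than computed.

    Parameters
    ----------
    tumor_size : float, optional
        Invasive tumor size in cm (> 0).
    nottingham_score : int, optional
        Nottingham grading sum, 3–9 (tubule formation + nuclear
        pleomorphism + mitotic activity, each 1–3).
    mitosis_score : int, optional
        The mitotic-activity component, 1–3.  Not used by the equations
        themselves but required by the decision algorithm for mid-band
        scores.
    er_h_score, pr_h_score : float, optional
        Immunohistochemistry H-scores, 0–300.
    her2_status : HER2Status or str, optional
        negative / equivocal / positive (see :func:`categorize_her2`).
    ki67_index : float, optional
        Ki-67 labeling index in percent, 0–100.  Accepted as a real number
        because the index is usually an estimate.
    """

    tumor_size: Optional[float] = None
    nottingham_score: Optional[int] = None
    mitosis_score: Optional[int] = None
    er_h_score: Optional[float] = None
    pr_h_score: Optional[float] = None
    her2_status: Optional[HER2Status] = None
    ki67_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tumor_size is not None and not self.tumor_size > 0:
            raise ValueError(f"tumor_size must be > 0 cm, got {self.tumor_size}")
        if self.nottingham_score is not None and not 3 <= self.nottingham_score <= 9:
            raise ValueError(
                f"nottingham_score must be in [3, 9], got {self.nottingham_score}"
            )
        if self.mitosis_score is not None:
            if not 1 <= self.mitosis_score <= 3:
                raise ValueError(
                    f"mitosis_score must be in [1, 3], got {self.mitosis_score}"
                )
            if (
                self.nottingham_score is not None
                and self.mitosis_score > self.nottingham_score - 2
            ):
                # the other two Nottingham components are each at least 1
                raise ValueError(
                    f"mitosis_score {self.mitosis_score} inconsistent with "
                    f"nottingham_score {self.nottingham_score}"
                )
        for name in ("er_h_score", "pr_h_score"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 300:
                raise ValueError(f"{name} must be in [0, 300], got {v}")
        if self.ki67_index is not None and not 0 <= self.ki67_index <= 100:
            raise ValueError(f"ki67_index must be in [0, 100], got {self.ki67_index}")
        if self.her2_status is not None and not isinstance(self.her2_status, HER2Status):
            object.__setattr__(self, "her2_status", HER2Status(str(self.her2_status)))


# which continuous variables each equation uses, in a fixed order
_EQUATION_VARIABLES: Mapping[str, tuple[str, ...]] = {
    "me1": ("nottingham_score", "er_h_score", "pr_h_score", "tumor_size", "ki67_index"),
    "me2": ("nottingham_score", "er_h_score", "pr_h_score", "tumor_size"),
    "me3": ("er_h_score", "pr_h_score", "ki67_index"),
}


@dataclass(frozen=True)
class MageeCoefficientSet:
    """Intercepts, per-variable coefficients and HER2 offsets for ME1–ME3.

    ``equations`` maps ``"me1"``/``"me2"``/``"me3"`` to
    ``{"intercept": float, <variable>: float, ..., "her2": {category: offset}}``.
    Validated so that each equation carries exactly the variables it is
    defined on and the negative-HER2 offset is 0.
    """

    equations: Mapping[str, Mapping[str, object]]

    def __post_init__(self) -> None:
        missing = set(_EQUATION_VARIABLES) - set(self.equations)
        if missing:
            raise ValueError(f"coefficient set missing equations: {sorted(missing)}")
        for eq, allowed in _EQUATION_VARIABLES.items():
            block = dict(self.equations[eq])
            if "intercept" not in block:
                raise ValueError(f"{eq}: missing intercept")
            her2 = block.get("her2")
            if not isinstance(her2, Mapping):
                raise ValueError(f"{eq}: missing her2 offset block")
            offsets = {str(k): float(v) for k, v in her2.items()}
            if set(offsets) != {s.value for s in HER2Status}:
                raise ValueError(f"{eq}: her2 offsets must cover negative/equivocal/positive")
            if offsets["negative"] != 0.0:
                raise ValueError(f"{eq}: her2 offset for negative must be 0")
            extra = set(block) - {"intercept", "her2"} - set(allowed)
            if extra:
                raise ValueError(f"{eq}: unexpected variables {sorted(extra)}")
            absent = set(allowed) - set(block)
            if absent:
                raise ValueError(f"{eq}: missing coefficients for {sorted(absent)}")

    def variables(self, equation: str) -> tuple[str, ...]:
        return _EQUATION_VARIABLES[equation]

    def evaluate(self, equation: str, values: Mapping[str, float], her2: HER2Status) -> float:
        """Raw (unrounded, unclamped) linear-combination value of one equation."""
        block = self.equations[equation]
        total = float(block["intercept"])
        for var in _EQUATION_VARIABLES[equation]:
            total += float(block[var]) * float(values[var])
        total += float(block["her2"][her2.value])
        return total


def load_coefficients(path: Optional[str | Path] = None) -> MageeCoefficientSet:
    """Load a coefficient set from YAML; defaults to the shipped set.

    The shipped defaults are the 2013 published revision of the equations,
    which reproduce the reference worked example (scores 21.5 / 21.7 /
    20.6 for a 2.0 cm, Nottingham 6, ER 300 / PR 0, HER2-negative,
    Ki-67 15% tumor).
    """
    if path is None:
        text = (resources.files("magee_triage") / "data" / "coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError("coefficient file must be a mapping of equations")
    return MageeCoefficientSet(equations={str(k): dict(v) for k, v in raw.items()})


_DEFAULT_COEFFS: Optional[MageeCoefficientSet] = None


def default_coefficients() -> MageeCoefficientSet:
    global _DEFAULT_COEFFS
    if _DEFAULT_COEFFS is None:
        _DEFAULT_COEFFS = load_coefficients()
    return _DEFAULT_COEFFS


@dataclass(frozen=True)
class MageeScores:
    """The three Magee Equation scores for one case, plus their mean.

    ``me1``/``me2``/``me3``/``mean_score`` are the reported one-decimal
    values (``None`` when an equation's required variable was missing).
    ``raw`` holds the unrounded (but zero-clamped) values for internal use
    such as latent-score simulation.
    """

    me1: Optional[float]
    me2: Optional[float]
    me3: Optional[float]
    mean_score: Optional[float]
    raw: tuple[Optional[float], Optional[float], Optional[float]] = field(
        default=(None, None, None), repr=False, compare=False
    )

    @property
    def raw_mean(self) -> Optional[float]:
        if any(v is None for v in self.raw):
            return None
        return sum(self.raw) / 3.0

    def available(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("me1", "me2", "me3") if getattr(self, name) is not None
        )


def compute_magee_scores(
    pathology: PathologyInput,
    coefficients: Optional[MageeCoefficientSet] = None,
) -> MageeScores:
    """Compute ME1, ME2 and ME3 (and their mean) for one case.

    Each equation whose required variables are all present yields
    ``max(0, linear value)`` rounded to one decimal; equations with a
    missing variable are flagged unavailable (``None``).  ``mean_score``
    is the mean of the three *unrounded* values, rounded to one decimal,
    and is only available when all three equations are.
    """
    coeffs = coefficients if coefficients is not None else default_coefficients()
    if pathology.her2_status is None:
        raise ValueError("her2_status is required for every Magee Equation")
    raw: dict[str, Optional[float]] = {}
    for eq in ("me1", "me2", "me3"):
        needed = coeffs.variables(eq)
        values = {v: getattr(pathology, v) for v in needed}
        if any(v is None for v in values.values()):
            raw[eq] = None
            continue
        raw[eq] = max(0.0, coeffs.evaluate(eq, values, pathology.her2_status))
    rounded = {
        eq: (round_score(v) if v is not None else None) for eq, v in raw.items()
    }
    raw_tuple = (raw["me1"], raw["me2"], raw["me3"])
    if all(v is not None for v in raw_tuple):
        mean = round_score(math.fsum(raw_tuple) / 3.0)
    else:
        mean = None
    return MageeScores(
        me1=rounded["me1"],
        me2=rounded["me2"],
        me3=rounded["me3"],
        mean_score=mean,
        raw=raw_tuple,
    )
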