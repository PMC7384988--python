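"""Magee Decision Algorithm: triage away from molecular testing.

The rule classifies an ER+/HER2-negative case by where its Magee Equation
scores fall relative to the historical Oncotype risk bands:

* L: score < 18
* M: 18 <= score <= 25
* S: 25 < score < 31
* H: score >= 31

If every used score is < 18, or every used score is <= 25 with a mitotic
activity score of 1, testing is not needed and the actual recurrence score
is expected to be <= 25 (``do_not_send_expect_low``).  If every used score
is >= 31, testing is also not needed — the actual score is expected to be
> 25 (``do_not_send_expect_high``).  Any score in the 25–31 window, or a
mid-band (18–25) score with mitosis > 1, sends the case for testing
(``send``).  Bands are computed on the one-decimal reported scores, so the
labels match what a user reading the public calculator's display would
decide.

Variants using a single equation or the average score are supported for
sensitivity comparison; the all-equations rule is the published default.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .scoring import MageeScores

__all__ = [
    "Band",
    "Thresholds",
    "TriageLabel",
    "Variant",
    "TriageResult",
    "CohortTriage",
    "TriageUnavailableError",
    "MitosisRequiredError",
    "score_band",
    "triage",
    "triage_cohort",
]


@dataclass(frozen=True)
class Thresholds:
    """Band edges and mitosis cutoff; defaults are the published rule.

    ``low``/``mid``/``high`` bound the bands (L: < low; M: [low, mid];
    S: (mid, high); H: >= high); a mitosis score <= ``mitosis_cutoff``
    lets a mid-band case forgo testing.
    """

    low: float = 18.0
    mid: float = 25.0
    high: float = 31.0
    mitosis_cutoff: int = 1

    def __post_init__(self) -> None:
        if not self.low < self.mid < self.high:
            raise ValueError("thresholds must be strictly increasing")
        if self.mitosis_cutoff not in (1, 2):
            raise ValueError("mitosis_cutoff must be 1 or 2")


DEFAULT_THRESHOLDS = Thresholds()


class TriageUnavailableError(ValueError):
    """A score required by the chosen variant is unavailable."""


class MitosisRequiredError(ValueError):
    """Mid-band scores need the mitotic activity score to decide, and it is missing."""


class Band(str, enum.Enum):
    L = "L"  # < 18
    M = "M"  # 18–25 inclusive
    S = "S"  # > 25 and < 31
    H = "H"  # >= 31


class TriageLabel(str, enum.Enum):
    DO_NOT_SEND_EXPECT_LOW = "do_not_send_expect_low"
    DO_NOT_SEND_EXPECT_HIGH = "do_not_send_expect_high"
    SEND = "send"


class Variant(str, enum.Enum):
    ALL_EQUATIONS = "all_equations"
    ME1_ONLY = "me1_only"
    ME2_ONLY = "me2_only"
    ME3_ONLY = "me3_only"
    AVERAGE = "average"


_VARIANT_SCORES: Mapping[Variant, tuple[str, ...]] = {
    Variant.ALL_EQUATIONS: ("me1", "me2", "me3"),
    Variant.ME1_ONLY: ("me1",),
    Variant.ME2_ONLY: ("me2",),
    Variant.ME3_ONLY: ("me3",),
    Variant.AVERAGE: ("mean_score",),
}

# short CLI spellings
_VARIANT_ALIASES = {
    "all": Variant.ALL_EQUATIONS,
    "me1": Variant.ME1_ONLY,
    "me2": Variant.ME2_ONLY,
    "me3": Variant.ME3_ONLY,
    "avg": Variant.AVERAGE,
}


def coerce_variant(value: str | Variant) -> Variant:
    if isinstance(value, Variant):
        return value
    v = str(value).strip().lower()
    if v in _VARIANT_ALIASES:
        return _VARIANT_ALIASES[v]
    return Variant(v)


def score_band(score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> Band:
    """Band of a one-decimal reported score (edges: 18 and 25 closed, 31 closed below)."""
    if score < thresholds.low:
        return Band.L
    if score <= thresholds.mid:
        return Band.M
    if score < thresholds.high:
        return Band.S
    return Band.H


@dataclass(frozen=True)
class TriageResult:
    """The algorithm's label for one case under one variant.

    ``bands`` records the band of each used score; ``mitosis_used`` is True
    exactly when the mitotic activity score decided the outcome (at least
    one used score mid-band, none above).
    """

    label: TriageLabel
    variant: Variant
    bands: Mapping[str, Band]
    mitosis_used: bool
    unclassified_by_rule: bool = False  # L/H mixture: conservative fallback applied


def triage(
    scores: MageeScores,
    mitosis_score: Optional[int] = None,
    variant: str | Variant = Variant.ALL_EQUATIONS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> TriageResult:
    """Apply the decision algorithm to one case.

    Decision order: (1) every used score >= 31 -> do-not-send-expect-high;
    (2) any score in the open 25–31 window -> send; (3) any score mid-band
    (18–25): mitosis 1 -> do-not-send-expect-low, otherwise send; (4) all
    scores < 18 -> do-not-send-expect-low; (5) the residual mixture of <18
    and >=31 scores with nothing in between is not enumerated by the
    published rule and is conservatively sent for testing (flagged
    ``unclassified_by_rule``).
    """
    var = coerce_variant(variant)
    used = _VARIANT_SCORES[var]
    values = {name: getattr(scores, name) for name in used}
    missing = [name for name, v in values.items() if v is None]
    if missing:
        raise TriageUnavailableError(
            f"variant {var.value} requires unavailable score(s): {', '.join(missing)}"
        )
    bands = {name: score_band(v, thresholds) for name, v in values.items()}
    band_set = set(bands.values())

    def result(label: TriageLabel, mitosis_used: bool = False, unclassified: bool = False):
        return TriageResult(
            label=label,
            variant=var,
            bands=bands,
            mitosis_used=mitosis_used,
            unclassified_by_rule=unclassified,
        )

    if band_set == {Band.H}:
        return result(TriageLabel.DO_NOT_SEND_EXPECT_HIGH)
    if Band.S in band_set:
        return result(TriageLabel.SEND)
    if Band.M in band_set:
        if Band.H in band_set:
            # mid-band rule does not apply above 25; treat as residual mixture
            return result(TriageLabel.SEND, unclassified=True)
        if mitosis_score is None:
            raise MitosisRequiredError(
                "scores in the 18–25 band require the mitotic activity score"
            )
        if mitosis_score <= thresholds.mitosis_cutoff:
            return result(TriageLabel.DO_NOT_SEND_EXPECT_LOW, mitosis_used=True)
        return result(TriageLabel.SEND, mitosis_used=True)
    if band_set == {Band.L}:
        return result(TriageLabel.DO_NOT_SEND_EXPECT_LOW)
    # L and H with nothing in between
    return result(TriageLabel.SEND, unclassified=True)


@dataclass
class CohortTriage:
    """Per-case triage results for a cohort, with label counts and any errors."""

    results: list[Optional[TriageResult]]
    case_ids: list[object]
    counts: Mapping[str, int]
    errors: list[tuple[object, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[Optional[TriageLabel]]:
        return [r.label if r is not None else None for r in self.results]

    @property
    def n_do_not_send(self) -> int:
        return (
            self.counts[TriageLabel.DO_NOT_SEND_EXPECT_LOW.value]
            + self.counts[TriageLabel.DO_NOT_SEND_EXPECT_HIGH.value]
        )

    @property
    def n_send(self) -> int:
        return self.counts[TriageLabel.SEND.value]


def triage_cohort(
    cases: Iterable,
    variant: str | Variant = Variant.ALL_EQUATIONS,
    coefficients=None,
    on_error: str = "fail",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CohortTriage:
    """Score and triage every case of a cohort, order-preserving.

    ``cases`` is an iterable of :class:`~magee_triage.records.CaseRecord`
    (anything with ``pathology_input()``, ``mitosis_score`` and
    ``case_id``).  ``on_error='skip'`` records per-case failures (with
    case identifiers) instead of raising; skipped cases appear as ``None``
    in ``results``.
    """
    if on_error not in {"fail", "skip"}:
        raise ValueError("on_error must be 'fail' or 'skip'")
    from .scoring import compute_magee_scores

    var = coerce_variant(variant)
    results: list[Optional[TriageResult]] = []
    case_ids: list[object] = []
    errors: list[tuple[object, str]] = []
    counts = {label.value: 0 for label in TriageLabel}
    for case in cases:
        cid = getattr(case, "case_id", None)
        case_ids.append(cid)
        try:
            scores = compute_magee_scores(case.pathology_input(), coefficients)
            res = triage(scores, mitosis_score=case.mitosis_score, variant=var,
                         thresholds=thresholds)
        except Exception as exc:  # per-case failures carry the identifier
            if on_error == "fail":
                raise type(exc)(f"case {cid!r}: {exc}") from exc
            errors.append((cid, str(exc)))
            results.append(None)
            continue
        results.append(res)
        counts[res.label.value] += 1
    return CohortTriage(results=results, case_ids=case_ids, counts=counts, errors=errors)
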