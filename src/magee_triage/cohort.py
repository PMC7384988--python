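"""Cohort-level validation statistics.

Concordance of the triage label against the actual recurrence-score band
(split at 25, the post-TAILORx clinical cutoff), cohort proportions,
subgroup analyses, clinicopathologic group comparisons (t-test /
chi-square / Fisher exact), and the avoided-test cost estimate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .decision import TriageLabel, TriageResult
from .records import CaseRecord
from .scoring import round_score

__all__ = [
    "ConcordanceSummary",
    "GroupComparisonResult",
    "SubgroupReport",
    "CostSavings",
    "build_concordance",
    "cohort_proportions",
    "subgroup_analysis",
    "compare_groups",
    "cost_savings",
    "DEFAULT_VARIABLE_SPEC",
]

RS_CUTOFF = 25  # actual recurrence score ≤25 = low risk, >25 = high risk


def _label_of(r) -> TriageLabel:
    if isinstance(r, TriageLabel):
        return r
    if isinstance(r, TriageResult):
        return r.label
    return TriageLabel(str(r))


def _pct1(fraction: float) -> float:
    return round_score(100.0 * fraction, 1)


@dataclass(frozen=True)
class ConcordanceSummary:
    """2x2 concordance of do-not-send labels vs the actual score band.

    Cells count do-not-send cases only; "send" cases are excluded from the
    table (as the validation design does) but tallied in ``n_send`` with
    the fraction of them whose actual score exceeded the cutoff.
    Accuracies are exact count ratios; ``*_pct`` properties report them as
    one-decimal percentages.
    """

    expect_high_actual_high: int
    expect_high_actual_low: int
    expect_low_actual_high: int
    expect_low_actual_low: int
    n_send: int
    n_send_actual_high: int
    n_missing_rs: int = 0

    # --- margins -------------------------------------------------------
    @property
    def n_expect_high(self) -> int:
        return self.expect_high_actual_high + self.expect_high_actual_low

    @property
    def n_expect_low(self) -> int:
        return self.expect_low_actual_high + self.expect_low_actual_low

    @property
    def n_do_not_send(self) -> int:
        return self.n_expect_high + self.n_expect_low

    @property
    def n_actual_high(self) -> int:
        return self.expect_high_actual_high + self.expect_low_actual_high

    @property
    def n_actual_low(self) -> int:
        return self.expect_high_actual_low + self.expect_low_actual_low

    # --- accuracies ----------------------------------------------------
    @property
    def overall_accuracy(self) -> Optional[float]:
        if self.n_do_not_send == 0:
            return None
        return (self.expect_high_actual_high + self.expect_low_actual_low) / self.n_do_not_send

    @property
    def expect_low_accuracy(self) -> Optional[float]:
        if self.n_expect_low == 0:
            return None
        return self.expect_low_actual_low / self.n_expect_low

    @property
    def expect_high_accuracy(self) -> Optional[float]:
        if self.n_expect_high == 0:
            return None
        return self.expect_high_actual_high / self.n_expect_high

    @property
    def discordant_fraction(self) -> Optional[float]:
        acc = self.overall_accuracy
        return None if acc is None else 1.0 - acc

    @property
    def send_high_fraction(self) -> Optional[float]:
        if self.n_send == 0:
            return None
        return self.n_send_actual_high / self.n_send

    @property
    def overall_accuracy_pct(self) -> Optional[float]:
        return None if self.overall_accuracy is None else _pct1(self.overall_accuracy)

    @property
    def expect_low_accuracy_pct(self) -> Optional[float]:
        return None if self.expect_low_accuracy is None else _pct1(self.expect_low_accuracy)

    @property
    def expect_high_accuracy_pct(self) -> Optional[float]:
        return None if self.expect_high_accuracy is None else _pct1(self.expect_high_accuracy)

    @property
    def discordant_fraction_pct(self) -> Optional[float]:
        return None if self.discordant_fraction is None else _pct1(self.discordant_fraction)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "expect_high": {"actual_high": self.expect_high_actual_high,
                                "actual_low": self.expect_high_actual_low},
                "expect_low": {"actual_high": self.expect_low_actual_high,
                               "actual_low": self.expect_low_actual_low},
            },
            "margins": {
                "n_expect_high": self.n_expect_high,
                "n_expect_low": self.n_expect_low,
                "n_do_not_send": self.n_do_not_send,
                "n_actual_high": self.n_actual_high,
                "n_actual_low": self.n_actual_low,
            },
            "n_send": self.n_send,
            "n_send_actual_high": self.n_send_actual_high,
            "n_missing_rs": self.n_missing_rs,
            "accuracy": {
                "overall_pct": self.overall_accuracy_pct,
                "expect_low_pct": self.expect_low_accuracy_pct,
                "expect_high_pct": self.expect_high_accuracy_pct,
                "discordant_pct": self.discordant_fraction_pct,
            },
        }


def build_concordance(
    triage_results: Sequence,
    actual_rs: Sequence[Optional[float]],
) -> ConcordanceSummary:
    """Cross-tabulate per-case triage labels against actual score bands.

    Cases without an actual recurrence score are excluded and counted in
    ``n_missing_rs``.  With zero do-not-send cases the accuracies are
    undefined and reported as ``None``.
    """
    if len(triage_results) != len(actual_rs):
        raise ValueError("triage_results and actual_rs must align")
    counts = {"hh": 0, "hl": 0, "lh": 0, "ll": 0}
    n_send = n_send_high = n_missing = 0
    for res, rs in zip(triage_results, actual_rs):
        if rs is None or (isinstance(rs, float) and math.isnan(rs)):
            n_missing += 1
            continue
        label = _label_of(res)
        high = rs > RS_CUTOFF
        if label is TriageLabel.SEND:
            n_send += 1
            n_send_high += int(high)
        elif label is TriageLabel.DO_NOT_SEND_EXPECT_HIGH:
            counts["hh" if high else "hl"] += 1
        else:
            counts["lh" if high else "ll"] += 1
    return ConcordanceSummary(
        expect_high_actual_high=counts["hh"],
        expect_high_actual_low=counts["hl"],
        expect_low_actual_high=counts["lh"],
        expect_low_actual_low=counts["ll"],
        n_send=n_send,
        n_send_actual_high=n_send_high,
        n_missing_rs=n_missing,
    )


def cohort_proportions(triage_results: Sequence) -> dict:
    """Do-not-send / send fractions of a triaged cohort, as one-decimal percents."""
    if len(triage_results) == 0:
        raise ValueError("empty cohort")
    labels = [_label_of(r) for r in triage_results]
    n = len(labels)
    n_send = sum(1 for l in labels if l is TriageLabel.SEND)
    n_dns = n - n_send
    return {
        "n": n,
        "n_do_not_send": n_dns,
        "n_send": n_send,
        "do_not_send_fraction": n_dns / n,
        "send_fraction": n_send / n,
        "do_not_send_pct": _pct1(n_dns / n),
        "send_pct": _pct1(n_send / n),
    }


@dataclass(frozen=True)
class SubgroupReport:
    """Concordance within a case subgroup, plus banded actual-score fractions.

    The extra fractions describe how low the actual scores run among
    do-not-send cases (share below 21 and below 16).
    """

    n_subgroup: int
    concordance: Optional[ConcordanceSummary]
    frac_rs_lt_21: Optional[float]
    frac_rs_lt_16: Optional[float]

    @property
    def applicable(self) -> bool:
        return self.concordance is not None


def subgroup_analysis(
    cases: Sequence[CaseRecord],
    triage_results: Sequence,
    predicate: Callable[[CaseRecord], bool],
) -> SubgroupReport:
    """Concordance restricted to cases satisfying ``predicate``.

    The shipped use is the age <= 50 subgroup.  An empty subgroup yields a
    not-applicable report.
    """
    pairs = [(c, r) for c, r in zip(cases, triage_results) if predicate(c)]
    if not pairs:
        return SubgroupReport(0, None, None, None)
    sub_cases, sub_results = zip(*pairs)
    summary = build_concordance(list(sub_results), [c.actual_rs for c in sub_cases])
    dns_rs = [
        c.actual_rs
        for c, r in pairs
        if c.actual_rs is not None and _label_of(r) is not TriageLabel.SEND
    ]
    if dns_rs:
        lt21 = sum(1 for v in dns_rs if v < 21) / len(dns_rs)
        lt16 = sum(1 for v in dns_rs if v < 16) / len(dns_rs)
    else:
        lt21 = lt16 = None
    return SubgroupReport(len(pairs), summary, lt21, lt16)


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-group comparison of one clinicopathologic variable."""

    variable: str
    kind: str  # continuous | categorical
    test: str  # t_test | chi_square | fisher_exact | skipped
    statistic: Optional[float]
    p_value: Optional[float]
    group_a_summary: Mapping[str, object]
    group_b_summary: Mapping[str, object]
    note: str = ""


# variable name -> (kind, accessor, levels-or-None); level order mirrors the
# conventional table layout (grade I/II/III, PR negative/positive, ...)
DEFAULT_VARIABLE_SPEC: dict = {
    "age": ("continuous", lambda c: c.age, None),
    "tumor_size": ("continuous", lambda c: c.tumor_size, None),
    "grade": ("categorical", lambda c: c.grade, [1, 2, 3]),
    "pr_status": (
        "categorical",
        lambda c: None if c.pr_positive is None else ("positive" if c.pr_positive else "negative"),
        ["negative", "positive"],
    ),
    "pr_h_score": ("continuous", lambda c: c.pr_h_score, None),
    "er_h_score": ("continuous", lambda c: c.er_h_score, None),
    "ki67_index": ("continuous", lambda c: c.ki67_index, None),
    "nodal_status": (
        "categorical",
        lambda c: c.nodal_status.value if c.nodal_status is not None else None,
        ["negative", "positive", "itc", "unknown"],
    ),
}


def _continuous_test(a: np.ndarray, b: np.ndarray, equal_var: bool):
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _categorical_test(table: np.ndarray):
    """Chi-square over the full cross-tabulation; Fisher exact for sparse 2x2.

    Fisher is substituted on 2x2 tables when any expected count is below 5
    (the usual small-sample rule); the chi-square carries no continuity
    correction.
    """
    table = np.asarray(table, dtype=float)
    if table.shape == (2, 2):
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table.astype(int))
            return "fisher_exact", float(odds), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi_square", float(chi2), float(p)


def compare_groups(
    cases_a: Sequence[CaseRecord],
    cases_b: Sequence[CaseRecord],
    variable_spec: Optional[Mapping] = None,
    equal_var: bool = False,
) -> list[GroupComparisonResult]:
    """Univariable comparison of two case groups, one row per variable.

    Continuous variables get an independent two-sample t-test — Welch by
    default (``equal_var=False``), because validation groups are typically
    wildly unbalanced; pass ``equal_var=True`` for the pooled-variance
    form.  Categorical variables get a chi-square over the full level
    cross-tabulation, with Fisher's exact test substituted for 2x2 tables
    when any expected count is below 5.  All p-values two-sided.
    """
    spec = dict(variable_spec) if variable_spec is not None else DEFAULT_VARIABLE_SPEC
    out: list[GroupComparisonResult] = []
    for name, (kind, accessor, levels) in spec.items():
        va = [accessor(c) for c in cases_a]
        vb = [accessor(c) for c in cases_b]
        va = [v for v in va if v is not None]
        vb = [v for v in vb if v is not None]
        if kind == "continuous":
            if len(va) < 2 or len(vb) < 2:
                out.append(GroupComparisonResult(
                    name, kind, "skipped", None, None,
                    {"n": len(va)}, {"n": len(vb)},
                    note="fewer than 2 non-missing values in a group",
                ))
                continue
            a, b = np.asarray(va, float), np.asarray(vb, float)
            statistic, p = _continuous_test(a, b, equal_var)
            test = "t_test"
            sa = {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))}
            sb = {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))}
            note = "pooled variance" if equal_var else "Welch (unequal variance)"
        elif kind == "categorical":
            lv = levels if levels is not None else sorted(set(va) | set(vb))
            # drop levels absent from both groups so chi-square df is right
            lv = [l for l in lv if (l in va) or (l in vb)]
            if not lv or not va or not vb:
                out.append(GroupComparisonResult(
                    name, kind, "skipped", None, None,
                    {"n": len(va)}, {"n": len(vb)}, note="no observed levels",
                ))
                continue
            ca = [va.count(l) for l in lv]
            cb = [vb.count(l) for l in lv]
            table = np.array([ca, cb])
            if len(lv) < 2:
                out.append(GroupComparisonResult(
                    name, kind, "skipped", None, None,
                    _cat_summary(lv, ca), _cat_summary(lv, cb),
                    note="only one observed level",
                ))
                continue
            test, statistic, p = _categorical_test(table)
            sa, sb = _cat_summary(lv, ca), _cat_summary(lv, cb)
            note = ""
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {name!r}")
        out.append(GroupComparisonResult(name, kind, test, statistic, p, sa, sb, note))
    return out


def _cat_summary(levels: Sequence, counts: Sequence[int]) -> dict:
    n = sum(counts)
    return {
        "n": n,
        "counts": dict(zip(levels, counts)),
        "percents": {l: _pct1(c / n) if n else None for l, c in zip(levels, counts)},
    }


@dataclass(frozen=True)
class CostSavings:
    """Avoided-assay cost for a batch of test requests, inputs echoed."""

    n_requests: int
    do_not_send_fraction: float
    unit_cost: float
    amount: float


def cost_savings(
    n_requests: int,
    do_not_send_fraction: float,
    unit_cost: float = 4000.0,
) -> CostSavings:
    """Cost avoided by not running the assay on do-not-send cases.

    Defaults to the commonly quoted assay list price of over $4000 per
    test: triaging ~70% of 100 requests away saves ~$300,000.
    """
    if not 0 <= do_not_send_fraction <= 1:
        raise ValueError("do_not_send_fraction must be in [0, 1]")
    if unit_cost <= 0:
        raise ValueError("unit_cost must be > 0")
    if n_requests < 0:
        raise ValueError("n_requests must be >= 0")
    return CostSavings(
        n_requests=n_requests,
        do_not_send_fraction=do_not_send_fraction,
        unit_cost=unit_cost,
        amount=n_requests * do_not_send_fraction * unit_cost,
    )
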