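"""End-to-end validation report assembly.

``run_report`` ties the pipeline together: load (or simulate) a cohort,
score and triage it under every algorithm variant, and assemble the
standard validation artifacts — the concordance table, clinicopathologic
group comparisons (discordant vs concordant; send vs do-not-send-expect-
low), a variant-comparison table, the age<=50 subgroup analysis, the DRFS
analysis of discordant cases, and the cost-savings estimate — as one
JSON-serializable structure with an embedded provenance block.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .cohort import (
    build_concordance,
    cohort_proportions,
    compare_groups,
    cost_savings,
    subgroup_analysis,
)
from .decision import Thresholds, TriageLabel, Variant, triage_cohort
from .io import read_cases
from .records import CaseRecord
from .scoring import load_coefficients
from .simulate import SimulationParams, generate_cohort, generate_survival
from .survival import drfs_report

__all__ = ["RunConfig", "run_report", "report_to_json"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a validation run.

    Either ``input_path`` (a case CSV) or ``simulate=True`` (the default
    synthetic cohort at ``n_cases``/``seed``) supplies the cohort.
    Thresholds default to the published rule (18 / 25 / 31, mitosis
    cutoff 1) but may be overridden for sensitivity analysis.
    """

    input_path: Optional[str] = None
    simulate: bool = False
    n_cases: int = 2196
    seed: int = 0
    coefficient_path: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    variant: str = "all_equations"
    unit_test_cost: float = 4000.0
    on_error: str = "fail"

    def __post_init__(self) -> None:
        if self.input_path is None and not self.simulate:
            raise ValueError("config needs input_path or simulate=True")
        if self.on_error not in {"fail", "skip"}:
            raise ValueError("on_error must be 'fail' or 'skip'")


def _load_cohort(config: RunConfig) -> list[CaseRecord]:
    if config.input_path is not None:
        records, errors = read_cases(config.input_path, on_error=config.on_error)
        return records
    params = SimulationParams(n_cases=config.n_cases)
    synth = generate_survival(
        generate_cohort(params, seed=config.seed), params, seed=config.seed + 1
    )
    return [c.record for c in synth]


def _comparison_rows(results) -> list[dict]:
    rows = []
    for r in results:
        rows.append({
            "variable": r.variable,
            "kind": r.kind,
            "test": r.test,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "group_a": dict(r.group_a_summary),
            "group_b": dict(r.group_b_summary),
            "note": r.note,
        })
    return rows


def run_report(config: RunConfig) -> dict:
    """Run the full validation pipeline and return the structured report.

    Deterministic: the same configuration (including seed) produces an
    identical report.  Raises with a stage-named message on failure.
    """
    stage = "load"
    try:
        cases = _load_cohort(config)
        coeffs = (
            load_coefficients(config.coefficient_path)
            if config.coefficient_path
            else None
        )

        stage = "triage"
        by_variant = {
            v: triage_cohort(cases, variant=v, coefficients=coeffs,
                             on_error=config.on_error, thresholds=config.thresholds)
            for v in Variant
        }
        primary = by_variant[Variant(config.variant)]

        stage = "concordance"
        rs = [c.actual_rs for c in cases]
        kept = [(r, s) for r, s in zip(primary.results, rs) if r is not None]
        concordance = build_concordance([r for r, _ in kept], [s for _, s in kept])
        proportions = cohort_proportions([r for r in primary.results if r is not None])

        stage = "variant_table"
        variant_table = {}
        for v, ct in by_variant.items():
            ok = [(r, s) for r, s in zip(ct.results, rs) if r is not None]
            summary = build_concordance([r for r, _ in ok], [s for _, s in ok])
            props = cohort_proportions([r for r in ct.results if r is not None])
            variant_table[v.value] = {
                "do_not_send_pct": props["do_not_send_pct"],
                "send_pct": props["send_pct"],
                "overall_accuracy_pct": summary.overall_accuracy_pct,
                "expect_low_accuracy_pct": summary.expect_low_accuracy_pct,
                "expect_high_accuracy_pct": summary.expect_high_accuracy_pct,
            }

        stage = "group_comparisons"
        paired = [(c, r) for c, r in zip(cases, primary.results) if r is not None]
        discordant = [
            c for c, r in paired
            if r.label is TriageLabel.DO_NOT_SEND_EXPECT_LOW
            and c.actual_rs is not None and c.actual_rs > 25
        ]
        concordant = [
            c for c, r in paired
            if r.label is TriageLabel.DO_NOT_SEND_EXPECT_LOW
            and c.actual_rs is not None and c.actual_rs <= 25
        ]
        send_cases = [c for c, r in paired if r.label is TriageLabel.SEND]
        dns_low = [c for c, r in paired if r.label is TriageLabel.DO_NOT_SEND_EXPECT_LOW]
        discordant_vs_concordant = (
            _comparison_rows(compare_groups(discordant, concordant))
            if discordant and concordant else []
        )
        send_vs_dns_low = (
            _comparison_rows(compare_groups(send_cases, dns_low))
            if send_cases and dns_low else []
        )

        stage = "subgroup"
        young = subgroup_analysis(
            [c for c, _ in paired], [r for _, r in paired],
            lambda c: c.age is not None and c.age <= 50,
        )
        subgroup = {
            "n": young.n_subgroup,
            "concordance": young.concordance.to_dict() if young.concordance else None,
            "frac_rs_lt_21": young.frac_rs_lt_21,
            "frac_rs_lt_16": young.frac_rs_lt_16,
        }

        stage = "survival"
        with_followup = [c for c in discordant if c.followup_months is not None]
        if with_followup:
            drfs = drfs_report(with_followup)
            survival = {
                "groups": [
                    {
                        "therapy": g.therapy,
                        "n": g.n,
                        "n_events": g.n_events,
                        "followup_mean": g.followup_mean,
                        "followup_iqr": list(g.followup_iqr),
                        "curve": g.curve.to_dict(),
                    }
                    for g in drfs.groups
                ],
                "global_logrank": (
                    None if drfs.global_test is None else {
                        "statistic": drfs.global_test.statistic,
                        "df": drfs.global_test.df,
                        "p_value": drfs.global_test.p_value,
                        "applicable": drfs.global_test.applicable,
                    }
                ),
                "n_excluded": len(drfs.excluded_case_ids),
            }
        else:
            survival = None

        stage = "cost"
        savings = cost_savings(100, proportions["do_not_send_fraction"], config.unit_test_cost)

        from . import __version__ as version

        return {
            "provenance": {
                "package_version": version,
                "config": {
                    "input_path": config.input_path,
                    "simulate": config.simulate,
                    "n_cases": config.n_cases,
                    "seed": config.seed,
                    "coefficient_path": config.coefficient_path,
                    "thresholds": asdict(config.thresholds),
                    "variant": config.variant,
                    "unit_test_cost": config.unit_test_cost,
                    "on_error": config.on_error,
                },
            },
            "n_cases": len(cases),
            "n_triage_errors": len(primary.errors),
            "proportions": proportions,
            "concordance": concordance.to_dict(),
            "variant_table": variant_table,
            "discordant_vs_concordant": discordant_vs_concordant,
            "send_vs_do_not_send_expect_low": send_vs_dns_low,
            "age_le_50_subgroup": subgroup,
            "discordant_drfs": survival,
            "cost_savings_per_100_requests": {
                "n_requests": savings.n_requests,
                "do_not_send_fraction": savings.do_not_send_fraction,
                "unit_cost": savings.unit_cost,
                "amount": savings.amount,
            },
        }
    except Exception as exc:
        raise RuntimeError(f"report stage '{stage}' failed: {exc}") from exc


def report_to_json(report: dict, path: Optional[str | Path] = None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
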