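"""Seeded synthetic-cohort generator and algorithm-verification harness.

The generator emulates the mock-patient exercise used to verify the checker:
a cohort with a fixed psoriasis / atopic-dermatitis split (default 25/25 over
50 patients), ages spread over the three bands, a realistic mix of therapies
drawn from the full 25-drug catalogue with clinically plausible dose ranges,
and independently sampled comorbidities.  Generation is bit-stable for a
fixed seed, and every emitted record passes profile validation by
construction.

The verification harness runs the engine over a cohort and audits each report
against the structural invariants (unique vaccine rows, non-empty reasons,
disclaimer present, live-vaccine safety) and against the independent
brute-force rule evaluator; failures are returned as data, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import EmptyInputError, InvalidSpecError
from .knowledge_base import KnowledgeBase
from .oracle import brute_force_evaluate
from .profile_model import (
    AGE_BANDS,
    CONDITIONS,
    DOSE_FIELD_BY_DRUG,
    MEDICATIONS,
    WEIGHT_DRUGS,
    PatientProfile,
    validate_profile,
)
from .recommendation_engine import (
    STATUS_RECOMMENDED,
    STATUS_SEASONAL,
    RecommendationReport,
    effective_suppression,
    recommend,
)

#: Clinically plausible dose ranges (mg) for the dose-item drugs.
DEFAULT_DOSE_RANGES: dict[str, tuple[float, float]] = {
    "ciclosporin": (100.0, 400.0),  # mg/day
    "methotrexate": (7.5, 25.0),  # mg/week
    "prednisone": (5.0, 50.0),  # mg/day
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort; defaults mirror the 50-patient check."""

    n_total: int = 50
    psoriasis_fraction: float = 0.5
    seed: int = 2023
    therapy_rate: float = 0.7
    condition_rate: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.1 for c in CONDITIONS}
    )
    dose_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_RANGES)
    )
    weight_range_kg: tuple[float, float] = (50.0, 110.0)


def _validate_spec(spec: CohortSpec) -> None:
    if spec.n_total <= 0:
        raise InvalidSpecError("n_total must be a positive integer")
    if not 0.0 <= spec.psoriasis_fraction <= 1.0:
        raise InvalidSpecError("psoriasis_fraction must lie in [0, 1]")
    if not 0.0 <= spec.therapy_rate <= 1.0:
        raise InvalidSpecError("therapy_rate must lie in [0, 1]")
    for token, p in spec.condition_rate.items():
        if token not in CONDITIONS:
            raise InvalidSpecError(f"unknown condition in condition_rate: {token!r}")
        if not 0.0 <= p <= 1.0:
            raise InvalidSpecError(f"condition_rate[{token!r}] must lie in [0, 1]")
    for drug, (lo, hi) in spec.dose_ranges.items():
        if drug not in DOSE_FIELD_BY_DRUG:
            raise InvalidSpecError(f"dose range for non-dose-item drug: {drug!r}")
        if not 0 <= lo < hi:
            raise InvalidSpecError(f"dose range for {drug!r} is degenerate")
    lo, hi = spec.weight_range_kg
    if not 0 < lo < hi:
        raise InvalidSpecError("weight_range_kg is degenerate")


def generate_cohort(spec: CohortSpec) -> list[PatientProfile]:
    """Generate exactly ``n_total`` valid profiles, reproducibly under ``seed``."""
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)

    n_pso = int(round(spec.n_total * spec.psoriasis_fraction))
    diseases = ["psoriasis"] * n_pso + ["atopic_dermatitis"] * (spec.n_total - n_pso)
    diseases = [diseases[i] for i in rng.permutation(spec.n_total)]

    profiles: list[PatientProfile] = []
    for disease in diseases:
        raw: dict[str, Any] = {
            "disease": disease,
            "hand_involvement": bool(rng.random() < 0.5),
            "age_band": str(rng.choice(AGE_BANDS)),
            "on_chronic_therapy": bool(rng.random() < spec.therapy_rate),
        }
        if raw["on_chronic_therapy"]:
            medication = str(rng.choice(MEDICATIONS))
            raw["medication"] = medication
            if medication in DOSE_FIELD_BY_DRUG:
                lo, hi = spec.dose_ranges.get(
                    medication, DEFAULT_DOSE_RANGES[medication]
                )
                raw[DOSE_FIELD_BY_DRUG[medication]] = round(
                    float(rng.uniform(lo, hi)), 1
                )
            if medication in WEIGHT_DRUGS:
                wlo, whi = spec.weight_range_kg
                raw["weight_kg"] = round(float(rng.uniform(wlo, whi)), 1)
        picked = [
            c for c in CONDITIONS if rng.random() < spec.condition_rate.get(c, 0.0)
        ]
        if "pregnancy" in picked and "msm" in picked:
            picked.remove("msm" if rng.random() < 0.5 else "pregnancy")
        raw["conditions"] = picked
        profiles.append(validate_profile(raw))
    return profiles


def coverage_cohort(kb: KnowledgeBase) -> list[PatientProfile]:
    """Deterministic branch-coverage cohort: one profile per
    (age band x medication-or-none x condition-or-none) combination, so every
    default-KB rule fires at least once."""
    profiles: list[PatientProfile] = []
    meds: list[str | None] = [None, *MEDICATIONS]
    conds: list[str | None] = [None, *CONDITIONS]
    for age_band in AGE_BANDS:
        for medication in meds:
            for condition in conds:
                raw: dict[str, Any] = {
                    "disease": "psoriasis",
                    "hand_involvement": False,
                    "age_band": age_band,
                    "on_chronic_therapy": medication is not None,
                    "conditions": [] if condition is None else [condition],
                }
                if medication is not None:
                    raw["medication"] = medication
                    if medication in DOSE_FIELD_BY_DRUG:
                        lo, hi = DEFAULT_DOSE_RANGES[medication]
                        raw[DOSE_FIELD_BY_DRUG[medication]] = hi  # breach thresholds
                    if medication in WEIGHT_DRUGS:
                        raw["weight_kg"] = 70.0
                profiles.append(validate_profile(raw))
    return profiles


# ----------------------------------------------------------------- auditing


@dataclass(frozen=True)
class ProfileFinding:
    index: int
    violations: tuple[str, ...]


@dataclass(frozen=True)
class CohortAudit:
    n_reports: int
    n_failures: int
    findings: tuple[ProfileFinding, ...]

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_reports": self.n_reports,
            "n_failures": self.n_failures,
            "findings": [
                {"index": f.index, "violations": list(f.violations)}
                for f in self.findings
            ],
        }


def audit_report(
    profile: PatientProfile, report: RecommendationReport, kb: KnowledgeBase
) -> list[str]:
    """Invariant and oracle checks for a single report; returns violations."""
    violations: list[str] = []

    ids = [r.vaccine_id for r in report.recommendations]
    if len(ids) != len(set(ids)):
        violations.append("duplicate vaccine rows in report")
    if any(not r.reasons for r in report.recommendations):
        violations.append("recommendation with empty reason list")
    if not report.disclaimer:
        violations.append("missing disclaimer")

    suppressed = effective_suppression(profile, kb) == "suppressive"
    pregnant = "pregnancy" in profile.conditions
    for rec in report.recommendations:
        if kb.vaccine(rec.vaccine_id).is_live and (suppressed or pregnant):
            if rec.status in (STATUS_RECOMMENDED, STATUS_SEASONAL):
                violations.append(
                    f"live vaccine {rec.vaccine_id} unconditionally recommended "
                    "under suppression or pregnancy"
                )

    expected = brute_force_evaluate(profile, kb)
    got = {
        r.vaccine_id: (r.status, frozenset((x.reason_category, x.description) for x in r.reasons))
        for r in report.recommendations
    }
    want = {v: (e.status, e.reasons) for v, e in expected.items()}
    if got != want:
        diff = set(got.items()) ^ set(want.items())
        violations.append(f"oracle mismatch: {sorted(v for v, _ in diff)}")
    return violations


def verify_cohort(
    cohort: Sequence[PatientProfile], kb: KnowledgeBase
) -> CohortAudit:
    """Run the engine over a cohort and audit every report.

    Failures are data: the audit counts profiles with at least one violation
    and lists each finding; nothing is raised for rule-level disagreements.
    """
    findings: list[ProfileFinding] = []
    for i, profile in enumerate(cohort):
        report = recommend(profile, kb)
        violations = audit_report(profile, report, kb)
        if violations:
            findings.append(ProfileFinding(index=i, violations=tuple(violations)))
    return CohortAudit(
        n_reports=len(cohort), n_failures=len(findings), findings=tuple(findings)
    )


# ---------------------------------------------------------- task completion


@dataclass(frozen=True)
class TaskCompletionResult:
    successes: int
    attempts: int
    fraction: Fraction
    percent: float


def task_completion_rate(
    attempts: Sequence[Mapping[str, Any] | tuple[str, bool] | bool]
) -> TaskCompletionResult:
    """Proportion of successful attempts over all attempts.

    Accepts ``{"task_id": ..., "success": bool}`` mappings, ``(task_id,
    success)`` pairs, or bare booleans.
    """
    if not attempts:
        raise EmptyInputError("task completion rate is undefined with no attempts")
    flags: list[bool] = []
    for a in attempts:
        if isinstance(a, bool):
            flags.append(a)
        elif isinstance(a, Mapping):
            flags.append(bool(a["success"]))
        else:
            flags.append(bool(a[1]))
    n_ok = sum(flags)
    n = len(flags)
    frac = Fraction(n_ok, n)
    return TaskCompletionResult(
        successes=n_ok, attempts=n, fraction=frac, percent=100.0 * n_ok / n
    )
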