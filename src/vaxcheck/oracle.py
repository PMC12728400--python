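"""Independent brute-force rule evaluator used to audit the engine.

This deliberately re-derives everything with plain loops and no shared engine
machinery: its own therapy classification, its own trigger matching, its own
status overlay.  The cohort verification harness compares the engine's report
against this evaluator vaccine by vaccine; any divergence is a finding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .knowledge_base import KnowledgeBase
from .profile_model import PatientProfile


@dataclass(frozen=True)
class OracleEntry:
    vaccine_id: str
    status: str
    reasons: frozenset[tuple[str, str]]  # (reason_category, description)


def _oracle_classify(profile: PatientProfile, kb: KnowledgeBase) -> str:
    if not profile.on_chronic_therapy:
        return "none"
    entry = None
    for d in kb.drugs:
        if d.drug_id == profile.medication:
            entry = d
            break
    assert entry is not None, "validated profile references a catalogue drug"
    if entry.drug_class == "topical":
        return "none"
    if entry.suppression_rule == "never":
        return "non_suppressive_systemic"
    if entry.suppression_rule == "always":
        return "suppressive"
    # dose-threshold drugs: suppressive as soon as any cutoff is reached
    dose = profile.dose_mg
    breached = False
    if entry.threshold_absolute is not None and dose >= entry.threshold_absolute.value:
        breached = True
    if entry.threshold_per_kg is not None:
        assert profile.weight_kg is not None
        if dose >= entry.threshold_per_kg.value * profile.weight_kg:
            breached = True
    return "suppressive" if breached else "non_suppressive_systemic"


def _oracle_describe(rule, profile: PatientProfile) -> str:
    t = rule.trigger
    if t.kind == "age":
        band = profile.age_band.replace("_", "-").replace("-plus", " or more")
        return f"age band: {band}"
    if t.kind == "condition":
        return f"condition: {t.condition.replace('_', ' ')}"
    med = (profile.medication or "").replace("_", " ")
    if t.therapy == "suppressive":
        return f"immunosuppressive therapy ({med})"
    if t.therapy == "any_systemic":
        return f"systemic therapy ({med})"
    return f"therapy class trigger ({med})"


def brute_force_evaluate(
    profile: PatientProfile, kb: KnowledgeBase
) -> dict[str, OracleEntry]:
    """Expected (status, reasons) per vaccine, by naive per-rule re-scan."""
    classification = _oracle_classify(profile, kb)
    pregnant = "pregnancy" in profile.conditions
    suppressed = classification == "suppressive" or bool(
        profile.conditions & kb.settings.suppressive_conditions
    )

    reasons: dict[str, set[tuple[str, str]]] = {}
    for rule in kb.rules:
        t = rule.trigger
        if t.kind == "age":
            fired = profile.age_band in t.age_bands
        elif t.kind == "condition":
            fired = t.condition in profile.conditions
        elif t.therapy == "suppressive":
            fired = classification == "suppressive"
        elif t.therapy == "any_systemic":
            fired = classification in ("suppressive", "non_suppressive_systemic")
        else:
            cls = t.therapy.split(":", 1)[1]
            fired = profile.medication is not None and any(
                d.drug_id == profile.medication and d.drug_class == cls
                for d in kb.drugs
            )
        if fired:
            reasons.setdefault(rule.vaccine_id, set()).add(
                (rule.reason_category, _oracle_describe(rule, profile))
            )

    out: dict[str, OracleEntry] = {}
    for vaccine in kb.vaccines:
        if vaccine.vaccine_id not in reasons:
            continue
        live = vaccine.platform == "live_attenuated"
        if live and pregnant:
            status = "contraindicated_during_current_therapy"
        elif live and suppressed:
            if kb.settings.therapy_timing == "upcoming":
                status = "recommended_pre_therapy_only"
            else:
                status = "contraindicated_during_current_therapy"
        elif vaccine.seasonal:
            status = "seasonal_recommended"
        else:
            status = "recommended"
        out[vaccine.vaccine_id] = OracleEntry(
            vaccine_id=vaccine.vaccine_id,
            status=status,
            reasons=frozenset(reasons[vaccine.vaccine_id]),
        )
    return out
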