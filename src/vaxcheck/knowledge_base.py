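"""Declarative knowledge base: vaccines, drugs, indication rules, templates.

The KB is a single human-editable YAML document (see ``data/default_kb.yaml``)
with a version string and citation list.  Loading validates every structural
invariant — exactly 25 drug entries matching the checker's medication
catalogue, unique identifiers, resolvable cross-references, every vaccine
reachable by at least one rule — and returns an immutable in-memory object.

The module also houses the immunosuppression classifier, which maps a patient
profile to one of three therapy classes (``none`` /
``non_suppressive_systemic`` / ``suppressive``) using the KB's per-drug
suppression rules and dose thresholds.  For the three dose-driven drugs
(ciclosporin, methotrexate, prednisone) the patient is classed suppressive as
soon as the reported dose reaches *any* applicable threshold — the absolute
cutoff or the per-kilogram cutoff scaled by body weight — which is the
conservative reading appropriate for live-vaccine safety decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import yaml

from .errors import (
    DanglingReferenceError,
    DrugCountMismatchError,
    DuplicateIdError,
    KBInvariantError,
    KBParseError,
    MissingWeightError,
    UnknownDrugError,
)
from .profile_model import (
    AGE_BANDS,
    CONDITIONS,
    DOSE_FIELD_BY_DRUG,
    MEDICATIONS,
    PatientProfile,
)

PLATFORMS = (
    "live_attenuated",
    "inactivated_or_subunit",
    "recombinant",
    "mrna",
    "non_replicating_viral_vector",
)

DRUG_CLASSES = (
    "topical",
    "conventional_systemic",
    "corticosteroid",
    "biologic_tnf",
    "biologic_il17",
    "biologic_il23",
    "biologic_il12_23",
    "biologic_il4_13",
    "jak_inhibitor",
    "other_systemic",
)

SUPPRESSION_RULES = ("never", "always", "dose_threshold")
DOSE_THRESHOLD_DRUGS = frozenset(DOSE_FIELD_BY_DRUG)

REASON_CATEGORIES = ("age", "comorbidity", "therapy")
THERAPY_PREDICATES = ("suppressive", "any_systemic")

#: Classification levels, ordered from least to most suppressed.
CLASS_NONE = "none"
CLASS_NON_SUPPRESSIVE = "non_suppressive_systemic"
CLASS_SUPPRESSIVE = "suppressive"

_REQUIRED_TEMPLATES = (
    "booster",
    "seasonal",
    "nonlive_timing",
    "live_contraindicated",
    "live_pre_therapy",
    "live_pregnancy",
    "other_vaccines_notice",
    "disclaimer",
)


@dataclass(frozen=True)
class Threshold:
    value: float
    units: str


@dataclass(frozen=True)
class VaccineDefinition:
    vaccine_id: str
    display_name: str
    platform: str
    seasonal: bool = False
    booster_interval_years: int | None = None
    notes_template_ids: tuple[str, ...] = ()

    @property
    def is_live(self) -> bool:
        return self.platform == "live_attenuated"


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    drug_class: str
    suppression_rule: str
    threshold_absolute: Threshold | None = None
    threshold_per_kg: Threshold | None = None


@dataclass(frozen=True)
class Trigger:
    """One of: age-band membership, a condition token, a therapy predicate."""

    kind: str  # "age" | "condition" | "therapy"
    age_bands: frozenset[str] = frozenset()
    condition: str | None = None
    therapy: str | None = None  # "suppressive" | "any_systemic" | "drug_class:<cls>"


@dataclass(frozen=True)
class IndicationRule:
    rule_id: str
    trigger: Trigger
    vaccine_id: str
    reason_category: str
    note_template_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class KBSettings:
    therapy_timing: str = "current"  # "current" | "upcoming"
    live_lead_time_weeks: int = 4
    nonlive_lead_time_weeks: int = 2
    suppressive_conditions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class KnowledgeBase:
    version: str
    source_citations: tuple[str, ...]
    vaccines: tuple[VaccineDefinition, ...]
    drugs: tuple[DrugEntry, ...]
    rules: tuple[IndicationRule, ...]
    note_templates: Mapping[str, str]
    settings: KBSettings = field(default_factory=KBSettings)

    def vaccine(self, vaccine_id: str) -> VaccineDefinition:
        return self._vaccine_index()[vaccine_id]

    def drug(self, drug_id: str) -> DrugEntry:
        try:
            return self._drug_index()[drug_id]
        except KeyError:
            raise UnknownDrugError(f"drug not in knowledge base: {drug_id!r}") from None

    def display_order(self, vaccine_id: str) -> int:
        """Position of a vaccine in the fixed report ordering."""
        return list(self._vaccine_index()).index(vaccine_id)

    def _vaccine_index(self) -> dict[str, VaccineDefinition]:
        return {v.vaccine_id: v for v in self.vaccines}

    def _drug_index(self) -> dict[str, DrugEntry]:
        return {d.drug_id: d for d in self.drugs}


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _parse_threshold(obj: Any, drug_id: str) -> Threshold | None:
    if obj is None:
        return None
    try:
        return Threshold(value=float(obj["value"]), units=str(obj["units"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise KBParseError(f"drug {drug_id!r}: malformed threshold: {exc}") from exc


def _parse_trigger(obj: Any, rule_id: str) -> Trigger:
    if not isinstance(obj, Mapping) or len(obj) != 1:
        raise KBParseError(
            f"rule {rule_id!r}: trigger must have exactly one of "
            "age_bands / condition / therapy"
        )
    if "age_bands" in obj:
        bands = frozenset(obj["age_bands"])
        bad = bands - set(AGE_BANDS)
        if bad or not bands:
            raise KBParseError(f"rule {rule_id!r}: bad age bands {sorted(bad)}")
        return Trigger(kind="age", age_bands=bands)
    if "condition" in obj:
        token = obj["condition"]
        if token not in CONDITIONS:
            raise KBParseError(f"rule {rule_id!r}: unknown condition {token!r}")
        return Trigger(kind="condition", condition=token)
    if "therapy" in obj:
        pred = obj["therapy"]
        ok = pred in THERAPY_PREDICATES or (
            isinstance(pred, str)
            and pred.startswith("drug_class:")
            and pred.split(":", 1)[1] in DRUG_CLASSES
        )
        if not ok:
            raise KBParseError(f"rule {rule_id!r}: unknown therapy predicate {pred!r}")
        return Trigger(kind="therapy", therapy=pred)
    raise KBParseError(f"rule {rule_id!r}: unrecognised trigger {obj!r}")


_TRIGGER_CATEGORY = {"age": "age", "condition": "comorbidity", "therapy": "therapy"}


def build_knowledge_base(doc: Mapping[str, Any]) -> KnowledgeBase:
    """Construct and fully validate a KB from an already-parsed document."""
    try:
        raw_settings = doc.get("settings", {}) or {}
        settings = KBSettings(
            therapy_timing=raw_settings.get("therapy_timing", "current"),
            live_lead_time_weeks=int(raw_settings.get("live_lead_time_weeks", 4)),
            nonlive_lead_time_weeks=int(raw_settings.get("nonlive_lead_time_weeks", 2)),
            suppressive_conditions=frozenset(
                raw_settings.get("suppressive_conditions", [])
            ),
        )
        vaccines = tuple(
            VaccineDefinition(
                vaccine_id=v["vaccine_id"],
                display_name=v["display_name"],
                platform=v["platform"],
                seasonal=bool(v.get("seasonal", False)),
                booster_interval_years=v.get("booster_interval_years"),
                notes_template_ids=tuple(v.get("notes_template_ids", [])),
            )
            for v in doc["vaccines"]
        )
        drugs = tuple(
            DrugEntry(
                drug_id=d["drug_id"],
                drug_class=d["drug_class"],
                suppression_rule=d["suppression_rule"],
                threshold_absolute=_parse_threshold(
                    d.get("threshold_absolute"), d["drug_id"]
                ),
                threshold_per_kg=_parse_threshold(
                    d.get("threshold_per_kg"), d["drug_id"]
                ),
            )
            for d in doc["drugs"]
        )
        rules = tuple(
            IndicationRule(
                rule_id=r["rule_id"],
                trigger=_parse_trigger(r["trigger"], r["rule_id"]),
                vaccine_id=r["vaccine_id"],
                reason_category=r["reason_category"],
                note_template_ids=tuple(r.get("note_template_ids", [])),
            )
            for r in doc["rules"]
        )
        kb = KnowledgeBase(
            version=str(doc["version"]),
            source_citations=tuple(doc.get("source_citations", [])),
            vaccines=vaccines,
            drugs=drugs,
            rules=rules,
            note_templates=dict(doc.get("note_templates", {})),
            settings=settings,
        )
    except KBParseError:
        raise
    except (KeyError, TypeError) as exc:
        raise KBParseError(f"malformed knowledge base document: {exc!r}") from exc

    _validate_kb(kb)
    return kb


def _validate_kb(kb: KnowledgeBase) -> None:
    _check_unique((v.vaccine_id for v in kb.vaccines), "vaccine")
    _check_unique((d.drug_id for d in kb.drugs), "drug")
    _check_unique((r.rule_id for r in kb.rules), "rule")

    if len(kb.drugs) != len(MEDICATIONS):
        raise DrugCountMismatchError(
            f"expected {len(MEDICATIONS)} drug entries, found {len(kb.drugs)}"
        )
    drug_ids = {d.drug_id for d in kb.drugs}
    if drug_ids != set(MEDICATIONS):
        missing = set(MEDICATIONS) - drug_ids
        extra = drug_ids - set(MEDICATIONS)
        raise KBInvariantError(
            f"drug catalogue mismatch: missing={sorted(missing)} extra={sorted(extra)}"
        )

    for v in kb.vaccines:
        if v.platform not in PLATFORMS:
            raise KBInvariantError(f"vaccine {v.vaccine_id!r}: bad platform")
        if v.seasonal and v.booster_interval_years is not None:
            raise KBInvariantError(
                f"vaccine {v.vaccine_id!r}: seasonal vaccines carry no booster interval"
            )
        if v.booster_interval_years is not None and v.booster_interval_years <= 0:
            raise KBInvariantError(
                f"vaccine {v.vaccine_id!r}: booster interval must be positive"
            )
        for tid in v.notes_template_ids:
            if tid not in kb.note_templates:
                raise DanglingReferenceError(
                    f"vaccine {v.vaccine_id!r}: unknown note template {tid!r}"
                )

    for d in kb.drugs:
        if d.drug_class not in DRUG_CLASSES:
            raise KBInvariantError(f"drug {d.drug_id!r}: bad drug class")
        if d.suppression_rule not in SUPPRESSION_RULES:
            raise KBInvariantError(f"drug {d.drug_id!r}: bad suppression rule")
        is_threshold = d.suppression_rule == "dose_threshold"
        if is_threshold != (d.drug_id in DOSE_THRESHOLD_DRUGS):
            raise KBInvariantError(
                f"drug {d.drug_id!r}: dose_threshold applies exactly to "
                f"{sorted(DOSE_THRESHOLD_DRUGS)}"
            )
        has_any = d.threshold_absolute is not None or d.threshold_per_kg is not None
        if is_threshold and not has_any:
            raise KBInvariantError(f"drug {d.drug_id!r}: no threshold configured")
        if not is_threshold and has_any:
            raise KBInvariantError(
                f"drug {d.drug_id!r}: thresholds only allowed with dose_threshold"
            )

    vaccine_ids = {v.vaccine_id for v in kb.vaccines}
    reachable: set[str] = set()
    for r in kb.rules:
        if r.vaccine_id not in vaccine_ids:
            raise DanglingReferenceError(
                f"rule {r.rule_id!r} references unknown vaccine {r.vaccine_id!r}"
            )
        if r.reason_category not in REASON_CATEGORIES:
            raise KBInvariantError(f"rule {r.rule_id!r}: bad reason category")
        if r.reason_category != _TRIGGER_CATEGORY[r.trigger.kind]:
            raise KBInvariantError(
                f"rule {r.rule_id!r}: reason_category {r.reason_category!r} "
                f"inconsistent with {r.trigger.kind} trigger"
            )
        for tid in r.note_template_ids:
            if tid not in kb.note_templates:
                raise DanglingReferenceError(
                    f"rule {r.rule_id!r}: unknown note template {tid!r}"
                )
        reachable.add(r.vaccine_id)

    unreachable = vaccine_ids - reachable
    if unreachable:
        raise KBInvariantError(
            f"vaccines unreachable by any rule: {sorted(unreachable)}"
        )

    for tid in _REQUIRED_TEMPLATES:
        if tid not in kb.note_templates:
            raise DanglingReferenceError(f"missing required note template {tid!r}")

    bad = kb.settings.suppressive_conditions - set(CONDITIONS)
    if bad:
        raise KBInvariantError(f"settings: unknown suppressive conditions {sorted(bad)}")
    if kb.settings.therapy_timing not in ("current", "upcoming"):
        raise KBInvariantError("settings: therapy_timing must be current or upcoming")


def load_knowledge_base(path: str | None = None) -> KnowledgeBase:
    """Load and validate a KB YAML file; ``None`` loads the bundled default."""
    if path is None:
        text = (
            resources.files("vaxcheck").joinpath("data/default_kb.yaml").read_text(
                encoding="utf-8"
            )
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KBParseError(f"could not parse knowledge base file: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise KBParseError("knowledge base document is not a mapping")
    return build_knowledge_base(doc)


def classify_immunosuppression(profile: PatientProfile, kb: KnowledgeBase) -> str:
    """Three-level therapy classification for a validated profile.

    ``none``: no chronic therapy, or topical therapy only.
    ``non_suppressive_systemic``: a systemic drug the KB marks never-suppressive,
    or a dose-threshold drug dosed below every applicable cutoff.
    ``suppressive``: a drug marked always-suppressive, or a dose-threshold drug
    at or above any applicable cutoff (absolute, or per-kg scaled by weight).
    """
    if not profile.on_chronic_therapy or profile.medication is None:
        return CLASS_NONE
    entry = kb.drug(profile.medication)
    if entry.drug_class == "topical":
        return CLASS_NONE
    if entry.suppression_rule == "never":
        return CLASS_NON_SUPPRESSIVE
    if entry.suppression_rule == "always":
        return CLASS_SUPPRESSIVE

    dose = profile.dose_mg
    if dose is None:  # unreachable for validated profiles
        raise MissingWeightError(
            f"dose missing for dose-threshold drug {entry.drug_id!r}"
        )
    cutoffs: list[float] = []
    if entry.threshold_absolute is not None:
        cutoffs.append(entry.threshold_absolute.value)
    if entry.threshold_per_kg is not None:
        if profile.weight_kg is None:
            raise MissingWeightError(
                f"weight required for per-kg threshold of {entry.drug_id!r}"
            )
        cutoffs.append(entry.threshold_per_kg.value * profile.weight_kg)
    if any(dose >= c for c in cutoffs):
        return CLASS_SUPPRESSIVE
    return CLASS_NON_SUPPRESSIVE
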