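"""Patient-input data model for the vaccine checker.

The checker asks ten questions: disease (psoriasis or atopic dermatitis), hand
involvement, age band, current/upcoming chronic (>2 weeks) therapy, the
prescribed medication (one of 25 catalogue entries), conditional dose and
weight items for ciclosporin / methotrexate / prednisone, and a multi-select
list of comorbidities and risk factors.  This module defines the validated
:class:`PatientProfile` record, the JSON dialect used for cohort files, and a
deterministic human-readable echo that round-trips back into a profile.

Validation is total: every raw mapping either yields a profile or raises
exactly one typed :class:`~vaxcheck.errors.ProfileError` subclass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

from .errors import (
    ConditionalFieldViolationError,
    InvalidFieldValueError,
    MissingRequiredFieldError,
    OutOfRangeDoseError,
    UnknownConditionError,
    UnknownFieldError,
    UnknownMedicationError,
)

DISEASES = ("psoriasis", "atopic_dermatitis")

AGE_BANDS = ("18_59", "60_64", "65_plus")

#: The 25 medication response options, exactly as offered by the checker.
MEDICATIONS = (
    "abrocitinib",
    "acitretin",
    "adalimumab",
    "apremilast",
    "baricitinib",
    "bimekizumab",
    "brodalumab",
    "certolizumab_pegol",
    "ciclosporin",
    "dimethyl_fumarate",
    "dupilumab",
    "etanercept",
    "golimumab",
    "guselkumab",
    "infliximab",
    "ixekizumab",
    "methotrexate",
    "prednisone",
    "risankizumab",
    "secukinumab",
    "tildrakizumab",
    "topical_medications",
    "tralokinumab",
    "upadacitinib",
    "ustekinumab",
)

#: The 11 health-condition / lifestyle response options.
CONDITIONS = (
    "type1_diabetes",
    "type2_diabetes",
    "respiratory_disease",
    "cardiovascular_disease",
    "congenital_or_acquired_immunodeficiency",
    "hiv_infection",
    "chronic_kidney_failure",
    "asplenia",
    "chronic_hepatic_disease_or_alcoholism",
    "msm",
    "pregnancy",
)

#: Drugs whose dose drives the immunosuppression threshold, and their dose field.
DOSE_FIELD_BY_DRUG = {
    "ciclosporin": "ciclosporin_daily_dose_mg",
    "methotrexate": "methotrexate_weekly_dose_mg",
    "prednisone": "prednisone_daily_dose_mg",
}

#: Drugs for which body weight must be captured (per-kg thresholds downstream).
WEIGHT_DRUGS = frozenset({"ciclosporin", "methotrexate"})

_REQUIRED_FIELDS = ("disease", "hand_involvement", "age_band", "on_chronic_therapy")

_ALL_FIELDS = _REQUIRED_FIELDS + (
    "medication",
    "ciclosporin_daily_dose_mg",
    "methotrexate_weekly_dose_mg",
    "prednisone_daily_dose_mg",
    "weight_kg",
    "conditions",
)

_AGE_BAND_DISPLAY = {
    "18_59": "18-59 years",
    "60_64": "60-64 years",
    "65_plus": "65 years or more",
}
_AGE_BAND_FROM_DISPLAY = {v: k for k, v in _AGE_BAND_DISPLAY.items()}


@dataclass(frozen=True)
class PatientProfile:
    """One respondent's validated checker answers."""

    disease: str
    hand_involvement: bool
    age_band: str
    on_chronic_therapy: bool
    medication: str | None = None
    ciclosporin_daily_dose_mg: float | None = None
    methotrexate_weekly_dose_mg: float | None = None
    prednisone_daily_dose_mg: float | None = None
    weight_kg: float | None = None
    conditions: frozenset[str] = frozenset()

    @property
    def dose_mg(self) -> float | None:
        """The dose answer for the prescribed drug, if it is a dose-item drug."""
        field = DOSE_FIELD_BY_DRUG.get(self.medication or "")
        return getattr(self, field) if field else None


def _as_bool(value: Any, field: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.lower() in ("yes", "no", "true", "false"):
        return value.lower() in ("yes", "true")
    raise InvalidFieldValueError(f"{field}: expected a boolean, got {value!r}")


def _as_number(value: Any, field: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise InvalidFieldValueError(f"{field}: expected a number, got {value!r}")
    return float(value)


def validate_profile(raw: Mapping[str, Any]) -> PatientProfile:
    """Validate a raw key-value record into a :class:`PatientProfile`.

    Raises exactly one typed error on the first violation found:
    unknown keys, missing required answers, a medication outside the
    25-entry catalogue, conditional dose/weight items that are present
    when they should be absent (or vice versa), negative doses, and
    unknown condition tokens are all rejected.
    """
    unknown = set(raw) - set(_ALL_FIELDS)
    if unknown:
        raise UnknownFieldError(f"unknown field(s): {', '.join(sorted(unknown))}")

    for field in _REQUIRED_FIELDS:
        if field not in raw or raw[field] is None:
            raise MissingRequiredFieldError(f"missing required field: {field}")

    disease = raw["disease"]
    if disease not in DISEASES:
        raise InvalidFieldValueError(f"disease: unknown token {disease!r}")
    age_band = raw["age_band"]
    if age_band not in AGE_BANDS:
        raise InvalidFieldValueError(f"age_band: unknown token {age_band!r}")

    hand = _as_bool(raw["hand_involvement"], "hand_involvement")
    on_therapy = _as_bool(raw["on_chronic_therapy"], "on_chronic_therapy")

    medication = raw.get("medication")
    if on_therapy:
        if medication is None:
            raise MissingRequiredFieldError(
                "medication is required when on_chronic_therapy is true"
            )
        if medication not in MEDICATIONS:
            raise UnknownMedicationError(f"unknown medication: {medication!r}")
    elif medication is not None:
        raise ConditionalFieldViolationError(
            "medication given but on_chronic_therapy is false"
        )

    doses: dict[str, float | None] = {}
    for drug, field in DOSE_FIELD_BY_DRUG.items():
        value = raw.get(field)
        if medication == drug:
            if value is None:
                raise ConditionalFieldViolationError(
                    f"{field} is required when medication is {drug}"
                )
            dose = _as_number(value, field)
            if dose < 0:
                raise OutOfRangeDoseError(f"{field}: dose must be non-negative")
            doses[field] = dose
        else:
            if value is not None:
                raise ConditionalFieldViolationError(
                    f"{field} given but medication is not {drug}"
                )
            doses[field] = None

    weight = raw.get("weight_kg")
    if medication in WEIGHT_DRUGS:
        if weight is None:
            raise ConditionalFieldViolationError(
                f"weight_kg is required when medication is {medication}"
            )
        weight = _as_number(weight, "weight_kg")
        if weight <= 0:
            raise OutOfRangeDoseError("weight_kg must be positive")
    elif weight is not None:
        raise ConditionalFieldViolationError(
            "weight_kg given but medication is not ciclosporin or methotrexate"
        )

    raw_conditions = raw.get("conditions", [])
    if not isinstance(raw_conditions, (list, tuple, set, frozenset)):
        raise InvalidFieldValueError("conditions: expected a list of tokens")
    seen: list[str] = []
    for token in raw_conditions:
        if token not in CONDITIONS:
            raise UnknownConditionError(f"unknown condition: {token!r}")
        if token in seen:
            raise InvalidFieldValueError(f"conditions: duplicate token {token!r}")
        seen.append(token)
    conditions = frozenset(seen)
    if {"pregnancy", "msm"} <= conditions:
        raise ConditionalFieldViolationError(
            "conditions pregnancy and msm are mutually exclusive"
        )

    return PatientProfile(
        disease=disease,
        hand_involvement=hand,
        age_band=age_band,
        on_chronic_therapy=on_therapy,
        medication=medication,
        weight_kg=weight,
        conditions=conditions,
        **doses,
    )


def profile_to_dict(profile: PatientProfile) -> dict[str, Any]:
    """Canonical JSON-dialect form: only answered items, conditions sorted."""
    out: dict[str, Any] = {
        "disease": profile.disease,
        "hand_involvement": profile.hand_involvement,
        "age_band": profile.age_band,
        "on_chronic_therapy": profile.on_chronic_therapy,
    }
    if profile.medication is not None:
        out["medication"] = profile.medication
    for field in DOSE_FIELD_BY_DRUG.values():
        value = getattr(profile, field)
        if value is not None:
            out[field] = value
    if profile.weight_kg is not None:
        out["weight_kg"] = profile.weight_kg
    out["conditions"] = sorted(profile.conditions)
    return out


def _fmt_num(value: float) -> str:
    return format(value, ".10g")


def profile_to_echo(profile: PatientProfile) -> str:
    """Deterministic, ordered, human-readable summary of every answered item.

    The block round-trips: :func:`parse_echo` recovers an equal profile.
    """
    yn = {True: "yes", False: "no"}
    lines = [
        f"disease: {profile.disease.replace('_', ' ')}",
        f"hand involvement: {yn[profile.hand_involvement]}",
        f"age: {_AGE_BAND_DISPLAY[profile.age_band]}",
        f"chronic therapy (>2 weeks): {yn[profile.on_chronic_therapy]}",
    ]
    if profile.medication is not None:
        lines.append(f"medication: {profile.medication.replace('_', ' ')}")
    if profile.ciclosporin_daily_dose_mg is not None:
        lines.append(
            f"ciclosporin daily dose: {_fmt_num(profile.ciclosporin_daily_dose_mg)} mg"
        )
    if profile.methotrexate_weekly_dose_mg is not None:
        lines.append(
            "methotrexate weekly dose: "
            f"{_fmt_num(profile.methotrexate_weekly_dose_mg)} mg"
        )
    if profile.prednisone_daily_dose_mg is not None:
        lines.append(
            f"prednisone daily dose: {_fmt_num(profile.prednisone_daily_dose_mg)} mg"
        )
    if profile.weight_kg is not None:
        lines.append(f"weight: {_fmt_num(profile.weight_kg)} kg")
    if profile.conditions:
        shown = ", ".join(c.replace("_", " ") for c in sorted(profile.conditions))
    else:
        shown = "none"
    lines.append(f"conditions: {shown}")
    return "\n".join(lines)


_ECHO_KEYS = {
    "disease": "disease",
    "hand involvement": "hand_involvement",
    "age": "age_band",
    "chronic therapy (>2 weeks)": "on_chronic_therapy",
    "medication": "medication",
    "ciclosporin daily dose": "ciclosporin_daily_dose_mg",
    "methotrexate weekly dose": "methotrexate_weekly_dose_mg",
    "prednisone daily dose": "prednisone_daily_dose_mg",
    "weight": "weight_kg",
    "conditions": "conditions",
}


def parse_echo(text: str) -> PatientProfile:
    """Parse an echo block back into a validated profile (inverse of echo)."""
    raw: dict[str, Any] = {}
    for line in text.strip().splitlines():
        label, _, value = line.partition(":")
        field = _ECHO_KEYS.get(label.strip())
        if field is None:
            raise InvalidFieldValueError(f"unrecognised echo line: {line!r}")
        value = value.strip()
        if field == "disease":
            raw[field] = value.replace(" ", "_")
        elif field == "age_band":
            if value not in _AGE_BAND_FROM_DISPLAY:
                raise InvalidFieldValueError(f"age: unknown band {value!r}")
            raw[field] = _AGE_BAND_FROM_DISPLAY[value]
        elif field in ("hand_involvement", "on_chronic_therapy"):
            raw[field] = value
        elif field == "medication":
            raw[field] = value.replace(" ", "_")
        elif field == "conditions":
            if value == "none":
                raw[field] = []
            else:
                raw[field] = [c.strip().replace(" ", "_") for c in value.split(",")]
        else:  # dose / weight lines end with a unit suffix
            raw[field] = float(value.split()[0])
    return validate_profile(raw)
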