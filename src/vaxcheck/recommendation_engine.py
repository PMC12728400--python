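"""Core checker: apply the knowledge base to a profile, produce the report.

The engine fires every indication rule whose trigger matches the profile
(age-band membership, condition membership, or a therapy predicate evaluated
through the immunosuppression classifier), unions the matched vaccines while
merging reasons, and then applies the safety overlay:

* live attenuated vaccine + suppressive therapy -> contraindicated during the
  current therapy (or flagged "complete before the planned therapy" when the
  KB's timing policy is ``upcoming``);
* live attenuated vaccine + pregnancy -> contraindicated, regardless of therapy;
* non-live vaccine + any systemic therapy -> timing note that administration
  is preferable at least two weeks before treatment initiation;
* seasonal vaccines carry a seasonality note, boostered vaccines a booster note.

Conditions the KB marks as intrinsically immunosuppressive (HIV infection,
congenital or acquired immunodeficiency, by default) drive the same live-
vaccine overlay as drug-induced suppression, without changing the drug
classification itself.

The module also provides the vaccination-center finder: a great-circle
(haversine, 6371 km sphere) nearest-facility search over a coordinate
registry, restricted to the app's 5- or 10-km radii.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyRegistryError,
    InvalidCoordinateError,
    InvalidRadiusError,
    UnknownFormatError,
)
from .knowledge_base import (
    CLASS_NONE,
    CLASS_SUPPRESSIVE,
    IndicationRule,
    KnowledgeBase,
    classify_immunosuppression,
)
from .profile_model import PatientProfile, profile_to_echo

EARTH_RADIUS_KM = 6371.0
ALLOWED_RADII_KM = (5, 10)

STATUS_RECOMMENDED = "recommended"
STATUS_PRE_THERAPY_ONLY = "recommended_pre_therapy_only"
STATUS_SEASONAL = "seasonal_recommended"
STATUS_CONTRAINDICATED = "contraindicated_during_current_therapy"

#: Ordering used by the monotonicity checks: higher rank = less restricted.
STATUS_RANK = {
    STATUS_CONTRAINDICATED: 0,
    STATUS_PRE_THERAPY_ONLY: 1,
    STATUS_SEASONAL: 2,
    STATUS_RECOMMENDED: 2,
}

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class Reason:
    reason_category: str
    description: str


@dataclass(frozen=True)
class VaccineRecommendation:
    vaccine_id: str
    display_name: str
    status: str
    reasons: tuple[Reason, ...]
    timing_note: str | None = None
    booster_note: str | None = None
    seasonality_note: str | None = None
    extra_notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RecommendationReport:
    generated_at: str
    kb_version: str
    patient_echo: str
    recommendations: tuple[VaccineRecommendation, ...]
    other_vaccines_notice: str
    disclaimer: str


def describe_trigger(rule: IndicationRule, profile: PatientProfile) -> str:
    """Stable human-readable reason text for a fired rule."""
    t = rule.trigger
    if t.kind == "age":
        return f"age band: {profile.age_band.replace('_', '-').replace('-plus', ' or more')}"
    if t.kind == "condition":
        return f"condition: {t.condition.replace('_', ' ')}"
    med = (profile.medication or "").replace("_", " ")
    if t.therapy == "suppressive":
        return f"immunosuppressive therapy ({med})"
    if t.therapy == "any_systemic":
        return f"systemic therapy ({med})"
    return f"therapy class trigger ({med})"


def _trigger_matches(
    rule: IndicationRule, profile: PatientProfile, classification: str, kb: KnowledgeBase
) -> bool:
    t = rule.trigger
    if t.kind == "age":
        return profile.age_band in t.age_bands
    if t.kind == "condition":
        return t.condition in profile.conditions
    # therapy predicates
    if t.therapy == "suppressive":
        return classification == CLASS_SUPPRESSIVE
    if t.therapy == "any_systemic":
        return classification != CLASS_NONE
    drug_class = t.therapy.split(":", 1)[1]
    if not profile.on_chronic_therapy or profile.medication is None:
        return False
    return kb.drug(profile.medication).drug_class == drug_class


def effective_suppression(profile: PatientProfile, kb: KnowledgeBase) -> str:
    """Drug classification, escalated by intrinsically suppressive conditions."""
    classification = classify_immunosuppression(profile, kb)
    if profile.conditions & kb.settings.suppressive_conditions:
        return CLASS_SUPPRESSIVE
    return classification


def recommend(
    profile: PatientProfile, kb: KnowledgeBase, *, now: datetime | None = None
) -> RecommendationReport:
    """Produce the full recommendation report for one validated profile.

    ``now`` is injectable so that reports are byte-reproducible in tests and
    batch runs; it defaults to the current UTC time.
    """
    classification = classify_immunosuppression(profile, kb)
    overlay_class = effective_suppression(profile, kb)
    pregnant = "pregnancy" in profile.conditions
    templates = kb.note_templates
    settings = kb.settings

    matched: dict[str, list[Reason]] = {}
    for rule in kb.rules:
        if not _trigger_matches(rule, profile, classification, kb):
            continue
        reason = Reason(rule.reason_category, describe_trigger(rule, profile))
        reasons = matched.setdefault(rule.vaccine_id, [])
        if reason not in reasons:
            reasons.append(reason)

    recommendations: list[VaccineRecommendation] = []
    for vaccine in kb.vaccines:  # KB order is the fixed display order
        reasons = matched.get(vaccine.vaccine_id)
        if not reasons:
            continue

        status = STATUS_SEASONAL if vaccine.seasonal else STATUS_RECOMMENDED
        timing_note: str | None = None
        if vaccine.is_live:
            if pregnant:
                status = STATUS_CONTRAINDICATED
                timing_note = templates["live_pregnancy"]
            elif overlay_class == CLASS_SUPPRESSIVE:
                if settings.therapy_timing == "upcoming":
                    status = STATUS_PRE_THERAPY_ONLY
                    timing_note = templates["live_pre_therapy"].format(
                        lead_weeks=settings.live_lead_time_weeks
                    )
                else:
                    status = STATUS_CONTRAINDICATED
                    timing_note = templates["live_contraindicated"]
        elif classification != CLASS_NONE:
            timing_note = templates["nonlive_timing"].format(
                lead_weeks=settings.nonlive_lead_time_weeks
            )

        booster_note = None
        if vaccine.booster_interval_years is not None:
            booster_note = templates["booster"].format(
                interval_years=vaccine.booster_interval_years
            )
        seasonality_note = templates["seasonal"] if vaccine.seasonal else None
        extra = tuple(templates[tid] for tid in vaccine.notes_template_ids)

        recommendations.append(
            VaccineRecommendation(
                vaccine_id=vaccine.vaccine_id,
                display_name=vaccine.display_name,
                status=status,
                reasons=tuple(reasons),
                timing_note=timing_note,
                booster_note=booster_note,
                seasonality_note=seasonality_note,
                extra_notes=extra,
            )
        )

    stamp = (now or datetime.now(timezone.utc)).isoformat(timespec="seconds")
    return RecommendationReport(
        generated_at=stamp,
        kb_version=kb.version,
        patient_echo=profile_to_echo(profile),
        recommendations=tuple(recommendations),
        other_vaccines_notice=templates["other_vaccines_notice"],
        disclaimer=templates["disclaimer"],
    )


# --------------------------------------------------------------- rendering

_STATUS_LABEL = {
    STATUS_RECOMMENDED: "Recommended",
    STATUS_PRE_THERAPY_ONLY: "Recommended before the planned therapy only",
    STATUS_SEASONAL: "Recommended (seasonal)",
    STATUS_CONTRAINDICATED: "Contraindicated during the current therapy",
}


def render_report(report: RecommendationReport, fmt: str = "markdown") -> str:
    """Render a report as ``markdown`` (human order) or ``json`` (lossless)."""
    if fmt == "json":
        return json.dumps(_report_to_dict(report), indent=2, ensure_ascii=False)
    if fmt != "markdown":
        raise UnknownFormatError(f"unknown report format: {fmt!r}")

    lines = [
        "# Vaccination recommendation report",
        "",
        f"Generated: {report.generated_at} — knowledge base version {report.kb_version}",
        "",
        "## Your answers",
        "",
        report.patient_echo,
        "",
        "## Recommended vaccines",
        "",
    ]
    if not report.recommendations:
        lines.append("No vaccine-specific recommendation was triggered by your answers.")
        lines.append("")
    for rec in report.recommendations:
        lines.append(f"### {rec.display_name} — {_STATUS_LABEL[rec.status]}")
        for reason in rec.reasons:
            lines.append(f"- Reason ({reason.reason_category}): {reason.description}")
        if rec.timing_note:
            lines.append(f"- Timing: {rec.timing_note}")
        if rec.booster_note:
            lines.append(f"- Booster: {rec.booster_note}")
        if rec.seasonality_note:
            lines.append(f"- Seasonality: {rec.seasonality_note}")
        for note in rec.extra_notes:
            lines.append(f"- Note: {note}")
        lines.append("")
    lines += [
        "## Other vaccines",
        "",
        report.other_vaccines_notice,
        "",
        "## Disclaimer",
        "",
        report.disclaimer,
        "",
    ]
    return "\n".join(lines)


def _report_to_dict(report: RecommendationReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generated_at": report.generated_at,
        "kb_version": report.kb_version,
        "patient_echo": report.patient_echo,
        "recommendations": [
            {
                "vaccine_id": r.vaccine_id,
                "display_name": r.display_name,
                "status": r.status,
                "reasons": [
                    {"reason_category": x.reason_category, "description": x.description}
                    for x in r.reasons
                ],
                "timing_note": r.timing_note,
                "booster_note": r.booster_note,
                "seasonality_note": r.seasonality_note,
                "extra_notes": list(r.extra_notes),
            }
            for r in report.recommendations
        ],
        "other_vaccines_notice": report.other_vaccines_notice,
        "disclaimer": report.disclaimer,
    }


def parse_report(text: str) -> RecommendationReport:
    """Inverse of ``render_report(..., fmt="json")``."""
    doc = json.loads(text)
    return RecommendationReport(
        generated_at=doc["generated_at"],
        kb_version=doc["kb_version"],
        patient_echo=doc["patient_echo"],
        recommendations=tuple(
            VaccineRecommendation(
                vaccine_id=r["vaccine_id"],
                display_name=r["display_name"],
                status=r["status"],
                reasons=tuple(
                    Reason(x["reason_category"], x["description"])
                    for x in r["reasons"]
                ),
                timing_note=r["timing_note"],
                booster_note=r["booster_note"],
                seasonality_note=r["seasonality_note"],
                extra_notes=tuple(r["extra_notes"]),
            )
            for r in doc["recommendations"]
        ),
        other_vaccines_notice=doc["other_vaccines_notice"],
        disclaimer=doc["disclaimer"],
    )


# ------------------------------------------------------------ center finder


@dataclass(frozen=True)
class CenterHit:
    name: str
    address_text: str
    lat: float
    lon: float
    distance_km: float


def haversine_km(
    lat1: float, lon1: float, lat2: np.ndarray | float, lon2: np.ndarray | float
) -> np.ndarray | float:
    """Great-circle distance on a 6371-km sphere, in kilometres."""
    p1, l1 = math.radians(lat1), math.radians(lon1)
    p2 = np.radians(lat2)
    l2 = np.radians(lon2)
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(
        (l2 - l1) / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def find_centers(
    lat: float, lon: float, registry: pd.DataFrame, radius_km: int
) -> list[CenterHit]:
    """Centers within ``radius_km`` (5 or 10), ascending by distance then name."""
    if radius_km not in ALLOWED_RADII_KM:
        raise InvalidRadiusError(f"radius must be one of {ALLOWED_RADII_KM} km")
    if abs(lat) > 90 or abs(lon) > 180 or not (math.isfinite(lat) and math.isfinite(lon)):
        raise InvalidCoordinateError(f"invalid query point ({lat}, {lon})")
    if registry.empty:
        raise EmptyRegistryError("the center registry is empty")
    lats = registry["lat"].to_numpy(dtype=float)
    lons = registry["lon"].to_numpy(dtype=float)
    if (np.abs(lats) > 90).any() or (np.abs(lons) > 180).any() or (
        ~np.isfinite(lats)
    ).any() or (~np.isfinite(lons)).any():
        raise InvalidCoordinateError("registry contains invalid coordinates")
    dist = np.asarray(haversine_km(lat, lon, lats, lons))
    hits = [
        CenterHit(
            name=str(row["name"]),
            address_text=str(row.get("address_text", "")),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            distance_km=float(d),
        )
        for (_, row), d in zip(registry.iterrows(), dist)
        if d <= radius_km
    ]
    hits.sort(key=lambda h: (h.distance_km, h.name))
    return hits


def load_center_registry(path: str) -> pd.DataFrame:
    """Read a center registry CSV (columns: name, address_text, lat, lon)."""
    df = pd.read_csv(path)
    missing = {"name", "lat", "lon"} - set(df.columns)
    if missing:
        raise InvalidCoordinateError(
            f"registry missing column(s): {', '.join(sorted(missing))}"
        )
    if "address_text" not in df.columns:
        df = df.assign(address_text="")
    return df
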