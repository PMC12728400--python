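"""uMARS survey scoring, group comparison and precision-based sample sizing.

The user version of the Mobile App Rating Scale (uMARS) has 26 items on a
1-5 Likert scale: 16 objective-quality items in four subscales (engagement 5,
functionality 4, aesthetics 3, information 4), 4 subjective-quality items
(the fourth being the star rating) and 6 perceived-impact items.  Scoring
follows the instrument's definition: each rater's subscale score is the mean
of that rater's item scores (not-applicable items dropped), and the rater's
total score is the unweighted mean of their four subscale scores.  Cohort
statistics aggregate the per-rater values; medians and IQRs use linear
interpolation.

Group comparisons use a two-tailed independent two-sample t test (Welch by
default, pooled-variance available), computable from raw scores or from
(mean, SD, n) summaries.  Sample sizing inverts the normal-approximation
confidence half-width for a mean: the smallest n with z * sd / sqrt(n) <=
the requested precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    EmptyInputError,
    InsufficientNError,
    InvalidParameterError,
    MalformedSheetError,
    ZeroVarianceError,
)

SUBSCALE_ITEMS: dict[str, tuple[str, ...]] = {
    "engagement": ("e1", "e2", "e3", "e4", "e5"),
    "functionality": ("f1", "f2", "f3", "f4"),
    "aesthetics": ("a1", "a2", "a3"),
    "information": ("i1", "i2", "i3", "i4"),
}
SUBJECTIVE_ITEMS = ("s1", "s2", "s3", "s4")  # s4 = star rating
IMPACT_ITEMS = ("p1", "p2", "p3", "p4", "p5", "p6")
ALL_ITEMS = tuple(
    item for items in SUBSCALE_ITEMS.values() for item in items
) + SUBJECTIVE_ITEMS + IMPACT_ITEMS  # 16 + 4 + 6 = 26

STRATA = ("dermatologist", "public_health_physician")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal display rounding (0.5 always rounds away from zero)."""
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class UmarsSheet:
    """One rater's 26 item scores; ``None`` encodes a not-applicable answer."""

    rater_id: str
    stratum: str
    scores: Mapping[str, int | None]

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise MalformedSheetError(
                f"rater {self.rater_id!r}: unknown stratum {self.stratum!r}"
            )
        missing = set(ALL_ITEMS) - set(self.scores)
        extra = set(self.scores) - set(ALL_ITEMS)
        if missing or extra:
            raise MalformedSheetError(
                f"rater {self.rater_id!r}: sheet must contain exactly the 26 items "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for item, score in self.scores.items():
            if score is not None and (not isinstance(score, int) or not 1 <= score <= 5):
                raise MalformedSheetError(
                    f"rater {self.rater_id!r}: item {item} score {score!r} "
                    "not in 1..5 or NA"
                )

    def subscale_mean(self, subscale: str) -> float:
        """Mean of this rater's items in a subscale, NA dropped; NaN if all NA."""
        values = [
            self.scores[i] for i in SUBSCALE_ITEMS[subscale] if self.scores[i] is not None
        ]
        return float(np.mean(values)) if values else float("nan")

    def total_score(self) -> float:
        """Unweighted mean of the four subscale means."""
        return float(np.mean([self.subscale_mean(s) for s in SUBSCALE_ITEMS]))


@dataclass(frozen=True)
class Stats:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n: int


def _stats(values: Sequence[float]) -> Stats:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return Stats(
        mean=float(arr.mean()), sd=sd, median=float(med), q1=float(q1), q3=float(q3),
        n=int(arr.size),
    )


@dataclass(frozen=True)
class AgreementResult:
    n_agree: int
    n: int
    percent: int  # rounded half-up to integer


@dataclass(frozen=True)
class UmarsSummary:
    n_raters: int
    item_stats: Mapping[str, Stats]
    subscale_stats: Mapping[str, Stats]
    total_stats: Stats
    subjective_stats: Stats
    star_rating_stats: Stats
    impact: Mapping[str, AgreementResult]
    per_rater_totals: tuple[float, ...]
    per_rater_subscales: Mapping[str, tuple[float, ...]]


def score_sheets(sheets: Sequence[UmarsSheet]) -> UmarsSummary:
    """Aggregate a set of rater sheets into the instrument's summary scores."""
    if not sheets:
        raise EmptyInputError("no uMARS sheets to score")

    per_sub = {
        s: tuple(sheet.subscale_mean(s) for sheet in sheets) for s in SUBSCALE_ITEMS
    }
    totals = tuple(sheet.total_score() for sheet in sheets)

    item_stats = {}
    for item in ALL_ITEMS:
        vals = [float(sheet.scores[item]) for sheet in sheets
                if sheet.scores[item] is not None]
        if vals:
            item_stats[item] = _stats(vals)

    subjective = [
        float(np.mean([sheet.scores[i] for i in SUBJECTIVE_ITEMS
                       if sheet.scores[i] is not None] or [np.nan]))
        for sheet in sheets
    ]
    stars = [float(sheet.scores["s4"]) for sheet in sheets
             if sheet.scores["s4"] is not None]

    return UmarsSummary(
        n_raters=len(sheets),
        item_stats=item_stats,
        subscale_stats={s: _stats(v) for s, v in per_sub.items()},
        total_stats=_stats(totals),
        subjective_stats=_stats(subjective),
        star_rating_stats=_stats(stars if stars else [float("nan")]),
        impact=agreement_proportions(
            {i: [sheet.scores[i] for sheet in sheets] for i in IMPACT_ITEMS}
        ),
        per_rater_totals=totals,
        per_rater_subscales=per_sub,
    )


def aggregate_item_means(item_means: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Subscale means and total from per-item mean scores.

    Applies the instrument's scoring identities one level up: each subscale
    mean is the unweighted mean of its item means, and the total is the
    unweighted mean of the four subscale means.  Useful for re-aggregating a
    published summary table.
    """
    unknown = set(item_means) - set(SUBSCALE_ITEMS)
    if unknown:
        raise InvalidParameterError(f"unknown subscale(s): {sorted(unknown)}")
    out: dict[str, float] = {}
    for subscale, means in item_means.items():
        expected = len(SUBSCALE_ITEMS[subscale])
        if len(means) != expected:
            raise InvalidParameterError(
                f"{subscale}: expected {expected} item means, got {len(means)}"
            )
        out[subscale] = float(np.mean(means))
    if set(item_means) == set(SUBSCALE_ITEMS):
        out["total"] = float(np.mean([out[s] for s in SUBSCALE_ITEMS]))
    return out


# ------------------------------------------------------------ group tests


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    two_sided_p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    variant: str


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], variant: str = "welch"
) -> GroupComparison:
    """Two-tailed independent t test between two groups of raw scores."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientNError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidParameterError("scores must be finite")
    return compare_groups_from_stats(
        float(a.mean()), float(a.std(ddof=1)), int(a.size),
        float(b.mean()), float(b.std(ddof=1)), int(b.size),
        variant=variant,
    )


def compare_groups_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "welch",
) -> GroupComparison:
    """The same test from (mean, SD, n) summary statistics per group."""
    if variant not in ("welch", "pooled"):
        raise InvalidParameterError(f"unknown t-test variant: {variant!r}")
    if n_a < 2 or n_b < 2:
        raise InsufficientNError("each group needs at least n=2")
    if sd_a == 0.0 and sd_b == 0.0:
        raise ZeroVarianceError("both groups have zero variance")

    va, vb = sd_a**2, sd_b**2
    if variant == "pooled":
        df = float(n_a + n_b - 2)
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        sea2, seb2 = va / n_a, vb / n_b
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (
            sea2**2 / (n_a - 1) + seb2**2 / (n_b - 1)
        )
    t = (mean_a - mean_b) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(
        t=t, df=df, two_sided_p=p,
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b, n_a=n_a, n_b=n_b,
        variant=variant,
    )


# ------------------------------------------------------------ sample size


def sample_size_for_mean(sd: float, precision: float, confidence: float = 0.95) -> int:
    """Smallest n with z(confidence) * sd / sqrt(n) <= precision."""
    if sd <= 0 or precision <= 0 or not 0.0 < confidence < 1.0:
        raise InvalidParameterError(
            "need sd > 0, precision > 0 and 0 < confidence < 1"
        )
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    n = max(1, math.ceil((z * sd / precision) ** 2))
    # enforce exact minimality against float slop at integer boundaries
    while n > 1 and z * sd / math.sqrt(n - 1) <= precision:
        n -= 1
    while z * sd / math.sqrt(n) > precision:
        n += 1
    return n


# -------------------------------------------------------------- agreement


def agreement_proportions(
    impact_scores: Mapping[str, Sequence[int | None]]
) -> dict[str, AgreementResult]:
    """Per-item share of raters scoring 4 ("agree") or 5 ("strongly agree")."""
    out: dict[str, AgreementResult] = {}
    for item, scores in impact_scores.items():
        answered = [s for s in scores if s is not None]
        if not answered:
            raise EmptyInputError(f"item {item!r} has no answered scores")
        n_agree = sum(1 for s in answered if s >= 4)
        out[item] = AgreementResult(
            n_agree=n_agree,
            n=len(answered),
            percent=int(round_half_up(100.0 * n_agree / len(answered))),
        )
    return out


# ------------------------------------------------------------------- I/O


def read_sheets_csv(path: str) -> list[UmarsSheet]:
    """Read rater sheets from CSV (columns rater_id, stratum, e1..p6; NA allowed)."""
    df = pd.read_csv(path, dtype={"rater_id": str})
    missing = {"rater_id", "stratum", *ALL_ITEMS} - set(df.columns)
    if missing:
        raise MalformedSheetError(f"survey CSV missing column(s): {sorted(missing)}")
    sheets = []
    for _, row in df.iterrows():
        scores = {
            item: (None if pd.isna(row[item]) else int(row[item]))
            for item in ALL_ITEMS
        }
        sheets.append(
            UmarsSheet(rater_id=str(row["rater_id"]), stratum=row["stratum"],
                       scores=scores)
        )
    return sheets


def summary_table(summary: UmarsSummary) -> pd.DataFrame:
    """Subscale-and-total summary laid out one row per scale."""
    rows = []
    for subscale in SUBSCALE_ITEMS:
        s = summary.subscale_stats[subscale]
        rows.append((subscale, s.mean, s.sd, s.median, s.q1, s.q3))
    t = summary.total_stats
    rows.append(("total", t.mean, t.sd, t.median, t.q1, t.q3))
    return pd.DataFrame(
        rows, columns=["scale", "mean", "sd", "median", "q1", "q3"]
    )
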