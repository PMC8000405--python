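"""Point rules, per-area level assignment and the composite organizational level.

Each of the eight criteria contributes at most one point, so an area's total
lies in [0, 8]. Points are computed as exact rationals (thirds, fourths and
ninths) with :class:`fractions.Fraction`, so level boundaries are evaluated
without floating-point artifacts; callers passing floats get their totals
rounded to 9 decimals before binning.

Level rubric for one clinical area (total -> level):

    total <= 3        Level 1
    3 < total <= 4    Level 2
    4 < total <= 5    Level 3
    5 < total <= 6    Level 4
    total > 6         Level 5

The organizational composite is the mean of the levels of the three clinical
areas with the longest program durations, padded with Level 0 when fewer than
three areas run PM programs, rounded to the nearest integer. Because the mean
of three integers has fractional part 0, 1/3 or 2/3, rounding ties cannot
occur. An organization reporting no PM areas is composite Level 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

from .rubric import (
    AreaResponse,
    ClinicalArea,
    ConsistencyLevel,
    DataCollectionResponse,
    DataTier,
    DiscreteTier,
    OrgResponse,
    CRITERIA,
    canonical_area_order,
)

__all__ = [
    "AreaScore",
    "CompositeAssessment",
    "ScoredOrg",
    "score_discrete_criterion",
    "score_utilization",
    "score_sharing",
    "baseline_data_score",
    "consistency_multiplier",
    "score_data_criterion",
    "score_area",
    "assign_level",
    "select_longest_areas",
    "composite_level",
    "score_org",
    "score_cohort",
]

_DISCRETE_POINTS = {
    DiscreteTier.NONE: Fraction(0),
    DiscreteTier.TIER1: Fraction(1, 3),
    DiscreteTier.TIER2: Fraction(2, 3),
    DiscreteTier.TIER3: Fraction(1),
}

_DATA_BASELINE = {
    DataTier.NONE: Fraction(0),
    DataTier.TIER1: Fraction(1, 9),
    DataTier.TIER2: Fraction(2, 9),
    DataTier.TIER3: Fraction(1, 3),
}

_CONSISTENCY_FACTOR = {
    ConsistencyLevel.NONE: 0,
    ConsistencyLevel.SOME: 1,
    ConsistencyLevel.MOST: 2,
    ConsistencyLevel.ALL: 3,
}


@dataclass(frozen=True)
class AreaScore:
    """Scored result for one clinical area: per-criterion points, total, level."""

    area: ClinicalArea
    criterion_points: dict[str, Fraction]
    total: Fraction
    level: int

    def __post_init__(self) -> None:
        assert self.total == sum(self.criterion_points.values())


@dataclass(frozen=True)
class CompositeAssessment:
    """Organizational composite: the padded level triple and its rounded mean."""

    org_id: str
    selected_areas: tuple[tuple[ClinicalArea, int, float], ...]  # (area, level, duration)
    padded_levels: tuple[int, int, int]
    mean_level: Fraction
    composite_level: int


@dataclass(frozen=True)
class ScoredOrg:
    """An organization with every area scored and the composite assessed."""

    org: OrgResponse
    area_scores: tuple[AreaScore, ...] = field(default_factory=tuple)
    composite: CompositeAssessment = None  # type: ignore[assignment]


def score_discrete_criterion(tier: DiscreteTier) -> Fraction:
    """Points for a discrete criterion: none -> 0, tiers 1-3 -> 1/3, 2/3, 1."""
    tier = DiscreteTier(tier)
    return _DISCRETE_POINTS[tier]


def score_utilization(flags) -> Fraction:
    """One-third point per satisfied data-utilization statement."""
    return Fraction(flags.count(), 3)


def score_sharing(flags) -> Fraction:
    """One-fourth point per satisfied data-sharing statement."""
    return Fraction(flags.count(), 4)


def baseline_data_score(tier: DataTier) -> Fraction:
    """Baseline for a data criterion: none -> 0, tiers 1-3 -> 1/9, 2/9, 1/3."""
    tier = DataTier(tier)
    return _DATA_BASELINE[tier]


def consistency_multiplier(consistency: ConsistencyLevel) -> int:
    """Multiplier for ordering breadth: none -> 0, some/most/all -> 1/2/3."""
    consistency = ConsistencyLevel(consistency)
    return _CONSISTENCY_FACTOR[consistency]


def score_data_criterion(resp: DataCollectionResponse) -> Fraction:
    """Baseline x consistency multiplier, e.g. multigene panels ordered by
    most physicians: 2/9 x 2 = 4/9. Maximum is 1/3 x 3 = 1."""
    if not isinstance(resp, DataCollectionResponse):
        resp = DataCollectionResponse.model_validate(resp)
    return baseline_data_score(resp.tier) * consistency_multiplier(resp.consistency)


def score_area(resp: AreaResponse) -> AreaScore:
    """Score all eight criteria for one clinical area and assign its level."""
    if not isinstance(resp, AreaResponse):
        resp = AreaResponse.model_validate(resp)
    points = {
        "testing_guidance": score_discrete_criterion(resp.testing_guidance),
        "leadership": score_discrete_criterion(resp.leadership),
        "internal_funding": score_discrete_criterion(resp.internal_funding),
        "utilization": score_utilization(resp.utilization),
        "sharing": score_sharing(resp.sharing),
        "genomic": score_data_criterion(resp.genomic),
        "other_omics": score_data_criterion(resp.other_omics),
        "non_laboratory": score_data_criterion(resp.non_laboratory),
    }
    assert tuple(points) == CRITERIA
    total = sum(points.values(), Fraction(0))
    return AreaScore(area=resp.area, criterion_points=points, total=total, level=assign_level(total))


def assign_level(total) -> int:
    """Map an eight-criterion total in [0, 8] to an integration level 1-5.

    Right-closed unit bins: totals exactly on a boundary take the lower
    level ("three or less" is Level 1). Float inputs are rounded to 9
    decimals first so that e.g. a total assembled from thirds as
    0.333... + ... binned at 3.0 lands where the exact rational would.
    """
    if isinstance(total, Rational):
        t = Fraction(total)
    else:
        t = Fraction(round(float(total), 9)).limit_denominator(10**9)
    if not 0 <= t <= 8:
        raise ValueError(f"area total must be in [0, 8], got {float(t)}")
    if t <= 3:
        return 1
    if t <= 4:
        return 2
    if t <= 5:
        return 3
    if t <= 6:
        return 4
    return 5


def select_longest_areas(org: OrgResponse) -> list[AreaResponse]:
    """The up-to-three areas with the longest program durations.

    Ties are broken by the canonical clinical-area order (oncology first),
    making selection deterministic.
    """
    order = {a: i for i, a in enumerate(canonical_area_order())}
    ranked = sorted(org.areas, key=lambda r: (-r.duration_years, order[r.area]))
    return ranked[:3]


def composite_level(org: OrgResponse) -> CompositeAssessment:
    """The organizational composite level.

    Mean of the selected areas' levels padded with 0s to length 3, rounded
    to the nearest integer. Zero reported areas gives composite Level 0;
    conversely any organization running at least one PM program rates at
    least Level 1, since Level 0 means "no PM approaches at all" — the
    rounded mean is floored at 1 in the single-low-area corner (one area at
    Level 1 gives mean 1/3, which would otherwise round to 0).
    """
    selected = select_longest_areas(org)
    scored = [(r, score_area(r)) for r in selected]
    levels = [s.level for _, s in scored]
    padded = tuple(levels + [0] * (3 - len(levels)))
    mean = Fraction(sum(padded), 3)
    # round half up; unreachable tie since fractional part is 0, 1/3 or 2/3
    composite = (2 * sum(padded) + 3) // 6
    if levels:
        composite = max(composite, 1)
    return CompositeAssessment(
        org_id=org.org_id,
        selected_areas=tuple((r.area, s.level, r.duration_years) for r, s in scored),
        padded_levels=padded,  # type: ignore[arg-type]
        mean_level=mean,
        composite_level=composite,
    )


def score_org(org: OrgResponse) -> ScoredOrg:
    """Score every reported area of an organization and its composite."""
    if not isinstance(org, OrgResponse):
        org = OrgResponse.model_validate(org)
    return ScoredOrg(
        org=org,
        area_scores=tuple(score_area(a) for a in org.areas),
        composite=composite_level(org),
    )


def score_cohort(cohort: list[OrgResponse]) -> list[ScoredOrg]:
    """Score a whole survey cohort."""
    return [score_org(org) for org in cohort]
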