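"""Shared fixtures: hand-built survey records and an independent scoring oracle."""

from __future__ import annotations

from fractions import Fraction

import pytest

from pmscore.rubric import AreaResponse, OrgResponse

META = {
    "practice_type": "health_system",
    "affiliation": "academic",
    "demographic": "urban",
    "region": "northeast",
    "n_hospitals": 3,
    "respondent_role": "lab_director",
}


def make_area(area="oncology", duration=5.0, **kw) -> AreaResponse:
    return AreaResponse(area=area, duration_years=duration, **kw)


def make_org(org_id="org0001", areas=(), **meta) -> OrgResponse:
    fields = {**META, **meta}
    return OrgResponse(org_id=org_id, areas=list(areas), **fields)


MAX_AREA_KW = dict(
    testing_guidance="tier3",
    leadership="tier3",
    internal_funding="tier3",
    utilization={"standard_of_care": True, "off_label_or_trial_matching": True, "experimental_research": True},
    sharing={
        "individual_physicians_only": True,
        "multidisciplinary_team_within_department": True,
        "across_departments": True,
        "external_organizations": True,
    },
    genomic={"tier": "tier3", "consistency": "all"},
    other_omics={"tier": "tier3", "consistency": "all"},
    non_laboratory={"tier": "tier3", "consistency": "all"},
)


def oracle_total(resp: AreaResponse) -> Fraction:
    """Sum-of-parts scoring oracle, coded independently of the engine.

    Walks the raw response and adds up rubric points directly from the
    printed rules: discrete tiers at 1/3 each step, breadth checklists at
    1/3 and 1/4 per statement, and data criteria as ninth-based baselines
    times the ordering multiplier.
    """
    tier_steps = {"none": 0, "tier1": 1, "tier2": 2, "tier3": 3}
    cons_steps = {"none": 0, "some": 1, "most": 2, "all": 3}
    total = Fraction(0)
    for crit in ("testing_guidance", "leadership", "internal_funding"):
        total += Fraction(tier_steps[getattr(resp, crit).value], 3)
    u = resp.utilization
    total += Fraction(
        int(u.standard_of_care) + int(u.off_label_or_trial_matching) + int(u.experimental_research), 3
    )
    s = resp.sharing
    total += Fraction(
        int(s.individual_physicians_only)
        + int(s.multidisciplinary_team_within_department)
        + int(s.across_departments)
        + int(s.external_organizations),
        4,
    )
    for crit in ("genomic", "other_omics", "non_laboratory"):
        d = getattr(resp, crit)
        total += Fraction(tier_steps[d.tier.value], 9) * cons_steps[d.consistency.value]
    return total


def random_area_kwargs(rng) -> dict:
    """Uniformly random (valid) raw answers for one clinical area."""
    tiers = ["none", "tier1", "tier2", "tier3"]
    cons = ["some", "most", "all"]
    kw = {
        "testing_guidance": tiers[rng.integers(4)],
        "leadership": tiers[rng.integers(4)],
        "internal_funding": tiers[rng.integers(4)],
        "utilization": {
            "standard_of_care": bool(rng.integers(2)),
            "off_label_or_trial_matching": bool(rng.integers(2)),
            "experimental_research": bool(rng.integers(2)),
        },
        "sharing": {
            "individual_physicians_only": bool(rng.integers(2)),
            "multidisciplinary_team_within_department": bool(rng.integers(2)),
            "across_departments": bool(rng.integers(2)),
            "external_organizations": bool(rng.integers(2)),
        },
    }
    for crit in ("genomic", "other_omics", "non_laboratory"):
        t = tiers[rng.integers(4)]
        kw[crit] = {"tier": t, "consistency": "none" if t == "none" else cons[rng.integers(3)]}
    return kw


def graded_profiles() -> list[AreaResponse]:
    """Five oncology profiles whose totals land in levels 1..5 in order,
    with data-sharing points strictly increasing (0, 1/4, 1/2, 3/4, 1)."""
    flags = (
        "individual_physicians_only",
        "multidisciplinary_team_within_department",
        "across_departments",
        "external_organizations",
    )

    def sharing(k):
        return {f: i < k for i, f in enumerate(flags)}

    discrete3 = dict(testing_guidance="tier3", leadership="tier3", internal_funding="tier3")
    return [
        # total 1 -> L1
        make_area(testing_guidance="tier3", sharing=sharing(0)),
        # 3 + 1/3 + 1/4 = 3.58 -> L2
        make_area(**discrete3, utilization={"standard_of_care": True}, sharing=sharing(1)),
        # 3 + 1 + 1/2 = 4.5 -> L3
        make_area(
            **discrete3,
            utilization=MAX_AREA_KW["utilization"],
            sharing=sharing(2),
        ),
        # 3 + 1 + 3/4 + 1/3 + 1/9 = 5.19 -> L4
        make_area(
            **discrete3,
            utilization=MAX_AREA_KW["utilization"],
            sharing=sharing(3),
            genomic={"tier": "tier3", "consistency": "some"},
            other_omics={"tier": "tier1", "consistency": "some"},
        ),
        # 3 + 1 + 1 + 1 + 1 = 7 -> L5
        make_area(
            **discrete3,
            utilization=MAX_AREA_KW["utilization"],
            sharing=sharing(4),
            genomic={"tier": "tier3", "consistency": "all"},
            other_omics={"tier": "tier3", "consistency": "all"},
        ),
    ]


@pytest.fixture
def mini_cohort() -> list[OrgResponse]:
    """Three organizations: two areas, one area, and a Level-0 record."""
    a1 = make_area("oncology", 10.0, **MAX_AREA_KW)
    a2 = make_area("rare_undiagnosed_disease", 4.0, testing_guidance="tier1")
    a3 = make_area("pharmacogenomics_chronic_disease", 2.5, leadership="tier2")
    return [
        make_org("org_a", [a1, a2]),
        make_org("org_b", [a3], practice_type="independent_hospital", demographic="rural"),
        make_org("org_c", [], affiliation="community_nonteaching", region="west"),
    ]
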