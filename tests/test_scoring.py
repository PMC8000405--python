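"""Point rules, level assignment, composite aggregation and their invariants."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmscore.rubric import (
    AreaResponse,
    ConsistencyLevel,
    DataCollectionResponse,
    DataTier,
    DiscreteTier,
    SharingFlags,
    UtilizationFlags,
)
from pmscore.scoring import (
    assign_level,
    baseline_data_score,
    composite_level,
    consistency_multiplier,
    score_area,
    score_data_criterion,
    score_discrete_criterion,
    score_sharing,
    score_utilization,
    select_longest_areas,
)

from conftest import MAX_AREA_KW, make_area, make_org, oracle_total, random_area_kwargs


class TestPointRules:
    @pytest.mark.parametrize(
        "tier,expected",
        [("none", 0), ("tier1", Fraction(1, 3)), ("tier2", Fraction(2, 3)), ("tier3", 1)],
    )
    def test_discrete_criterion(self, tier, expected):
        assert score_discrete_criterion(DiscreteTier(tier)) == expected

    @pytest.mark.parametrize("n_true", [0, 1, 2, 3])
    def test_utilization_third_per_statement(self, n_true):
        flags = UtilizationFlags(
            standard_of_care=n_true > 0,
            off_label_or_trial_matching=n_true > 1,
            experimental_research=n_true > 2,
        )
        assert score_utilization(flags) == Fraction(n_true, 3)

    @pytest.mark.parametrize("n_true", [0, 1, 2, 3, 4])
    def test_sharing_quarter_per_statement(self, n_true):
        flags = SharingFlags(
            individual_physicians_only=n_true > 0,
            multidisciplinary_team_within_department=n_true > 1,
            across_departments=n_true > 2,
            external_organizations=n_true > 3,
        )
        assert score_sharing(flags) == Fraction(n_true, 4)

    @pytest.mark.parametrize(
        "tier,expected",
        [("none", 0), ("tier1", Fraction(1, 9)), ("tier2", Fraction(2, 9)), ("tier3", Fraction(1, 3))],
    )
    def test_data_baseline(self, tier, expected):
        assert baseline_data_score(DataTier(tier)) == expected

    @pytest.mark.parametrize(
        "consistency,factor", [("none", 0), ("some", 1), ("most", 2), ("all", 3)]
    )
    def test_consistency_multiplier(self, consistency, factor):
        assert consistency_multiplier(ConsistencyLevel(consistency)) == factor

    @pytest.mark.parametrize(
        "tier,consistency,expected",
        [
            # multigene hotspot panels: baseline 2/9, scaled by ordering breadth
            ("tier2", "most", Fraction(4, 9)),
            ("tier2", "all", Fraction(6, 9)),
            # WGS/WES ordered by all physicians caps the criterion at one point
            ("tier3", "all", Fraction(1)),
            ("none", "none", Fraction(0)),
        ],
    )
    def test_data_criterion_two_step(self, tier, consistency, expected):
        resp = DataCollectionResponse(tier=tier, consistency=consistency)
        assert score_data_criterion(resp) == expected


class TestScoreArea:
    def test_maximal_response_scores_eight(self):
        score = score_area(make_area(**MAX_AREA_KW))
        assert score.total == 8
        assert score.level == 5
        assert all(p == 1 for p in score.criterion_points.values())

    def test_empty_response_scores_zero_level_one(self):
        score = score_area(make_area())
        assert score.total == 0
        assert score.level == 1

    def test_worked_genomic_contribution(self):
        area = make_area(genomic={"tier": "tier2", "consistency": "most"})
        score = score_area(area)
        assert score.criterion_points["genomic"] == Fraction(4, 9)
        assert score.total == Fraction(4, 9)

    def test_total_is_sum_of_criterion_points(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            score = score_area(make_area(**random_area_kwargs(rng)))
            assert score.total == sum(score.criterion_points.values())
            assert all(0 <= p <= 1 for p in score.criterion_points.values())
            assert 0 <= score.total <= 8


class TestAssignLevel:
    @pytest.mark.parametrize(
        "total,level",
        [
            (0, 1),
            (3.0, 1),
            (3.01, 2),
            (4.0, 2),
            (4.5, 3),
            (5.0, 3),
            (5.5, 4),
            (6.0, 4),
            (6.01, 5),
            (7.0, 5),
            (8.0, 5),
        ],
    )
    def test_boundaries_close_on_the_right(self, total, level):
        assert assign_level(total) == level

    def test_float_third_artifacts_do_not_cross_boundaries(self):
        # sub-nanounit float drift around a boundary must not flip the level
        assert assign_level(3 + 1e-10) == 1
        assert assign_level(3 - 1e-10) == 1
        assert assign_level(Fraction(1, 3) * 9) == 1

    @pytest.mark.parametrize("bad", [-0.5, 8.1, 100])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_level(bad)

    def test_non_decreasing_step_function_with_five_images(self):
        grid = [x / 100 for x in range(0, 801)]
        levels = [assign_level(x) for x in grid]
        assert levels == sorted(levels)
        assert set(levels) == {1, 2, 3, 4, 5}


class TestSelection:
    def test_strict_duration_ordering(self):
        durations = {
            "oncology": 10,
            "prenatal_neonatal_screening": 8,
            "pharmacogenomics_chronic_disease": 6,
            "rare_undiagnosed_disease": 4,
            "healthy_patient_screening": 2,
        }
        org = make_org(areas=[make_area(a, d) for a, d in durations.items()])
        picked = [a.area.value for a in select_longest_areas(org)]
        assert picked == ["oncology", "prenatal_neonatal_screening", "pharmacogenomics_chronic_disease"]

    def test_fewer_than_three_areas_all_returned(self):
        org = make_org(areas=[make_area("oncology", 1), make_area("healthy_patient_screening", 9)])
        picked = [a.area.value for a in select_longest_areas(org)]
        assert picked == ["healthy_patient_screening", "oncology"]

    def test_ties_break_by_canonical_order(self):
        org = make_org(
            areas=[
                make_area("pharmacogenomics_chronic_disease", 2),
                make_area("oncology", 5),
                make_area("rare_undiagnosed_disease", 5),
                make_area("healthy_patient_screening", 5),
            ]
        )
        picked = [a.area.value for a in select_longest_areas(org)]
        assert picked == ["oncology", "rare_undiagnosed_disease", "healthy_patient_screening"]


class TestComposite:
    def test_constant_triple(self):
        areas = [
            make_area(a, 5.0, **MAX_AREA_KW)
            for a in ("oncology", "prenatal_neonatal_screening", "rare_undiagnosed_disease")
        ]
        comp = composite_level(make_org(areas=areas))
        assert comp.padded_levels == (5, 5, 5)
        assert comp.composite_level == 5

    def test_single_area_padded_with_zeros(self):
        comp = composite_level(make_org(areas=[make_area("oncology", 3.0, **MAX_AREA_KW)]))
        assert comp.padded_levels == (5, 0, 0)
        assert comp.mean_level == Fraction(5, 3)
        assert comp.composite_level == 2

    def test_zero_areas_is_level_zero(self):
        comp = composite_level(make_org(areas=[]))
        assert comp.padded_levels == (0, 0, 0)
        assert comp.composite_level == 0

    def test_any_pm_activity_rates_at_least_level_one(self):
        # one minimal program: mean 1/3 must not round down to "no PM at all"
        comp = composite_level(make_org(areas=[make_area("oncology")]))
        assert comp.padded_levels == (1, 0, 0)
        assert comp.composite_level == 1

    def test_all_triples_match_brute_force_rounding(self):
        for triple in product(range(6), repeat=3):
            s = sum(triple)
            mean = s / 3
            # no rounding ties are possible: 3*mean is an integer, never odd*0.5
            assert abs(mean - round(mean)) != 0.5
            nearest = int(np.floor(mean + 0.5))
            assert (2 * s + 3) // 6 == nearest
            assert 0 <= nearest <= 5


upgrade_strategy = st.integers(min_value=0, max_value=10**9)


class TestMonotonicity:
    """Upgrading any single answer never lowers the total, level or composite."""

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=upgrade_strategy)
    def test_componentwise_upgrade_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        kw = random_area_kwargs(rng)
        base = make_area(**kw)
        upgraded = _upgrade_one(kw, rng)
        if upgraded is None:
            return
        before, after = score_area(base), score_area(make_area(**upgraded))
        assert after.total >= before.total
        assert after.level >= before.level
        org_b = make_org(areas=[base])
        org_a = make_org(areas=[make_area(**upgraded)])
        assert composite_level(org_a).composite_level >= composite_level(org_b).composite_level


def _upgrade_one(kw: dict, rng) -> dict | None:
    """Raise one randomly chosen component of a response, if it has headroom."""
    import copy

    kw = copy.deepcopy(kw)
    tiers = ["none", "tier1", "tier2", "tier3"]
    cons = ["none", "some", "most", "all"]
    targets = (
        ["testing_guidance", "leadership", "internal_funding"]
        + [("utilization", f) for f in kw["utilization"]]
        + [("sharing", f) for f in kw["sharing"]]
        + [(c, "tier") for c in ("genomic", "other_omics", "non_laboratory")]
        + [(c, "consistency") for c in ("genomic", "other_omics", "non_laboratory")]
    )
    order = rng.permutation(len(targets))
    for i in order:
        t = targets[i]
        if isinstance(t, str):
            idx = tiers.index(kw[t])
            if idx < 3:
                kw[t] = tiers[idx + 1]
                return kw
        elif t[0] in ("utilization", "sharing"):
            group, flag = t
            if not kw[group][flag]:
                kw[group][flag] = True
                return kw
        else:
            crit, field = t
            d = kw[crit]
            if field == "tier" and d["tier"] != "tier3":
                d["tier"] = tiers[tiers.index(d["tier"]) + 1]
                if d["consistency"] == "none":
                    d["consistency"] = "some"  # keep the pairing invariant
                return kw
            if field == "consistency" and d["tier"] != "none" and d["consistency"] != "all":
                d["consistency"] = cons[cons.index(d["consistency"]) + 1]
                return kw
    return None


class TestOracleEquivalence:
    def test_engine_matches_sum_of_parts_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(2000):
            area = make_area(**random_area_kwargs(rng))
            assert score_area(area).total == oracle_total(area)
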