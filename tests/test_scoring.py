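import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tease16.codebook import (
    DOMAINS,
    EnforcementLevel,
    PolicyObservation,
    default_codebook,
)
from tease16.scoring import (
    COMBINATIONS,
    AssumptionSet,
    ScoringError,
    WeightScheme,
    assumption_grid,
    calibrate,
    enforcement_fraction,
    rank_areas,
    round_half_away,
    score_area,
    score_topic,
    star_weight_scheme,
    stringency_fraction,
    topic_max_points,
)

CB = default_codebook()


class TestFractions:
    def test_stringency_anchors_and_linearity(self):
        t = CB.topic("purchase_age")  # 5 levels
        fracs = [stringency_fraction(t, lab) for lab in t.stringency_levels]
        assert fracs == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_advertising_ban_is_full_stringency(self):
        t = CB.topic("advertising_restrictions")
        assert stringency_fraction(t, "Ban") == 1.0

    @pytest.mark.parametrize(
        "label,rule,expected",
        [
            ("strong", "fifty_fifty", 1.0),
            ("strong", "twentyfive_seventyfive", 1.0),
            ("strong", "multiplicative", 1.0),
            ("moderate", "fifty_fifty", 0.5),
            ("moderate", "multiplicative", 2 / 3),
            ("poor", "fifty_fifty", 0.0),
            ("poor", "twentyfive_seventyfive", 0.0),
            ("poor", "multiplicative", 1 / 3),
        ],
    )
    def test_enforcement_fraction(self, label, rule, expected):
        assert enforcement_fraction(EnforcementLevel(label), rule) == pytest.approx(
            expected
        )


class TestTopicMaxPoints:
    def test_baseline_one_star_topic(self, baseline):
        t = CB.topic("advertising_restrictions")
        assert topic_max_points(t, baseline, CB) == pytest.approx(100 / 38)
        assert round_half_away(topic_max_points(t, baseline, CB), 1) == 2.6

    def test_equal_scheme_is_uniform(self):
        scheme = star_weight_scheme("equal", CB)
        for t in CB:
            assert topic_max_points(t, scheme, CB) == pytest.approx(6.25)

    def test_heavy_three_star_topic(self):
        scheme = star_weight_scheme("heavy", CB)
        # heavy weight total: 7*5 + 8*3 + 1*1 = 60
        t = CB.topic("purchase_age")
        assert topic_max_points(t, scheme, CB) == pytest.approx(500 / 60)

    def test_maxima_sum_to_100_under_every_scheme(self):
        for name in ("baseline", "heavy", "equal"):
            scheme = star_weight_scheme(name, CB)
            assert sum(topic_max_points(t, scheme, CB) for t in CB) == pytest.approx(
                100.0
            )

    def test_negative_weight_rejected(self):
        with pytest.raises(ScoringError):
            WeightScheme("bad", {"a": -1.0})


class TestScoreTopic:
    def test_zero_stringency_annihilates_multiplicative(self, baseline):
        t = CB.topic("purchase_age")
        obs = PolicyObservation("X", t.id, "16", EnforcementLevel("strong"))
        assert score_topic(obs, t, baseline, "multiplicative", CB) == 0.0

    def test_self_regulated_poorly_enforced_advertising(self, baseline):
        # sigma = 1/3, epsilon = 0 under 50:50 -> 100/38 * 1/6 ~ 0.44
        t = CB.topic("advertising_restrictions")
        obs = PolicyObservation(
            "X", t.id, "Industry self-regulation", EnforcementLevel("poor")
        )
        pts = score_topic(obs, t, baseline, "fifty_fifty", CB)
        assert pts == pytest.approx(100 / 38 / 6)
        assert round_half_away(pts, 1) == 0.4

    def test_top_band_price_topic_scores_a_third_of_prices_domain(self, baseline):
        t = CB.topic("beer_price_index")
        obs = PolicyObservation("X", t.id, ">=0.90", EnforcementLevel("strong"))
        pts = score_topic(obs, t, baseline, "fifty_fifty", CB)
        assert pts == pytest.approx(300 / 38)  # ~7.9, a third of 23.7


class TestScoreArea:
    @pytest.mark.parametrize("weighting", ["baseline", "heavy", "equal"])
    @pytest.mark.parametrize("rule", COMBINATIONS)
    def test_all_max_framework_scores_100(self, all_max_framework, weighting, rule):
        scheme = star_weight_scheme(weighting, CB)
        assert score_area(all_max_framework, scheme, rule, CB).total == pytest.approx(
            100.0
        )

    @pytest.mark.parametrize("rule", ["fifty_fifty", "multiplicative"])
    def test_all_min_framework_scores_0(self, all_min_framework, baseline, rule):
        assert score_area(all_min_framework, baseline, rule, CB).total == pytest.approx(
            0.0
        )

    def test_domain_points_sum_to_total(self, nine_areas, baseline):
        for fw in nine_areas:
            rep = score_area(fw, baseline, "fifty_fifty", CB)
            assert sum(rep.domain_points.values()) == pytest.approx(
                rep.total, abs=1e-9
            )
            assert sum(rep.topic_points.values()) == pytest.approx(rep.total, abs=1e-9)
            assert 0 <= rep.total <= 100

    @given(st.integers(0, 15), st.data())
    @settings(max_examples=30, deadline=None)
    def test_single_upgrade_never_decreases_score(
        self, nine_areas, topic_pos, data
    ):
        """Raising one stringency or enforcement level is monotone for every
        fixed weighting scheme and combination rule."""
        fw = nine_areas[data.draw(st.integers(0, len(nine_areas) - 1))]
        topic = CB.topics[topic_pos]
        obs = fw.observation(topic.id)
        s_idx = topic.level_index(obs.stringency_label)
        e_idx = obs.enforcement.raw - 1
        upgrade_enf = data.draw(st.booleans())
        if upgrade_enf and e_idx < 2:
            new = PolicyObservation(
                fw.area,
                topic.id,
                obs.stringency_label,
                EnforcementLevel(("poor", "moderate", "strong")[e_idx + 1]),
            )
        elif s_idx < topic.n_levels - 1:
            new = PolicyObservation(
                fw.area,
                topic.id,
                topic.stringency_levels[s_idx + 1],
                obs.enforcement,
            )
        else:
            return
        upgraded = fw.replace(new)
        for weighting in ("baseline", "heavy", "equal"):
            scheme = star_weight_scheme(weighting, CB)
            for rule in COMBINATIONS:
                before = score_area(fw, scheme, rule, CB)
                after = score_area(upgraded, scheme, rule, CB)
                assert after.total >= before.total - 1e-12
                assert (
                    after.topic_points[topic.id]
                    >= before.topic_points[topic.id] - 1e-12
                )
                assert (
                    after.domain_points[topic.domain]
                    >= before.domain_points[topic.domain] - 1e-12
                )

    def test_scale_equivariance_of_weights(self, nine_areas, baseline):
        scaled = WeightScheme(
            "baseline", {k: 7.3 * v for k, v in baseline.weights.items()}
        )
        for fw in nine_areas[:3]:
            a = score_area(fw, baseline, "twentyfive_seventyfive", CB).total
            b = score_area(fw, scaled, "twentyfive_seventyfive", CB).total
            assert a == pytest.approx(b)


class TestCalibration:
    def test_identity_when_max_is_100(self, baseline):
        assert calibrate(67.5, baseline, "fifty_fifty", CB) == pytest.approx(67.5)

    def test_proportionality(self):
        # a scheme/rule with max 100 still rescales raw scores linearly
        scheme = star_weight_scheme("equal", CB)
        assert calibrate(30.0, scheme, "multiplicative", CB) == pytest.approx(30.0)
        assert calibrate(0.0, scheme, "fifty_fifty", CB) == 0.0


class TestRanking:
    def test_published_total_ordering(self):
        totals = [67.5, 64.4, 62.3, 58.1, 56.4, 55.8, 50.1, 41.8, 24.1]
        names = [
            "Australia",
            "Singapore",
            "New Zealand",
            "Hong Kong SAR",
            "Japan",
            "Malaysia",
            "China",
            "Viet Nam",
            "Philippines",
        ]
        reports = [
            _report(area, total) for area, total in zip(reversed(names), reversed(totals))
        ]
        ranked = rank_areas(reports)
        assert [r.area for r in ranked] == names
        assert [r.rank for r in ranked] == list(range(1, 10))

    def test_ties_share_minimum_rank(self):
        ranked = rank_areas([_report("a", 50), _report("b", 50), _report("c", 40)])
        assert [(r.area, r.rank) for r in ranked] == [("a", 1), ("b", 1), ("c", 3)]

    def test_all_equal_scores_all_rank_one(self):
        ranked = rank_areas([_report(a, 10.0) for a in "abcd"])
        assert all(r.rank == 1 for r in ranked)

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_matches_sort_and_assign_oracle(self, totals):
        reports = [_report(f"a{i}", float(x)) for i, x in enumerate(totals)]
        ranked = {r.area: r.rank for r in rank_areas(reports)}
        # independent oracle: rank = 1 + number of strictly higher scores
        for i, x in enumerate(totals):
            expected = 1 + sum(1 for y in totals if y > x)
            assert ranked[f"a{i}"] == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ScoringError):
            rank_areas([])


def _report(area, total):
    from tease16.scoring import ScoreReport

    return ScoreReport(
        area=area,
        assumption=AssumptionSet("baseline", "fifty_fifty"),
        topic_points={},
        domain_points={},
        total=total,
    )


def test_assumption_grid_has_twelve_members():
    grid = assumption_grid()
    assert len(grid) == 12
    assert len(set(grid)) == 12


def test_display_rounding_half_away_from_zero():
    assert round_half_away(0.35, 1) == 0.4
    assert round_half_away(2.25, 1) == 2.3
    assert round_half_away(-0.35, 1) == -0.4
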