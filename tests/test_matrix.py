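"""Indicator scoring, dimension aggregation and judgment-band classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from progeval import (
    DEFAULT_JUDGMENT_SCALE,
    DimensionSpec,
    EvaluationMatrix,
    Indicator,
    InvalidConfigError,
    InvalidDimensionError,
    InvalidIndicatorError,
    JudgmentScale,
    dimension_achievement,
    indicator_achievement,
    indicator_score,
    judge,
    overall_implementation,
)


def make_ind(expected, observed, weight, id="x", score=None):
    return Indicator(
        id=id, label="", dimension_id="d",
        expected=expected, observed=observed, weight=weight,
        score_override=score,
    )


@st.composite
def indicators(draw, id="x"):
    e = draw(st.integers(min_value=1, max_value=500))
    o = draw(st.integers(min_value=0, max_value=e))
    w = draw(st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    return make_ind(e, o, w, id=id)


class TestIndicatorScore:
    @pytest.mark.parametrize(
        "expected, observed, weight, score",
        [
            (14, 11, 3.4, 2.67),  # trained-worker row of the availability checklist
            (14, 14, 2.5, 2.5),   # full achievement returns the weight
            (14, 0, 1, 0.0),      # nothing observed scores zero
        ],
    )
    def test_examples(self, expected, observed, weight, score):
        assert indicator_score(make_ind(expected, observed, weight)) == pytest.approx(
            score, abs=0.005
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(expected=0, observed=0, weight=1),
            dict(expected=10, observed=11, weight=1),
            dict(expected=10, observed=-1, weight=1),
            dict(expected=10, observed=5, weight=0),
            dict(expected=10, observed=5, weight=1, score=1.5),  # override > W
        ],
    )
    def test_invalid_indicators_rejected(self, kwargs):
        with pytest.raises(InvalidIndicatorError):
            make_ind(**kwargs)

    @given(indicators())
    def test_score_bounded_by_weight(self, ind):
        assert 0 <= indicator_score(ind) <= ind.weight + 1e-12

    def test_score_override_takes_precedence(self):
        ind = make_ind(484, 240, 2.7, score=2.45)
        assert indicator_score(ind) == 2.45
        assert indicator_achievement(ind) == pytest.approx(90.7, abs=0.1)


class TestIndicatorAchievement:
    @pytest.mark.parametrize(
        "expected, observed, achievement",
        [
            (70, 63, 90.0),       # pneumonia-treated compliance row
            (42, 42, 100.0),      # chief-complaint row
            (14, 11, 1100 / 14),  # 78.571..., printed with mixed rounding
        ],
    )
    def test_examples(self, expected, observed, achievement):
        assert indicator_achievement(make_ind(expected, observed, 2.0)) == pytest.approx(
            achievement
        )

    @given(
        e=st.integers(min_value=1, max_value=300),
        o_frac=st.floats(min_value=0, max_value=1),
        w1=st.floats(min_value=0.1, max_value=10),
        w2=st.floats(min_value=0.1, max_value=10),
    )
    def test_achievement_independent_of_weight(self, e, o_frac, w1, w2):
        o = int(round(o_frac * e))
        a1 = indicator_achievement(make_ind(e, o, w1))
        a2 = indicator_achievement(make_ind(e, o, w2))
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert a1 == pytest.approx(100 * o / e, abs=1e-9)


class TestDimensionAchievement:
    def test_single_indicator_equals_its_achievement(self):
        ind = make_ind(14, 11, 3.4)
        dim = DimensionSpec("d", "d", 35.0, (ind,))
        assert dimension_achievement(dim) == pytest.approx(indicator_achievement(ind))

    def test_full_achievement_conserves_100(self):
        inds = tuple(make_ind(10, 10, w, id=f"i{w}") for w in (1.0, 2.5, 0.3))
        assert dimension_achievement(DimensionSpec("d", "d", 10, inds)) == pytest.approx(100.0)

    def test_empty_dimension_rejected(self):
        with pytest.raises(InvalidDimensionError):
            DimensionSpec("d", "d", 10.0, ())
        with pytest.raises(InvalidDimensionError):
            dimension_achievement([])

    @given(st.lists(indicators(), min_size=1, max_size=12))
    def test_equals_weighted_mean_of_achievements(self, inds):
        inds = [make_ind(i.expected, i.observed, i.weight, id=f"i{k}")
                for k, i in enumerate(inds)]
        pooled = dimension_achievement(inds)
        weights = np.array([i.weight for i in inds])
        achievements = np.array([indicator_achievement(i) for i in inds])
        assert pooled == pytest.approx(
            float(np.average(achievements, weights=weights)), abs=1e-9
        )


class TestOverallImplementation:
    def test_published_weighted_combination(self):
        assert overall_implementation((84.2, 83.1, 75.3), (35, 40, 25)) == pytest.approx(
            81.5, abs=0.05
        )

    def test_equal_achievements_pass_through(self):
        assert overall_implementation((77.0, 77.0), (3, 9)) == pytest.approx(77.0)

    def test_single_dimension_identity(self):
        assert overall_implementation((63.2,), (100,)) == pytest.approx(63.2)

    @pytest.mark.parametrize("a, w", [((), ()), ((50.0,), (0.0,)), ((50.0,), (-1,))])
    def test_bad_inputs_rejected(self, a, w):
        with pytest.raises(InvalidConfigError):
            overall_implementation(a, w)

    @given(
        ach=st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=6),
        weights=st.lists(st.floats(min_value=0.1, max_value=50), min_size=6, max_size=6),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_invariant_to_uniform_weight_rescaling(self, ach, weights, scale):
        w = weights[: len(ach)]
        a1 = overall_implementation(ach, w)
        a2 = overall_implementation(ach, [x * scale for x in w])
        assert a1 == pytest.approx(a2, rel=1e-9, abs=1e-9)
        assert min(ach) - 1e-9 <= a1 <= max(ach) + 1e-9


class TestJudge:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.0, "poor"),
            (42.8, "poor"),
            (59.99, "poor"),
            (60.0, "fair"),      # lower-inclusive boundary
            (74.99, "fair"),
            (75.0, "good"),
            (81.5, "good"),      # the published overall judgment
            (84.99, "good"),
            (85.0, "very good"),
            (100.0, "very good"),
        ],
    )
    def test_band_edges(self, value, label):
        assert judge(value) == label

    @pytest.mark.parametrize("value", [-0.01, 100.01, float("nan")])
    def test_out_of_domain_rejected(self, value):
        with pytest.raises(InvalidConfigError):
            judge(value)

    @given(st.floats(min_value=0, max_value=100))
    def test_total_on_unit_interval(self, value):
        label = judge(value)
        assert label in DEFAULT_JUDGMENT_SCALE.labels
        # exactly one band contains the value
        hits = [
            (lo <= value < hi) or (hi == 100.0 and value == 100.0)
            for lo, hi, _ in DEFAULT_JUDGMENT_SCALE.bands
        ]
        assert sum(hits) == 1

    @pytest.mark.parametrize(
        "bands",
        [
            ((0, 50, "a"), (55, 100, "b")),   # gap
            ((0, 60, "a"), (50, 100, "b")),   # overlap
            ((10, 100, "a"),),                # does not start at 0
            ((0, 100, "a"), (100, 90, "b")),  # inverted
        ],
    )
    def test_malformed_scales_rejected(self, bands):
        with pytest.raises(InvalidConfigError):
            JudgmentScale(bands=bands)


class TestEvaluationMatrix:
    def test_duplicate_indicator_ids_rejected(self):
        ind = make_ind(10, 5, 1.0, id="dup")
        dims = [
            DimensionSpec("a", "a", 10, (ind,)),
            DimensionSpec("b", "b", 10, (make_ind(10, 5, 1.0, id="dup"),)),
        ]
        with pytest.raises(InvalidConfigError):
            EvaluationMatrix(dimensions=dims)

    def test_report_covers_every_indicator_once(self):
        inds = [make_ind(10, k, 1.0, id=f"i{k}") for k in range(5)]
        matrix = EvaluationMatrix.from_indicators(inds, {"d": 10.0})
        report = matrix.evaluate()
        assert sorted(report.indicator_table["id"]) == sorted(i.id for i in inds)
        assert 0.0 <= report.overall_achievement <= 100.0
        assert report.overall_judgment in DEFAULT_JUDGMENT_SCALE.labels
        assert "Overall implementation" in report.summary()
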