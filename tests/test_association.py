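"""Odds ratios, screening, logistic regression and sample-size planning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from progeval import (
    DegenerateOutcomeError,
    InvalidConfigError,
    TwoByTwoTable,
    ZeroCellError,
    categorical_crude_ors,
    crude_odds_ratio,
    fit_logistic,
    sample_size_proportion,
    screen_bivariable,
)

cells = st.integers(min_value=1, max_value=500)


def table_to_frame(a, b, c, d):
    """Expand a 2x2 table into respondent-level records."""
    return pd.DataFrame(
        {
            "satisfied": [1] * a + [0] * b + [1] * c + [0] * d,
            "exposed": ["yes"] * (a + b) + ["no"] * (c + d),
        }
    )


class TestCrudeOddsRatio:
    @pytest.mark.parametrize(
        "a, b, c, d, or_, ci",
        [
            # primary education vs illiterate
            (64, 39, 220, 32, 0.24, (0.14, 0.41)),
            # prescribed drugs received vs not
            (325, 84, 44, 31, 2.72, (1.62, 4.57)),
        ],
    )
    def test_published_examples(self, a, b, c, d, or_, ci):
        r = crude_odds_ratio(TwoByTwoTable(a, b, c, d))
        assert r.odds_ratio == pytest.approx(or_, abs=0.01)
        assert r.ci_low == pytest.approx(ci[0], abs=0.01)
        assert r.ci_high == pytest.approx(ci[1], abs=0.01)
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_symmetric_table_is_null(self):
        r = crude_odds_ratio(TwoByTwoTable(7, 7, 7, 7))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_cell_is_an_error_without_correction(self):
        with pytest.raises(ZeroCellError):
            crude_odds_ratio(TwoByTwoTable(10, 0, 5, 5))

    def test_haldane_anscombe_correction_flagged(self):
        r = crude_odds_ratio(TwoByTwoTable(10, 0, 5, 5), continuity=True)
        assert r.corrected
        assert math.isfinite(r.odds_ratio) and r.odds_ratio > 1

    def test_negative_or_empty_tables_rejected(self):
        with pytest.raises(InvalidConfigError):
            TwoByTwoTable(-1, 2, 3, 4)
        with pytest.raises(InvalidConfigError):
            TwoByTwoTable(0, 0, 0, 0)

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(min_value=2, max_value=9))
    def test_row_scaling_invariance(self, a, b, c, d, k):
        r1 = crude_odds_ratio(TwoByTwoTable(a, b, c, d))
        r2 = crude_odds_ratio(TwoByTwoTable(a * k, b * k, c, d))
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(min_value=2, max_value=9))
    def test_interval_contains_or_and_shrinks(self, a, b, c, d, k):
        r1 = crude_odds_ratio(TwoByTwoTable(a, b, c, d))
        r2 = crude_odds_ratio(TwoByTwoTable(a * k, b * k, c * k, d * k))
        assert r1.ci_low < r1.odds_ratio < r1.ci_high
        assert (r2.ci_high / r2.ci_low) < (r1.ci_high / r1.ci_low) + 1e-12


class TestCategoricalCrudeOrs:
    counts = {
        "illiterate": (220, 32),
        "read_write": (63, 16),
        "primary": (64, 39),
        "secondary": (19, 17),
        "college": (3, 11),
    }

    def test_education_levels_match_published_table(self):
        results = categorical_crude_ors(self.counts, "illiterate", variable="education")
        by_level = {r.level_label: r for r in results}
        assert by_level["illiterate"].is_reference
        assert by_level["illiterate"].odds_ratio == 1.0
        assert by_level["college"].odds_ratio == pytest.approx(0.04, abs=0.01)
        assert by_level["read_write"].odds_ratio == pytest.approx(0.57, abs=0.01)

    def test_two_levels_reduce_to_single_table(self):
        counts = {"<30min": (351, 101), ">=30min": (18, 14)}
        results = categorical_crude_ors(counts, ">=30min")
        direct = crude_odds_ratio(TwoByTwoTable(351, 101, 18, 14))
        assert results[1].odds_ratio == pytest.approx(direct.odds_ratio)
        assert results[1].odds_ratio == pytest.approx(2.70, abs=0.01)

    def test_unknown_reference_rejected(self):
        with pytest.raises(InvalidConfigError):
            categorical_crude_ors(self.counts, "graduate")


class TestFitLogistic:
    def test_intercept_only_recovers_logit_of_proportion(self):
        frame = pd.DataFrame({"satisfied": [1] * 30 + [0] * 10})
        fit = fit_logistic(frame, "satisfied", [])
        assert fit.params["const"] == pytest.approx(math.log(30 / 10), abs=1e-6)
        assert fit.converged

    def test_single_binary_covariate_equals_closed_form(self):
        frame = table_to_frame(64, 39, 220, 32)
        fit = fit_logistic(frame, "satisfied", ["exposed"],
                           reference_levels={"exposed": "no"})
        closed = crude_odds_ratio(TwoByTwoTable(64, 39, 220, 32))
        assert float(np.exp(fit.params["exposed[yes]"])) == pytest.approx(
            closed.odds_ratio, rel=1e-6
        )
        # Wald interval agrees with the Woolf interval for a 2x2 table
        assert fit.or_conf_int.loc["exposed[yes]", 0] == pytest.approx(
            closed.ci_low, rel=1e-4
        )

    def test_separation_is_warned_and_flagged(self):
        frame = pd.DataFrame(
            {"satisfied": [1] * 20 + [0] * 20,
             "exposed": ["yes"] * 20 + ["no"] * 20}
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(frame, "satisfied", ["exposed"])
        assert fit.separation_suspected

    def test_constant_outcome_rejected(self):
        frame = pd.DataFrame({"satisfied": [1] * 10, "x": ["a", "b"] * 5})
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(frame, "satisfied", ["x"])


class TestScreening:
    def test_alpha_one_retains_all_varying_candidates(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "satisfied": rng.integers(0, 2, 200),
                "a": rng.choice(["x", "y"], 200),
                "b": rng.choice(["u", "v", "w"], 200),
            }
        )
        retained = screen_bivariable(frame, "satisfied", ["a", "b"], alpha_screen=1.0)
        assert set(retained) == {"a", "b"}

    def test_constant_candidate_excluded_with_warning(self):
        frame = pd.DataFrame(
            {"satisfied": [1, 0] * 50, "fixed": ["only"] * 100,
             "real": ["a", "a", "b", "b"] * 25}
        )
        with pytest.warns(UserWarning, match="constant"):
            retained = screen_bivariable(frame, "satisfied", ["fixed", "real"],
                                         alpha_screen=1.0)
        assert "fixed" not in retained

    def test_true_effect_retained_at_moderate_n(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.choice(["no", "yes"], n)
        logit = -0.5 + 1.2 * (x == "yes")
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        noise = rng.choice(["a", "b"], n)
        frame = pd.DataFrame({"satisfied": y.astype(int), "x": x, "noise": noise})
        retained = screen_bivariable(frame, "satisfied", ["x", "noise"])
        assert "x" in retained
        assert retained["x"] < 0.001

    def test_null_covariate_retained_at_screening_rate(self):
        """A no-effect covariate passes the p<0.25 screen about 25% of the time."""
        rng = np.random.default_rng(29)
        n, reps = 50, 400
        kept = 0
        for _ in range(reps):
            frame = pd.DataFrame(
                {
                    "satisfied": rng.integers(0, 2, n),
                    "x": rng.choice(["a", "b"], n),
                }
            )
            try:
                kept += "x" in screen_bivariable(frame, "satisfied", ["x"])
            except DegenerateOutcomeError:
                reps -= 1
        assert kept / reps == pytest.approx(0.25, abs=0.06)


class TestSampleSize:
    def test_published_survey_plan(self):
        assert sample_size_proportion(0.74, 0.04, 0.95, 0.10) == 508

    def test_tiny_hand_computed_case(self):
        # 1.96^2 * 0.25 / 0.25 = 3.84 -> ceil 4
        assert sample_size_proportion(0.5, 0.5, 0.95, 0.0) == 4

    def test_zero_nonresponse_is_base_size(self):
        base = sample_size_proportion(0.3, 0.05, 0.95, 0.0)
        assert base == math.ceil(1.959963984540054**2 * 0.3 * 0.7 / 0.05**2)

    @given(
        p=st.floats(min_value=0.05, max_value=0.95),
        d1=st.floats(min_value=0.01, max_value=0.2),
        d2=st.floats(min_value=0.01, max_value=0.2),
    )
    def test_decreasing_in_margin(self, p, d1, d2):
        lo, hi = sorted((d1, d2))
        assert sample_size_proportion(p, lo) >= sample_size_proportion(p, hi)

    @given(p=st.floats(min_value=0.01, max_value=0.99))
    def test_maximized_at_half(self, p):
        assert sample_size_proportion(p, 0.04) <= sample_size_proportion(0.5, 0.04)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p=0.0, d=0.1),
            dict(p=1.0, d=0.1),
            dict(p=0.5, d=0.0),
            dict(p=0.5, d=1.0),
            dict(p=0.5, d=0.1, nonresponse=1.0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(InvalidConfigError):
            sample_size_proportion(**kwargs)
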