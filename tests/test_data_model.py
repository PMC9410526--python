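import numpy as np
import pandas as pd
import pytest

from delmm import (
    DesignSpec,
    OutcomeSeries,
    ParameterVector,
    TermSpec,
    build_design,
    eval_term,
    read_series_csv,
    write_series_csv,
)
from delmm.data_model import POWER_BOUND


def term(base, power, outer=1.0):
    return TermSpec(bases=(base,), inner_powers=(power,), outer_power=outer)


class TestEvalTerm:
    @pytest.mark.parametrize(
        "spec, row, expected",
        [
            (term("time", 7.8), {"time": 1.0}, 1.0),  # 1^p = 1
            (term("time", 1.0), {"time": 1e13}, POWER_BOUND),  # overflow cap
            (
                TermSpec(("x", "time"), (1.0, 1.0), outer_power=2.0),
                {"x": 2.0, "time": 3.0},
                36.0,  # (2*3)^2
            ),
            (term("x", -5.0), {"x": 0.0}, POWER_BOUND),  # 0^negative capped
            (term("x", 0.0), {"x": 0.0}, 1.0),  # 0^0 := 1
            (term("x", 3.0), {"x": 0.0}, 0.0),
        ],
    )
    def test_examples(self, spec, row, expected):
        assert eval_term(spec, row) == pytest.approx(expected)

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            eval_term(term("x", 0.5), {"x": -1.0})

    def test_monotone_in_base_for_positive_power(self):
        values = [eval_term(term("x", 1.7), {"x": v}) for v in (0.5, 1.0, 2.0, 5.0)]
        assert values == sorted(values)

    def test_inner_product_bounded_before_outer_power(self):
        # (1e13 * 1)^2 must cap the inner product first, then re-cap
        t = TermSpec(("x", "time"), (1.0, 1.0), outer_power=2.0)
        assert eval_term(t, {"x": 1e13, "time": 1.0}) == POWER_BOUND


@pytest.fixture
def series():
    return OutcomeSeries(
        times=np.array([1, 2, 3]),
        outcomes=np.array([0.0, 1.0, 0.0]),
        support=np.array([0.0, 1.0]),
        covariates={"x": np.array([1.0, 1.0, 1.0])},
    )


class TestBuildDesign:
    def test_disp_intercept_only(self, series):
        spec = DesignSpec("censored_poisson", prob_intercept=True)
        _, xd = build_design(series, spec)
        np.testing.assert_array_equal(xd, np.ones((3, 1)))

    def test_intercept_plus_time(self, series):
        spec = DesignSpec(
            "censored_poisson", prob_terms=(term("time", 1.0),)
        )
        x, _ = build_design(series, spec)
        np.testing.assert_allclose(x, [[1, 1], [1, 2], [1, 3]])

    def test_zero_intercept_unit_time_row(self, series):
        # time = 1 maps to (1, 1) under powers 0.2 and -1
        spec = DesignSpec(
            "censored_poisson",
            prob_terms=(term("time", 0.2), term("time", -1.0)),
            prob_intercept=False,
        )
        x, _ = build_design(series, spec)
        np.testing.assert_allclose(x[0], [1.0, 1.0])

    def test_constant_covariate_gives_constant_column(self, series):
        spec = DesignSpec("censored_poisson", prob_terms=(term("x", 2.3),))
        x, _ = build_design(series, spec)
        assert np.ptp(x[:, 1]) == 0.0

    def test_unknown_covariate_raises(self, series):
        spec = DesignSpec("censored_poisson", prob_terms=(term("nope", 1.0),))
        with pytest.raises(KeyError):
            build_design(series, spec)

    def test_empty_probability_design_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            DesignSpec("censored_poisson", prob_intercept=False)


class TestOutcomeSeries:
    def test_validation_errors(self):
        with pytest.raises(ValueError, match="integers"):
            OutcomeSeries(np.array([1.5, 2.0]), np.array([0.0, 1.0]),
                          np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="increasing"):
            OutcomeSeries(np.array([2, 2]), np.array([0.0, 1.0]),
                          np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="member of the support"):
            OutcomeSeries(np.array([1, 2]), np.array([0.0, 3.0]),
                          np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="support"):
            OutcomeSeries(np.array([1, 2]), np.array([0.0, 0.0]),
                          np.array([0.0]))

    def test_subset_preserves_gaps(self, series):
        sub = series.subset([0, 2])
        np.testing.assert_array_equal(sub.times, [1, 3])
        np.testing.assert_array_equal(sub.covariates["x"], [1.0, 1.0])

    def test_csv_round_trip(self, series, tmp_path):
        path = tmp_path / "s.csv"
        write_series_csv(series, path)
        back = read_series_csv(path)
        np.testing.assert_array_equal(back.times, series.times)
        np.testing.assert_array_equal(back.outcomes, series.outcomes)
        np.testing.assert_array_equal(back.covariates["x"],
                                      series.covariates["x"])

    def test_category_index(self, series):
        np.testing.assert_array_equal(series.category_index(), [0, 1, 0])


class TestParameterVector:
    def test_flat_round_trip(self):
        spec = DesignSpec("multinomial", prob_terms=(term("time", 1.0),))
        theta = ParameterVector(
            beta=np.arange(6.0), beta_disp=np.array([0.5]), rho=0.3
        )
        theta.validate(spec, k=3)
        flat = theta.to_flat()
        back = ParameterVector.from_flat(flat, spec, k=3)
        np.testing.assert_array_equal(back.beta, theta.beta)
        assert back.rho == theta.rho

    def test_layout_counts(self):
        spec = DesignSpec("ordinal", prob_terms=(term("time", 1.0),))
        assert spec.n_beta(4) == 4 + 2
        spec2 = DesignSpec("multinomial", prob_terms=(term("time", 1.0),))
        assert spec2.n_beta(4) == 4 * 2
        spec3 = DesignSpec("censored_poisson", prob_terms=(term("time", 1.0),))
        assert spec3.n_beta(4) == 2

    def test_rho_bound(self):
        with pytest.raises(ValueError):
            ParameterVector(beta=np.zeros(1), beta_disp=np.zeros(1), rho=1.0)
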