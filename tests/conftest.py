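import numpy as np
import pytest

from delmm import DesignSpec, OutcomeSeries, ParameterVector, TermSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_series(rng, n=10, k=3, x_max=3.0):
    """Small random series with an ``x`` covariate, for derivative tests."""
    times = np.sort(rng.choice(np.arange(1, 4 * n), size=n, replace=False))
    support = np.sort(rng.choice(np.arange(0.0, 10.0), size=k + 1, replace=False))
    outcomes = rng.choice(support, size=n)
    while np.unique(outcomes).size < 2:
        outcomes = rng.choice(support, size=n)
    return OutcomeSeries(
        times=times,
        outcomes=outcomes,
        support=support,
        covariates={"x": rng.uniform(0.0, x_max, size=n)},
    )


def make_spec(ptype, disp=True):
    return DesignSpec(
        probability_type=ptype,
        prob_terms=(TermSpec(("x",), (1.0,)),),
        prob_intercept=True,
        disp_terms=(TermSpec(("time",), (1.0,)),) if disp else (),
        disp_intercept=True,
    )


def make_theta(rng, series, spec, rho=None):
    k = series.k
    if spec.probability_type == "ordinal":
        alpha = np.sort(rng.normal(0.0, 1.0, size=k))
        beta = np.concatenate(
            [alpha, rng.normal(0.0, 0.3, spec.n_prob_columns)]
        )
    else:
        beta = rng.normal(0.0, 0.3, spec.n_beta(k))
    if rho is None:
        rho = float(rng.uniform(-0.7, 0.7))
    return ParameterVector(
        beta=beta,
        beta_disp=rng.normal(0.0, 0.05, spec.n_disp_columns),
        rho=rho,
    )
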