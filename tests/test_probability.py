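import numpy as np
import pytest

from delmm import (
    censored_poisson_moments,
    moments,
    multinomial_moments,
    ordinal_moments,
)

ENGINES = ("multinomial", "ordinal", "censored_poisson")


def n_beta(ptype, k, j):
    return {"multinomial": k * j, "ordinal": k + j, "censored_poisson": j}[ptype]


def random_beta(rng, ptype, k, j, scale=0.5):
    if ptype == "ordinal":
        return np.concatenate(
            [np.sort(rng.normal(0, 1, k)), rng.normal(0, scale, j)]
        )
    return rng.normal(0, scale, n_beta(ptype, k, j))


class TestFrozenExamples:
    def test_multinomial_zero_beta_uniform(self):
        b = multinomial_moments(np.array([[1.0, 2.0]]), np.zeros(6),
                                np.arange(0.0, 4.0))
        np.testing.assert_allclose(b.probs, 0.25)

    def test_multinomial_k2_mean_var(self):
        # equal thirds on support (0,1,2): mu = 1, Var = 2/3
        b = multinomial_moments(np.array([[1.0]]), np.zeros(2),
                                np.array([0.0, 1.0, 2.0]))
        assert b.mean[0] == pytest.approx(1.0)
        assert b.var[0] == pytest.approx(2.0 / 3.0)

    def test_ordinal_zero_params_mass_at_extremes(self):
        # all cumulative probabilities 0.5 => interior categories empty
        k = 4
        b = ordinal_moments(np.array([[0.0]]), np.zeros(k + 1),
                            np.arange(0.0, k + 1.0))
        np.testing.assert_allclose(b.probs[0, 0], 0.5)
        np.testing.assert_allclose(b.probs[0, -1], 0.5)
        np.testing.assert_allclose(b.probs[0, 1:-1], 0.0, atol=1e-15)

    def test_ordinal_k1_bernoulli(self):
        b = ordinal_moments(np.array([[1.0]]), np.zeros(2),
                            np.array([0.0, 1.0]))
        np.testing.assert_allclose(b.probs[0], [0.5, 0.5])
        assert b.mean[0] == pytest.approx(0.5)
        assert b.var[0] == pytest.approx(0.25)

    def test_censored_poisson_unit_rate(self):
        # lambda = 1, K = 2: p = (1/e, 1/e, 1 - 2/e)
        b = censored_poisson_moments(np.array([[1.0]]), np.array([0.0]),
                                     np.array([0.0, 1.0, 2.0]))
        e = np.exp(-1.0)
        np.testing.assert_allclose(b.probs[0], [e, e, 1 - 2 * e])
        assert b.mean[0] == pytest.approx(0.89636168, abs=1e-6)

    def test_censored_poisson_degenerate_small_rate(self):
        b = censored_poisson_moments(np.array([[1.0]]), np.array([-30.0]),
                                     np.array([1.0, 2.0, 3.0]))
        assert b.probs[0, 0] == pytest.approx(1.0)
        assert b.mean[0] == pytest.approx(1.0)
        assert b.var[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 50.0])
    def test_censored_poisson_normalized_on_rating_support(self, lam):
        b = censored_poisson_moments(
            np.array([[1.0]]), np.array([np.log(lam)]), np.arange(1.0, 10.0)
        )
        assert b.probs[0].sum() == pytest.approx(1.0, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("ptype", ENGINES)
    def test_normalization_and_moment_consistency(self, rng, ptype):
        for _ in range(50):
            k = int(rng.integers(1, 5))
            j = 2
            support = np.sort(
                rng.choice(np.arange(0.0, 12.0), size=k + 1, replace=False)
            )
            x = rng.uniform(0, 3, size=(6, j))
            beta = random_beta(rng, ptype, k, j)
            b = moments(ptype, x, beta, support)
            np.testing.assert_allclose(b.probs.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(b.probs >= -1e-12)
            assert np.all(b.var >= -1e-12)
            assert np.all(b.mean >= support[0] - 1e-9)
            assert np.all(b.mean <= support[-1] + 1e-9)
            # two textbook forms of the variance agree
            alt = np.einsum(
                "tu,tu->t", (support[None, :] - b.mean[:, None]) ** 2, b.probs
            )
            np.testing.assert_allclose(b.var, alt, atol=1e-10)

    def test_ordinal_increasing_alpha_positive_probs(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 6))
            alpha = np.sort(rng.normal(0, 1.5, k))
            # strictly increasing intercepts
            alpha += np.arange(k) * 1e-3
            beta = np.concatenate([alpha, rng.normal(0, 0.5, 2)])
            b = ordinal_moments(
                rng.uniform(0, 2, (4, 2)), beta, np.arange(0.0, k + 1.0)
            )
            assert b.valid
            assert np.all(b.probs > 0)

    def test_ordinal_unordered_alpha_flagged(self):
        beta = np.array([1.0, -1.0, 0.0])  # decreasing intercepts
        b = ordinal_moments(np.array([[0.0]]), beta, np.array([0.0, 1.0, 2.0]))
        assert not b.valid

    def test_multinomial_matches_ordinal_binary(self, rng):
        # K = 1: both engines are binary logistic up to the sign of the
        # logit (multinomial models P(y=v1), ordinal models P(y<=v0))
        for _ in range(10):
            z = rng.uniform(0, 2, (5, 1))
            x = np.column_stack([np.ones(5), z])
            bm = rng.normal(0, 1, 2)  # multinomial intercept + slope
            m = multinomial_moments(x, bm, np.array([0.0, 1.0]))
            # ordinal logit of P(y <= v0) is the negated multinomial logit
            o = ordinal_moments(z, np.array([-bm[0], -bm[1]]),
                                np.array([0.0, 1.0]))
            np.testing.assert_allclose(m.probs, o.probs, atol=1e-12)
            np.testing.assert_allclose(m.mean, o.mean, atol=1e-12)
            np.testing.assert_allclose(m.var, o.var, atol=1e-12)


class TestDerivativesAgainstFiniteDifferences:
    @pytest.mark.parametrize("ptype", ENGINES)
    def test_moment_derivatives(self, rng, ptype):
        eps = 1e-6
        for _ in range(40):
            k = int(rng.integers(1, 4))
            j = 2
            support = np.sort(
                rng.choice(np.arange(0.0, 10.0), size=k + 1, replace=False)
            )
            x = rng.uniform(0, 3, size=(3, j))
            beta = random_beta(rng, ptype, k, j, scale=0.3)
            b = moments(ptype, x, beta, support)
            p = beta.size
            dmean_fd = np.empty((3, p))
            dvar_fd = np.empty((3, p))
            d2mean_fd = np.empty((3, p, p))
            d2var_fd = np.empty((3, p, p))
            for a in range(p):
                step = np.zeros(p)
                step[a] = eps
                hi = moments(ptype, x, beta + step, support)
                lo = moments(ptype, x, beta - step, support)
                dmean_fd[:, a] = (hi.mean - lo.mean) / (2 * eps)
                dvar_fd[:, a] = (hi.var - lo.var) / (2 * eps)
                d2mean_fd[:, a] = (hi.dmean - lo.dmean) / (2 * eps)
                d2var_fd[:, a] = (hi.dvar - lo.dvar) / (2 * eps)
            scale = 1.0 + np.abs(dmean_fd)
            assert np.max(np.abs(b.dmean - dmean_fd) / scale) < 1e-6
            scale = 1.0 + np.abs(dvar_fd)
            assert np.max(np.abs(b.dvar - dvar_fd) / scale) < 1e-6
            scale = 1.0 + np.abs(d2mean_fd)
            assert np.max(np.abs(b.d2mean - d2mean_fd) / scale) < 1e-5
            scale = 1.0 + np.abs(d2var_fd)
            assert np.max(np.abs(b.d2var - d2var_fd) / scale) < 1e-5
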