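"""Probability engines: multinomial, ordinal, and censored Poisson.

Each engine maps a row of the probability design matrix and the
coefficient vector beta to the per-time category probabilities p_u over
the outcome support v_0 < ... < v_K, together with the mean

    mu = sum_u v_u p_u,

the variance

    Var(y) = sum_u v_u^2 p_u - mu^2,

and analytic first and second derivatives of mu and Var with respect to
beta.  These moments and derivatives are the only interface the
likelihood core needs; all chain rules through the standardized
residuals are assembled there, identically for the three engines.

Derivatives here are derived directly from each link function and are
validated against central finite differences in the test-suite rather
than transcribed from any secondary source.

Engine parameterizations
------------------------
multinomial
    Generalized logits against the reference category v_0:
    p_u ~ exp(x'beta_u) for u = 1..K with beta laid out as K blocks of
    J slopes, so every category has its own coefficient vector.
ordinal
    Cumulative logits (proportional odds): logit P(y <= v_u) =
    alpha_u + x'b for u = 0..K-1, with K intercepts followed by J shared
    slopes.  Unordered alpha can produce negative category
    probabilities; the bundle flags this instead of raising so a line
    search can back off.
censored_poisson
    log lambda = x'beta; Poisson probabilities on the *category index*
    u = 0..K-1 with the top category absorbing the remaining mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "MomentBundle",
    "multinomial_moments",
    "ordinal_moments",
    "censored_poisson_moments",
    "moments",
]

#: Linear predictors are clamped here before exponentiation so that a wild
#: Newton step cannot overflow doubles; the clamp is far outside any region
#: a converged fit visits.
LINPRED_CLAMP = 700.0


@dataclass(frozen=True)
class MomentBundle:
    """Per-time probabilities, moments, and beta-derivatives.

    Arrays are vectorized over the N observation times: ``probs`` is
    N x (K+1); ``mean``/``var`` are length N; ``dmean``/``dvar`` are
    N x P and ``d2mean``/``d2var`` are N x P x P where P = len(beta).
    ``valid`` is False when some category probability is negative
    (possible for the ordinal engine with unordered intercepts).
    """

    probs: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    dmean: np.ndarray
    dvar: np.ndarray
    d2mean: np.ndarray
    d2var: np.ndarray
    valid: bool = True


def _clamp(eta: np.ndarray) -> np.ndarray:
    return np.clip(eta, -LINPRED_CLAMP, LINPRED_CLAMP)


def _bundle_from_probs(
    probs: np.ndarray,
    dprobs: np.ndarray,
    d2probs: np.ndarray,
    support: np.ndarray,
    valid: bool = True,
) -> MomentBundle:
    """Assemble mean/variance (and derivatives) from category probabilities."""
    v = np.asarray(support, dtype=float)
    v2 = v * v
    mean = probs @ v
    e2 = probs @ v2
    var = e2 - mean**2
    dmean = np.einsum("tup,u->tp", dprobs, v)
    de2 = np.einsum("tup,u->tp", dprobs, v2)
    dvar = de2 - 2.0 * mean[:, None] * dmean
    d2mean = np.einsum("tupq,u->tpq", d2probs, v)
    d2e2 = np.einsum("tupq,u->tpq", d2probs, v2)
    d2var = (
        d2e2
        - 2.0 * dmean[:, :, None] * dmean[:, None, :]
        - 2.0 * mean[:, None, None] * d2mean
    )
    return MomentBundle(
        probs=probs,
        mean=mean,
        var=var,
        dmean=dmean,
        dvar=dvar,
        d2mean=d2mean,
        d2var=d2var,
        valid=valid,
    )


def multinomial_moments(
    x: np.ndarray, beta: np.ndarray, support: np.ndarray
) -> MomentBundle:
    """Generalized-logit (multinomial) engine.

    ``beta`` is the flat (K*J,) vector of K per-category slope blocks.
    Probabilities use a log-sum-exp stabilized softmax over the K+1
    logits (the reference logit is identically 0).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.asarray(support, dtype=float)
    n, j = x.shape
    k = v.size - 1
    b = np.asarray(beta, dtype=float).reshape(k, j)
    eta = np.concatenate(
        [np.zeros((n, 1)), _clamp(x @ b.T)], axis=1
    )  # N x (K+1), reference first
    eta = eta - eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    probs = ex / ex.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite multinomial probabilities")

    # Softmax derivatives w.r.t. the K free logits eta_w (w = 1..K):
    #   dp_u/deta_w  = p_u (delta_{uw} - p_w)
    #   d2p_u/deta_w deta_w' =
    #       p_u [(delta_{uw}-p_w)(delta_{uw'}-p_w') - p_w (delta_{ww'}-p_w')]
    pw = probs[:, 1:]  # N x K
    delta_uw = np.zeros((k + 1, k))
    delta_uw[1:, :] = np.eye(k)
    a_uw = delta_uw[None, :, :] - pw[:, None, :]  # N x (K+1) x K
    dp_deta = probs[:, :, None] * a_uw
    eye_k = np.eye(k)
    b_ww = eye_k[None, :, :] - pw[:, None, :]  # N x K x K, delta_{ww'} - p_w'
    d2p_deta = probs[:, :, None, None] * (
        a_uw[:, :, :, None] * a_uw[:, :, None, :]
        - pw[:, None, :, None] * b_ww[:, None, :, :]
    )
    # Chain to beta_{w,j}: multiply by x_j (and x_j') and flatten (w, j).
    dprobs = (dp_deta[:, :, :, None] * x[:, None, None, :]).reshape(
        n, k + 1, k * j
    )
    d2probs = (
        d2p_deta[:, :, :, None, :, None]
        * x[:, None, None, :, None, None]
        * x[:, None, None, None, None, :]
    ).reshape(n, k + 1, k * j, k * j)
    return _bundle_from_probs(probs, dprobs, d2probs, v)


def ordinal_moments(
    x: np.ndarray, beta: np.ndarray, support: np.ndarray
) -> MomentBundle:
    """Cumulative-logit (proportional-odds) engine.

    ``beta`` = (alpha_0..alpha_{K-1}, b_1..b_J).  Cumulative
    probabilities c_u = expit(alpha_u + x'b) for u < K with c_K = 1 and
    c_{-1} = 0 are differenced into category probabilities.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.asarray(support, dtype=float)
    n, j = x.shape
    k = v.size - 1
    beta = np.asarray(beta, dtype=float).reshape(-1)
    alpha, slope = beta[:k], beta[k:]
    eta = _clamp(alpha[None, :] + (x @ slope)[:, None])  # N x K
    c = expit(eta)
    cfull = np.concatenate([np.zeros((n, 1)), c, np.ones((n, 1))], axis=1)
    probs = np.diff(cfull, axis=1)  # N x (K+1)
    # Tolerance is loose enough to let a line search traverse boundary
    # optima where an empty category ties adjacent intercepts (p_u = 0
    # up to roundoff); the objective touches probabilities only through
    # the mean and variance, so a -1e-8 excursion is harmless.
    valid = bool(np.all(probs >= -1e-8))

    g = c * (1.0 - c)  # dc/deta
    gp = g * (1.0 - 2.0 * c)  # d2c/deta2
    # dc_u w.r.t. theta = (alpha, b): alpha_w -> delta_{uw} g_u; b_j -> x_j g_u
    p = k + j
    dc = np.zeros((n, k, p))
    dc[:, np.arange(k), np.arange(k)] = g
    dc[:, :, k:] = g[:, :, None] * x[:, None, :]
    # d2c_u: gp_u times (dtheta eta_u) outer (dtheta eta_u)
    deta = np.zeros((n, k, p))
    deta[:, np.arange(k), np.arange(k)] = 1.0
    deta[:, :, k:] = x[:, None, :]
    d2c = gp[:, :, None, None] * deta[:, :, :, None] * deta[:, :, None, :]
    # p_u = c_u - c_{u-1}; pad with zero-derivative boundaries c_{-1}, c_K.
    zero = np.zeros((n, 1, p))
    dcfull = np.concatenate([zero, dc, zero], axis=1)
    dprobs = np.diff(dcfull, axis=1)
    zero2 = np.zeros((n, 1, p, p))
    d2cfull = np.concatenate([zero2, d2c, zero2], axis=1)
    d2probs = np.diff(d2cfull, axis=1)
    return _bundle_from_probs(probs, dprobs, d2probs, v, valid=valid)


def censored_poisson_moments(
    x: np.ndarray, beta: np.ndarray, support: np.ndarray
) -> MomentBundle:
    """Censored-Poisson engine: Poisson on category indices, top censored.

    log lambda = x'beta; p_u = exp(-lambda) lambda^u / u! for u < K and
    p_K = 1 - sum_{u<K} p_u.  The index entering the Poisson mass is the
    category position u, not the support value v_u, so any ordered
    numeric support can be used.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.asarray(support, dtype=float)
    n, j = x.shape
    k = v.size - 1
    beta = np.asarray(beta, dtype=float).reshape(-1)
    # the rate predictor gets a tighter clamp than the generic +-700:
    # lambda beyond e^30 is already complete top-category saturation for
    # any realistic K, and lambda^2 must stay inside double range in the
    # second-derivative formulas
    lam = np.exp(np.clip(x @ beta, -30.0, 30.0))  # N
    u = np.arange(k, dtype=float)  # categories 0..K-1
    with np.errstate(divide="ignore"):
        logpm = -lam[:, None] + u[None, :] * np.log(lam)[:, None] - gammaln(
            u + 1.0
        )[None, :]
    pm = np.exp(logpm)  # N x K, Poisson pmf at 0..K-1
    top = 1.0 - pm.sum(axis=1)
    # Guard tiny negative mass from roundoff when lambda is huge.
    top = np.maximum(top, 0.0)
    probs = np.concatenate([pm, top[:, None]], axis=1)

    # dp_u/dbeta_j = x_j p_u (u - lambda); top category via negative sum.
    um = u[None, :] - lam[:, None]  # N x K
    dpm_deta = pm * um  # d/d(x'beta)
    d2pm_deta = pm * (um * um - lam[:, None])
    dprobs = np.concatenate(
        [
            dpm_deta[:, :, None] * x[:, None, :],
            -(dpm_deta.sum(axis=1))[:, None, None] * x[:, None, :],
        ],
        axis=1,
    )
    xx = x[:, :, None] * x[:, None, :]  # N x J x J
    d2probs = np.concatenate(
        [
            d2pm_deta[:, :, None, None] * xx[:, None, :, :],
            -(d2pm_deta.sum(axis=1))[:, None, None, None] * xx[:, None, :, :],
        ],
        axis=1,
    )
    return _bundle_from_probs(probs, dprobs, d2probs, v)


_ENGINES = {
    "multinomial": multinomial_moments,
    "ordinal": ordinal_moments,
    "censored_poisson": censored_poisson_moments,
}


def moments(
    probability_type: str,
    x: np.ndarray,
    beta: np.ndarray,
    support: np.ndarray,
) -> MomentBundle:
    """Dispatch to the engine named by ``probability_type``."""
    try:
        engine = _ENGINES[probability_type]
    except KeyError:
        raise ValueError(f"unknown probability type {probability_type!r}")
    return engine(x, beta, support)
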