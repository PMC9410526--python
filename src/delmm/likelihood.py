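"""Likelihood-like objective, gradient, Hessian, parameter covariance.

The estimation objective treats the standardized residuals of the
discrete outcome as if multivariate normal:

    ell(theta) = -stde' R(rho)^-1 stde / 2 - log|R(rho)| / 2
                 - sum log phi_t / 2 - sum log Var_t / 2
                 - N log(2 pi) / 2

with stde_t = (y_t - mu_t) / sigma_t, sigma_t = sqrt(phi_t Var_t), and
log phi_t = x'_t beta' the modeled dispersion.  This is a
pseudo-likelihood: the multivariate normal density evaluated at the
residual vector with covariance DIAG(sigma) R DIAG(sigma), not the true
discrete-data likelihood.  Maximizing it in *all* parameters (mean,
dispersion, correlation) at once is what distinguishes this approach
from GEE-style estimating equations.

The gradient and Hessian are assembled generically from the per-time
moment derivatives supplied by the probability engines: writing
W_a = (dVar/d beta_a)/Var, the standardized residual has

    d stde / d beta_a   = -(d mu/d beta_a)/sigma - stde W_a / 2
    d stde / d beta'_j  = -stde x'_j / 2

and second derivatives follow by one more application of the chain rule.
Every block is validated against finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .correlation import Ar1Workspace, ar1_build
from .data_model import DesignSpec, OutcomeSeries, ParameterVector, build_design
from .probability import MomentBundle, moments

__all__ = [
    "ModelState",
    "evaluate_ell",
    "gradient",
    "hessian",
    "parameter_covariance",
    "VARIANCE_FLOOR",
]

#: Additive smoothing of the per-time variance: Var + floor is used in
#: every log and square root.  Unlike a hard max-clamp this keeps the
#: objective differentiable (analytic derivatives remain exact) while
#: still capping the density spike that a collapsing variance with a
#: near-zero residual would otherwise produce.
VARIANCE_FLOOR = 1e-10

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelState:
    """Everything needed to evaluate ell and its derivatives at theta."""

    series: OutcomeSeries
    spec: DesignSpec
    theta: ParameterVector
    x: np.ndarray  # N x J probability design
    xd: np.ndarray  # N x J' dispersion design
    bundle: MomentBundle
    phi: np.ndarray  # dispersions
    sigma: np.ndarray  # extended standard deviations
    e: np.ndarray  # residuals y - mu
    stde: np.ndarray  # standardized residuals
    ar1: Ar1Workspace
    ell: float
    valid: bool


def evaluate_ell(
    series: OutcomeSeries,
    spec: DesignSpec,
    theta: ParameterVector,
    subset: Sequence[int] | None = None,
) -> ModelState:
    """Evaluate the objective (optionally on a subset of observations).

    Subsets keep their actual observation times, so the AR(1)
    correlation sub-matrix reflects true gaps -- required for coherent
    fold-deleted evaluations in cross-validation.
    """
    if subset is not None:
        series = series.subset(subset)
    theta.validate(spec, series.k)
    x, xd = build_design(series, spec)
    bundle = moments(spec.probability_type, x, theta.beta, series.support)
    var = bundle.var + VARIANCE_FLOOR
    if xd.shape[1]:
        phi = np.exp(np.clip(xd @ theta.beta_disp, -700.0, 700.0))
    else:
        phi = np.ones(series.n)
    sigma = np.sqrt(phi * var)
    e = series.outcomes - bundle.mean
    stde = e / sigma
    ar1 = ar1_build(series.times, theta.rho)
    quad = float(stde @ ar1.Rinv @ stde)
    ell = -0.5 * (
        quad
        + ar1.logdetR
        + float(np.sum(np.log(phi)))
        + float(np.sum(np.log(var)))
        + series.n * _LOG2PI
    )
    valid = bool(bundle.valid and np.isfinite(ell))
    if not valid:
        ell = -np.inf
    return ModelState(
        series=series,
        spec=spec,
        theta=theta,
        x=x,
        xd=xd,
        bundle=bundle,
        phi=phi,
        sigma=sigma,
        e=e,
        stde=stde,
        ar1=ar1,
        ell=ell,
        valid=valid,
    )


def _stde_derivs(state: ModelState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First derivatives of stde and the W ratios.

    Returns (ds_beta: N x P, ds_disp: N x J', W: N x P).
    """
    b = state.bundle
    var = b.var + VARIANCE_FLOOR
    w = b.dvar / var[:, None]  # N x P
    ds_beta = -b.dmean / state.sigma[:, None] - 0.5 * state.stde[:, None] * w
    ds_disp = -0.5 * state.stde[:, None] * state.xd
    return ds_beta, ds_disp, w


def gradient(state: ModelState) -> np.ndarray:
    """Full gradient (d ell/d beta, d ell/d beta', d ell/d rho)."""
    ds_beta, ds_disp, w = _stde_derivs(state)
    ri = state.ar1.Rinv
    q = ri @ state.stde
    g_beta = -(q @ ds_beta) - 0.5 * w.sum(axis=0)
    g_disp = -(q @ ds_disp) - 0.5 * state.xd.sum(axis=0)
    # dR^-1 s = -R^-1 dR R^-1 s = -A q, so s' dR^-1 s = -s' A q.
    a, dlogdet, _ = state.ar1.rho_scalars()
    g_rho = 0.5 * float(state.stde @ (a @ q)) - 0.5 * dlogdet
    return np.concatenate([g_beta, g_disp, [g_rho]])


def hessian(state: ModelState) -> np.ndarray:
    """Full Hessian over (beta, beta', rho), symmetric by construction."""
    b = state.bundle
    s = state.stde
    sigma = state.sigma
    xd = state.xd
    ri = state.ar1.Rinv
    var = b.var + VARIANCE_FLOOR
    ds_beta, ds_disp, w = _stde_derivs(state)
    q = ri @ s
    p = ds_beta.shape[1]
    jd = xd.shape[1]

    # W_ab = d W_a / d beta_b
    w2 = b.d2var / var[:, None, None] - (
        b.dvar[:, :, None] * b.dvar[:, None, :]
    ) / (var**2)[:, None, None]
    # d2 stde / d beta_a d beta_b
    d2s_bb = (
        -b.d2mean / sigma[:, None, None]
        + 0.5 * b.dmean[:, :, None] * w[:, None, :] / sigma[:, None, None]
        - 0.5 * w[:, :, None] * ds_beta[:, None, :]
        - 0.5 * s[:, None, None] * w2
    )
    # d2 stde / d beta_a d beta'_j = -(x'_j/2) d stde/d beta_a
    d2s_bd = -0.5 * ds_beta[:, :, None] * xd[:, None, :]
    # d2 stde / d beta'_j d beta'_j' = x'_j x'_j' stde / 4
    d2s_dd = 0.25 * s[:, None, None] * xd[:, :, None] * xd[:, None, :]

    h_bb = (
        -(ds_beta.T @ ri @ ds_beta)
        - np.einsum("t,tab->ab", q, d2s_bb)
        - 0.5 * w2.sum(axis=0)
    )
    h_bd = -(ds_beta.T @ ri @ ds_disp) - np.einsum("t,taj->aj", q, d2s_bd)
    h_dd = -(ds_disp.T @ ri @ ds_disp) - np.einsum("t,tjk->jk", q, d2s_dd)

    # rho blocks via matrix-vector algebra: with A = R^-1 dR, q = R^-1 s,
    # dR^-1 s = -A q and s' d2R^-1 s = 2 (dR q)' A q - q' d2R q.
    a, _, d2logdet = state.ar1.rho_scalars()
    aq = a @ q
    h_brho = ds_beta.T @ aq
    h_drho = ds_disp.T @ aq
    s_d2ri_s = 2.0 * float((state.ar1.dR @ q) @ aq) - float(
        q @ (state.ar1.d2R @ q)
    )
    h_rho = -0.5 * s_d2ri_s - 0.5 * d2logdet

    dim = p + jd + 1
    h = np.zeros((dim, dim))
    h[:p, :p] = h_bb
    h[:p, p : p + jd] = h_bd
    h[p : p + jd, :p] = h_bd.T
    h[p : p + jd, p : p + jd] = h_dd
    h[:p, -1] = h_brho
    h[-1, :p] = h_brho
    h[p : p + jd, -1] = h_drho
    h[-1, p : p + jd] = h_drho
    h[-1, -1] = h_rho
    return 0.5 * (h + h.T)


def parameter_covariance(h: np.ndarray) -> np.ndarray:
    """Covariance of theta-hat as -H^-1 at the maximizer.

    Raises ``ValueError`` when the Hessian is singular or not negative
    definite, in which case no covariance should be reported.
    """
    h = np.asarray(h, dtype=float)
    try:
        cho = linalg.cho_factor(-h, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise ValueError(
            "Hessian is not negative definite; covariance withheld"
        ) from err
    cov = linalg.cho_solve(cho, np.eye(h.shape[0]), check_finite=False)
    return 0.5 * (cov + cov.T)
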