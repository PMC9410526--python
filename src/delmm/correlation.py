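"""Spatial AR(1) working correlation over observed integer times.

The correlation between observations d = |t(i) - t(i')| integer time
units apart is rho**d, so gaps between observation days are respected
(unlike index-based AR(1)).  The workspace carries the matrix, its
inverse and log-determinant, and first/second derivatives in rho, all of
which enter the likelihood gradient and Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["Ar1Workspace", "ar1_build", "ar1_inv_derivs", "RHO_BOUND"]

#: The objective is defined on |rho| < 1; the solver projects onto this
#: closed sub-interval to keep R safely positive definite.
RHO_BOUND = 0.99


@dataclass(frozen=True)
class Ar1Workspace:
    """AR(1) correlation matrix with inverse, log-det, and rho-derivatives."""

    rho: float
    times: np.ndarray
    R: np.ndarray
    Rinv: np.ndarray
    logdetR: float
    dR: np.ndarray
    d2R: np.ndarray

    def rho_scalars(self) -> tuple[np.ndarray, float, float]:
        """(R^-1 dR, dlog|R|/drho, d2log|R|/drho2), cached.

        The matrix A = R^-1 dR is the single O(N^3) product the
        likelihood derivatives need; everything else in the rho blocks
        reduces to matrix-vector work given A.
        """
        cached = getattr(self, "_rho_cache", None)
        if cached is None:
            a = self.Rinv @ self.dR
            dlogdet = float(np.trace(a))
            d2logdet = float(
                -np.sum(a * a.T) + np.sum(self.Rinv * self.d2R)
            )
            cached = (a, dlogdet, d2logdet)
            object.__setattr__(self, "_rho_cache", cached)
        return cached


def ar1_build(times: np.ndarray, rho: float) -> Ar1Workspace:
    """Build the workspace at ``rho`` for sorted distinct integer times.

    Entrywise, with d = |t(i) - t(i')|:
    R = rho**d (diagonal 1), dR = d rho**(d-1), d2R = d(d-1) rho**(d-2),
    with the diagonal of dR and d2R zero.  The inverse and log
    determinant use a Cholesky factorization (R is SPD for |rho| < 1).
    """
    times = np.asarray(times, dtype=float).reshape(-1)
    if np.unique(times).size != times.size:
        raise ValueError("times must be distinct")
    rho = float(rho)
    if abs(rho) > RHO_BOUND:
        raise ValueError(f"|rho| must be <= {RHO_BOUND}")
    d = np.abs(times[:, None] - times[None, :])
    off = d > 0
    # rho**d with rho possibly 0: 0**0 on the diagonal must give 1, and
    # the d-1 / d-2 exponents below use the same convention.
    R = _safe_pow(rho, d)
    dR = np.where(off, d * _safe_pow(rho, d - 1.0), 0.0)
    d2R = np.where(off & (d > 1), d * (d - 1.0) * _safe_pow(rho, d - 2.0), 0.0)
    cho = linalg.cho_factor(R, lower=True, check_finite=False)
    rinv = linalg.cho_solve(cho, np.eye(times.size), check_finite=False)
    rinv = 0.5 * (rinv + rinv.T)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return Ar1Workspace(
        rho=rho, times=times, R=R, Rinv=rinv, logdetR=logdet, dR=dR, d2R=d2R
    )


def _safe_pow(rho: float, expo: np.ndarray) -> np.ndarray:
    expo = np.asarray(expo, dtype=float)
    if rho == 0.0:
        return np.where(expo == 0.0, 1.0, np.where(expo > 0, 0.0, np.nan))
    if rho < 0.0:
        # integer exponents only; sign from parity
        mag = np.abs(rho) ** expo
        sign = np.where(np.mod(expo, 2.0) == 0.0, 1.0, -1.0)
        return sign * mag
    return rho**expo


def ar1_inv_derivs(
    ws: Ar1Workspace,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """First/second rho-derivatives of R^-1 and log|R|.

    dR^-1 = -R^-1 dR R^-1
    d2R^-1 = 2 R^-1 dR R^-1 dR R^-1 - R^-1 d2R R^-1
    dlog|R| = trace(R^-1 dR)
    d2log|R| = -trace(R^-1 dR R^-1 dR) + trace(R^-1 d2R)
    """
    ri, d2r = ws.Rinv, ws.d2R
    a, dlogdet, d2logdet = ws.rho_scalars()
    dri = -(a @ ri)
    d2ri = 2.0 * (a @ a @ ri) - ri @ d2r @ ri
    dri = 0.5 * (dri + dri.T)
    d2ri = 0.5 * (d2ri + d2ri.T)
    return dri, d2ri, dlogdet, d2logdet
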