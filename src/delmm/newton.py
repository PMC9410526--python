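"""Safeguarded Newton maximization of the likelihood-like objective.

Solves g(theta) = 0 via theta <- theta - H^-1 g with three safeguards on
top of the raw iteration: (i) if the Newton direction is not an ascent
direction (H not negative definite there) a ridge H - tau I is grown
until it is; (ii) the step is halved while the objective decreases or
the state is invalid (e.g. negative ordinal category probabilities);
(iii) rho is projected back into [-RHO_BOUND, RHO_BOUND] after every
step.  Estimation is staged by default: (beta, beta') are fit first with
rho = 0, then rho is released -- the correlation surface is much better
behaved near a good mean/dispersion fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .correlation import RHO_BOUND
from .data_model import DesignSpec, OutcomeSeries, ParameterVector
from .likelihood import evaluate_ell, gradient, hessian, parameter_covariance

__all__ = ["FitOptions", "FitResult", "fit", "initial_parameters"]


@dataclass(frozen=True)
class FitOptions:
    """Solver controls.

    ``fix_rho`` pins the autocorrelation (use 0.0 for the independence
    working model); ``staged`` first fits coefficients at rho = 0 before
    releasing rho.
    """

    grad_tol: float = 1e-6
    #: scale-invariant companion to grad_tol: converged when the Newton
    #: decrement g' (-H)^-1 g (the predicted objective gain of the next
    #: step) falls below this, which handles strongly curved objectives
    #: where max|g| stays above grad_tol at machine-precision optima
    decrement_tol: float = 1e-9
    step_tol: float = 1e-8
    max_iter: int = 200
    max_halvings: int = 30
    rho_bound: float = RHO_BOUND
    staged: bool = True
    fix_rho: float | None = None


@dataclass(frozen=True)
class FitResult:
    theta: ParameterVector
    ell: float
    gradient_norm: float
    converged: bool
    n_iter: int
    covariance: np.ndarray | None
    se: np.ndarray | None
    message: str
    trace: list = field(default_factory=list)

    def z_values(self) -> np.ndarray | None:
        """Estimate / SE for each parameter.

        These are unreliable after adaptive model selection (selection
        inflates apparent significance); report them only for fixed
        models of prior interest.
        """
        if self.se is None:
            return None
        return self.theta.to_flat() / self.se


def initial_parameters(
    series: OutcomeSeries, spec: DesignSpec
) -> ParameterVector:
    """Marginal-distribution starting values; all slopes zero, rho = 0.

    censored Poisson: intercept (or first column's coefficient scaled to
    act like one) from log of the mean category index; multinomial:
    empirical log-odds versus v_0 with +0.5 smoothing; ordinal:
    empirical cumulative logits.
    """
    k = series.k
    cat = series.category_index().astype(float)
    j = spec.n_prob_columns
    ptype = spec.probability_type
    if ptype == "censored_poisson":
        beta = np.zeros(j)
        lam0 = float(np.clip(cat.mean(), 0.05, k - 0.05))
        if spec.prob_intercept:
            beta[0] = np.log(lam0)
    elif ptype == "multinomial":
        counts = np.array(
            [np.sum(cat == u) for u in range(k + 1)], dtype=float
        ) + 0.5
        beta = np.zeros((k, j))
        if spec.prob_intercept:
            beta[:, 0] = np.log(counts[1:] / counts[0])
        beta = beta.reshape(-1)
    else:  # ordinal
        counts = np.array(
            [np.sum(cat == u) for u in range(k + 1)], dtype=float
        ) + 0.5
        cum = np.cumsum(counts)[:-1] / counts.sum()
        alpha = np.log(cum / (1.0 - cum))
        beta = np.concatenate([alpha, np.zeros(j)])
    return ParameterVector(
        beta=beta, beta_disp=np.zeros(spec.n_disp_columns), rho=0.0
    )


def _project(flat: np.ndarray, bound: float, fix_rho: float | None) -> np.ndarray:
    out = flat.copy()
    out[-1] = fix_rho if fix_rho is not None else np.clip(out[-1], -bound, bound)
    return out


def _tie_projection(state, spec: DesignSpec, k: int):
    """Averaging projector for boundary-tied ordinal intercepts.

    With freely parameterized cumulative-logit intercepts the objective
    is boundary-attracted: driving a category probability to zero ties
    the adjacent intercepts, and the unconstrained gradient then points
    into the invalid region at every scale.  Treating an empty category
    (p_u = 0 up to roundoff at every time) as an active equality
    constraint, steps and gradients are projected so the tied
    intercepts alpha_{u-1}, alpha_u move jointly.  Returns None when no
    tie is active or for the other engines.
    """
    if spec.probability_type != "ordinal":
        return None
    # interior category u has p_u = c_u - c_{u-1}, which vanishes for
    # every time exactly when alpha_{u-1} and alpha_u coincide (the
    # shared slope cancels), so ties are detected on the intercept gaps
    alpha = state.theta.beta[:k]
    tied = [u for u in range(1, k) if abs(alpha[u] - alpha[u - 1]) < 1e-4]
    if not tied:
        return None
    groups: list[set[int]] = []
    for u in tied:
        pair = {u - 1, u}
        merged = None
        for grp in groups:
            if grp & pair:
                grp |= pair
                merged = grp
                break
        if merged is None:
            groups.append(pair)
    return groups


def _merge_basis(groups, dim: int) -> np.ndarray:
    """Columns spanning the subspace where tied intercepts move jointly."""
    grouped = sorted({i for grp in groups for i in grp})
    cols = []
    for grp in groups:
        col = np.zeros(dim)
        col[sorted(grp)] = 1.0
        cols.append(col)
    for i in range(dim):
        if i not in grouped:
            col = np.zeros(dim)
            col[i] = 1.0
            cols.append(col)
    return np.column_stack(cols)


def _newton_loop(
    series: OutcomeSeries,
    spec: DesignSpec,
    flat: np.ndarray,
    free: np.ndarray,
    options: FitOptions,
    trace: list,
) -> tuple[np.ndarray, float, float, bool, int]:
    """Maximize over the coordinates marked free; returns final state."""
    k = series.k
    fix_rho = None if free[-1] else flat[-1]

    def state_at(vec: np.ndarray):
        return evaluate_ell(series, spec, ParameterVector.from_flat(vec, spec, k))

    state = state_at(flat)
    if not state.valid:
        raise ValueError("initial parameters give an invalid model state")
    converged = False
    it = 0
    gnorm = np.inf
    for it in range(1, options.max_iter + 1):
        g = gradient(state)[free]
        groups = _tie_projection(state, spec, k)
        if groups is not None:
            basis = _merge_basis(groups, int(free.sum()))
            g_eff = basis @ (basis.T @ g / basis.sum(axis=0))
        else:
            basis = None
            g_eff = g
        gnorm = float(np.max(np.abs(g_eff))) if g.size else 0.0
        if gnorm < options.grad_tol:
            converged = True
            break
        h = hessian(state)[np.ix_(free, free)]
        step = _ascent_direction(h, g)
        norm = float(np.max(np.abs(step)))
        if norm > 50.0:  # near-singular H can propose absurd steps
            step *= 50.0 / norm

        def try_step(direction):
            scale = 1.0
            dnorm = float(np.max(np.abs(direction)))
            for _ in range(options.max_halvings + 1):
                if scale * dnorm < options.step_tol:
                    break  # steps this small cannot make real progress
                cand = flat.copy()
                cand[free] = flat[free] + scale * direction
                cand = _project(cand, options.rho_bound, fix_rho)
                try:
                    cand_state = state_at(cand)
                except (ValueError, FloatingPointError):
                    cand_state = None
                # Monotone up to roundoff: near the optimum a full Newton
                # step can change ell by less than machine epsilon.
                if cand_state is not None and cand_state.valid and (
                    cand_state.ell
                    >= state.ell - 1e-13 * (1.0 + abs(state.ell))
                ):
                    return cand, cand_state, scale
                scale *= 0.5
            return None, None, 0.0

        if basis is not None:
            # near boundary ties the raw Newton/gradient directions
            # point across the validity boundary and only micro-steps
            # survive; a Newton step solved in the merged basis (tied
            # intercepts move jointly) makes real progress along it
            red_step = basis @ _ascent_direction(
                basis.T @ h @ basis, basis.T @ g
            )
            rnorm = float(np.max(np.abs(red_step)))
            if rnorm > 50.0:
                red_step *= 50.0 / rnorm
            attempts = [
                red_step,
                step,
                g_eff / (1.0 + np.linalg.norm(g_eff)),
                g / (1.0 + np.linalg.norm(g)),
            ]
        else:
            attempts = [step, g / (1.0 + np.linalg.norm(g))]
        decrement = float(g @ attempts[0])
        if 0.0 <= decrement < options.decrement_tol:
            converged = True
            break
        cand = None
        for direction in attempts:
            c, c_state, c_scale = try_step(direction)
            if c is None:
                continue
            if c_scale == 1.0 and direction is attempts[0]:
                # clean full Newton-type step: take it (quadratic phase)
                cand, cand_state, scale = c, c_state, c_scale
                break
            if cand is None or c_state.ell > cand_state.ell:
                cand, cand_state, scale = c, c_state, c_scale
        if cand is None:
            break
        delta = float(np.max(np.abs(cand - flat)))
        flat, state = cand, cand_state
        trace.append((state.ell, scale, gnorm))
        if delta < options.step_tol:
            g = gradient(state)[free]
            groups = _tie_projection(state, spec, k)
            if groups is not None:
                basis = _merge_basis(groups, int(free.sum()))
                g_eff = basis @ (basis.T @ g / basis.sum(axis=0))
            else:
                g_eff = g
            gnorm = float(np.max(np.abs(g_eff))) if g.size else 0.0
            converged = gnorm < max(options.grad_tol, 1e-4)
            break
    return flat, state.ell, gnorm, converged, it


def _ascent_direction(h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Newton step -H^-1 g, ridged to an ascent direction if needed."""
    tau = 0.0
    eye = np.eye(h.shape[0])
    for _ in range(40):
        try:
            step = np.linalg.solve(h - tau * eye, -g)
        except np.linalg.LinAlgError:
            step = None
        if step is not None and np.dot(step, g) > 0 and np.all(
            np.isfinite(step)
        ):
            return step
        tau = max(2.0 * tau, 1e-4 * (1.0 + float(np.max(np.abs(np.diag(h))))))
    return g / (1.0 + np.linalg.norm(g))  # steepest ascent fallback


def _snap_ordinal_ties(flat: np.ndarray, k: int, tol: float = 1e-6) -> np.ndarray:
    """Equalize boundary-tied ordinal intercepts exactly.

    A run of intercepts within ``tol`` of each other marks categories
    the fit has emptied; setting the run to its mean makes those
    category probabilities exactly zero at every predictor value, so
    the estimate stays valid when evaluated on held-out observations.
    """
    out = flat.copy()
    alpha = out[:k]
    start = 0
    for u in range(1, k + 1):
        if u == k or abs(alpha[u] - alpha[u - 1]) >= tol:
            if u - start > 1:
                alpha[start:u] = alpha[start:u].mean()
            start = u
    out[:k] = alpha
    return out


def _release_ordinal_ties(series, spec, flat, k):
    """KKT check at a tied point: nudge apart a profitable tie, if any.

    For a run of exactly equal intercepts, splitting it raises the
    upper part (valid direction; the emptied category regains positive
    probability).  If the directional derivative of ell for some split
    is positive, return the nudged parameter vector; otherwise None.
    """
    state = evaluate_ell(series, spec, ParameterVector.from_flat(flat, spec, k))
    g = gradient(state)
    alpha = flat[:k]
    start = 0
    best = None
    for u in range(1, k + 1):
        if u == k or alpha[u] != alpha[u - 1]:
            if u - start > 1:
                for split in range(start + 1, u):
                    up = float(np.sum(g[split:u]))  # raise upper part
                    dn = -float(np.sum(g[start:split]))  # lower lower part
                    gain = max(up, dn)
                    if gain > 1e-6 and (best is None or gain > best[0]):
                        best = (gain, start, split, u, up >= dn)
            start = u
    if best is None:
        return None
    _, start, split, end, raise_upper = best
    out = flat.copy()
    if raise_upper:
        out[split:end] += 2e-4
    else:
        out[start:split] -= 2e-4
    return out


def fit(
    series: OutcomeSeries,
    spec: DesignSpec,
    init: ParameterVector | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit theta by safeguarded Newton iteration.

    Never raises on non-convergence; inspect ``converged``.  Raises
    ``ValueError`` for structurally hopeless data (a single observed
    outcome value has zero variance everywhere).
    """
    options = options or FitOptions()
    if series.n < 2:
        raise ValueError("fitting requires at least two observations")
    if np.unique(series.outcomes).size < 2:
        raise ValueError(
            "outcomes take a single value; the variance is identically zero"
        )
    dim = spec.n_parameters(series.k, include_rho=True)
    if series.n <= dim - 1:
        import warnings

        warnings.warn(
            f"N={series.n} observations for {dim} parameters; "
            "estimates may be unstable",
            stacklevel=2,
        )
    theta0 = init if init is not None else initial_parameters(series, spec)
    theta0.validate(spec, series.k)
    flat = theta0.to_flat()
    trace: list = []
    nb = spec.n_beta(series.k)
    nd = spec.n_disp_columns
    total_iter = 0

    if options.fix_rho is not None:
        flat[-1] = float(options.fix_rho)
        free = np.ones(flat.size, dtype=bool)
        free[-1] = False
        flat, ell, gnorm, converged, it = _newton_loop(
            series, spec, flat, free, options, trace
        )
        total_iter += it
    else:
        if options.staged:
            free = np.ones(flat.size, dtype=bool)
            free[-1] = False
            stage_opts = replace(options, max_iter=max(options.max_iter // 2, 25))
            flat, _, _, _, it = _newton_loop(
                series, spec, flat, free, stage_opts, trace
            )
            total_iter += it
        free = np.ones(flat.size, dtype=bool)
        flat, ell, gnorm, converged, it = _newton_loop(
            series, spec, flat, free, options, trace
        )
        total_iter += it

    if spec.probability_type == "ordinal":
        # Boundary-tied intercepts approach equality only geometrically;
        # snap near-ties exactly and re-solve in the constrained
        # subspace, then check the KKT condition for each tie: if
        # separating a tied run in the valid direction (which makes the
        # emptied category's probability positive) would increase ell,
        # nudge it apart and re-solve.
        for _ in range(6):
            snapped = _snap_ordinal_ties(flat, series.k, tol=1e-4)
            if not np.array_equal(snapped, flat) or not converged:
                flat = snapped
                flat, ell, gnorm, converged, it = _newton_loop(
                    series, spec, flat, free, options, trace
                )
                total_iter += it
                continue
            released = _release_ordinal_ties(series, spec, flat, series.k)
            if released is None:
                break
            flat = released
            flat, ell, gnorm, converged, it = _newton_loop(
                series, spec, flat, free, options, trace
            )
            total_iter += it
        flat = _snap_ordinal_ties(flat, series.k, tol=1e-4)
        ell = evaluate_ell(
            series, spec, ParameterVector.from_flat(flat, spec, series.k)
        ).ell
    theta_hat = ParameterVector.from_flat(flat, spec, series.k)
    if options.fix_rho is None and abs(theta_hat.rho) >= options.rho_bound:
        converged = False
    cov = None
    se = None
    message = "converged" if converged else "did not converge"
    if converged:
        state = evaluate_ell(series, spec, theta_hat)
        h = hessian(state)
        if options.fix_rho is not None:
            keep = np.ones(flat.size, dtype=bool)
            keep[-1] = False
            h_free = h[np.ix_(keep, keep)]
        else:
            h_free = h
        try:
            cov_free = parameter_covariance(h_free)
            if options.fix_rho is not None:
                cov = np.zeros((flat.size, flat.size))
                cov[np.ix_(keep, keep)] = cov_free
            else:
                cov = cov_free
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except ValueError as err:
            message = f"converged; {err}"
    return FitResult(
        theta=theta_hat,
        ell=float(ell),
        gradient_norm=float(gnorm),
        converged=bool(converged),
        n_iter=total_iter,
        covariance=cov,
        se=se,
        message=message,
        trace=trace,
    )
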