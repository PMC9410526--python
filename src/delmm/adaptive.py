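"""Adaptive two-phase model search over fractional-polynomial designs.

The search grows and then prunes power-transform terms for both the
probability design and the dispersion design, steered entirely by the
k-fold LCV score (computed with one fixed fold seed so all candidate
models are comparable):

* EXPANSION -- repeatedly, over candidate terms (each base predictor,
  plus pairwise geometric combinations of in-model bases when enabled),
  run a one-dimensional power search (coarse offset grid, then step
  halving to a fixed resolution) and add the best-scoring term, first to
  the probability design and then to the dispersion design; stop when
  the best relative LCV gain falls below ``tol_expand``.
* CONTRACTION -- repeatedly remove the term (or an intercept: the
  selected models of interest are often zero-intercept) whose removal
  costs the least relative LCV, accepting while the loss is below
  ``tol_contract``, optionally re-refining the remaining powers after
  each removal.

The best-LCV specification encountered anywhere in the search is
returned.  The search is deterministic given (data, options, seeds).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import DesignSpec, OutcomeSeries, TermSpec
from .lcv import LCVResult, lcv_score
from .newton import FitOptions, FitResult, fit

__all__ = ["AdaptiveOptions", "AdaptiveResult", "TraceStep", "adaptive_fit"]


@dataclass(frozen=True)
class AdaptiveOptions:
    """Controls for the adaptive search.

    ``power_grid`` holds the coarse offsets tried on either side of the
    current power; ``power_resolution`` is the step-halving floor.
    Tolerances are *relative* LCV changes (0.001 = 0.1%).
    """

    k: int = 5
    seed: int = 1
    geometric: bool = False
    tol_expand: float = 0.001
    tol_contract: float = 0.001
    power_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 5.0)
    power_resolution: float = 0.01
    max_prob_terms: int = 4
    max_disp_terms: int = 3
    refine_after_removal: bool = True
    fit_options: FitOptions = field(default_factory=FitOptions)


@dataclass(frozen=True)
class TraceStep:
    action: str  # add / remove / adjust-power
    target: str  # prob / disp
    term: str
    lcv_before: float
    lcv_after: float


@dataclass(frozen=True)
class AdaptiveResult:
    selected: DesignSpec
    fit: FitResult
    lcv: LCVResult
    trace: tuple[TraceStep, ...]


class _Scorer:
    """Caches LCV scores per design spec; failures score -inf."""

    def __init__(self, series: OutcomeSeries, options: AdaptiveOptions):
        self.series = series
        self.options = options
        self.cache: dict[DesignSpec, float] = {}

    def __call__(self, spec: DesignSpec) -> float:
        if spec in self.cache:
            return self.cache[spec]
        o = self.options
        try:
            res = lcv_score(
                self.series, spec, k=o.k, seed=o.seed, fit_options=o.fit_options
            )
            score = res.score if np.isfinite(res.score) else -np.inf
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as err:
            warnings.warn(f"candidate {spec} skipped: {err}", stacklevel=2)
            score = -np.inf
        self.cache[spec] = score
        return score


def _rel_gain(new: float, old: float) -> float:
    if not np.isfinite(new):
        return -np.inf
    if old <= 0 or not np.isfinite(old):
        return np.inf if new > old else -np.inf
    return (new - old) / old


def _set_term(
    spec: DesignSpec, side: str, index: int | None, term: TermSpec
) -> DesignSpec:
    terms = list(spec.prob_terms if side == "prob" else spec.disp_terms)
    if index is None:
        terms.append(term)
    else:
        terms[index] = term
    if side == "prob":
        return replace(spec, prob_terms=tuple(terms))
    return replace(spec, disp_terms=tuple(terms))


def _power_search(
    scorer: _Scorer,
    spec: DesignSpec,
    side: str,
    index: int | None,
    term: TermSpec,
    options: AdaptiveOptions,
) -> tuple[TermSpec, float]:
    """1-D search over the term's power: coarse grid then step halving."""
    res = options.power_resolution
    p0 = term.search_power
    candidates = {round(p0, 10)}
    for off in options.power_grid:
        candidates.add(round(p0 + off, 10))
        candidates.add(round(p0 - off, 10))
    best_p, best_score = None, -np.inf
    for p in sorted(candidates):
        if abs(p) < res:  # a zero power duplicates the intercept column
            continue
        score = scorer(_set_term(spec, side, index, term.with_power(p)))
        if score > best_score:
            best_p, best_score = p, score
    if best_p is None:
        return term, -np.inf
    step = 0.5
    while step >= res:
        moved = False
        for p in (best_p + step, best_p - step):
            p = round(p, 10)
            if abs(p) < res:
                continue
            score = scorer(_set_term(spec, side, index, term.with_power(p)))
            if score > best_score:
                best_p, best_score, moved = p, score, True
        if not moved:
            step /= 2.0
    return term.with_power(round(best_p, 10)), best_score


def _expansion_candidates(
    spec: DesignSpec, side: str, base_predictors: tuple[str, ...], geometric: bool
) -> list[TermSpec]:
    terms = spec.prob_terms if side == "prob" else spec.disp_terms
    cands = [TermSpec(bases=(b,), inner_powers=(1.0,)) for b in base_predictors]
    if geometric:
        # Pairwise products of bases already in the model (with their
        # current inner powers), outer power searched.
        singles = {
            t.bases[0]: t.inner_powers[0] for t in terms if not t.is_geometric
        }
        for b1, b2 in itertools.combinations(sorted(singles), 2):
            cands.append(
                TermSpec(
                    bases=(b1, b2),
                    inner_powers=(singles[b1], singles[b2]),
                    outer_power=1.0,
                )
            )
    existing = {(t.bases, t.inner_powers if t.is_geometric else None) for t in terms}
    return [
        c
        for c in cands
        if (c.bases, c.inner_powers if c.is_geometric else None) not in existing
    ]


def _try_expand(
    scorer: _Scorer,
    spec: DesignSpec,
    side: str,
    base_predictors: tuple[str, ...],
    current: float,
    options: AdaptiveOptions,
    trace: list,
) -> tuple[DesignSpec, float, bool]:
    limit = options.max_prob_terms if side == "prob" else options.max_disp_terms
    n_terms = len(spec.prob_terms if side == "prob" else spec.disp_terms)
    if n_terms >= limit:
        return spec, current, False
    best: tuple[DesignSpec, float, TermSpec] | None = None
    for cand in _expansion_candidates(
        spec, side, base_predictors, options.geometric
    ):
        term, score = _power_search(scorer, spec, side, None, cand, options)
        if best is None or score > best[1]:
            best = (_set_term(spec, side, None, term), score, term)
    if best is None:
        return spec, current, False
    new_spec, score, term = best
    if _rel_gain(score, current) > options.tol_expand:
        trace.append(TraceStep("add", side, term.label(), current, score))
        return new_spec, score, True
    return spec, current, False


def _refine_powers(
    scorer: _Scorer, spec: DesignSpec, current: float, options: AdaptiveOptions, trace: list
) -> tuple[DesignSpec, float]:
    for side in ("prob", "disp"):
        terms = spec.prob_terms if side == "prob" else spec.disp_terms
        for i, term in enumerate(terms):
            new_term, score = _power_search(scorer, spec, side, i, term, options)
            if score > current:
                trace.append(
                    TraceStep(
                        "adjust-power", side, new_term.label(), current, score
                    )
                )
                spec = _set_term(spec, side, i, new_term)
                current = score
    return spec, current


def _removal_candidates(spec: DesignSpec) -> list[tuple[str, str, DesignSpec]]:
    out = []
    for i, t in enumerate(spec.prob_terms):
        if spec.n_prob_columns > 1:
            terms = spec.prob_terms[:i] + spec.prob_terms[i + 1 :]
            out.append(("prob", t.label(), replace(spec, prob_terms=terms)))
    if spec.prob_intercept and spec.prob_terms:
        out.append(("prob", "intercept", replace(spec, prob_intercept=False)))
    for i, t in enumerate(spec.disp_terms):
        terms = spec.disp_terms[:i] + spec.disp_terms[i + 1 :]
        out.append(("disp", t.label(), replace(spec, disp_terms=terms)))
    if spec.disp_intercept and spec.disp_terms:
        out.append(("disp", "intercept", replace(spec, disp_intercept=False)))
    return out


def adaptive_fit(
    series: OutcomeSeries,
    base_predictors: tuple[str, ...] | list[str],
    probability_type: str = "censored_poisson",
    options: AdaptiveOptions | None = None,
) -> AdaptiveResult:
    """Run the two-phase adaptive search and fit the selected model."""
    options = options or AdaptiveOptions()
    base_predictors = tuple(base_predictors)
    for b in base_predictors:
        series.column(b)  # raise early on unknown covariates
    scorer = _Scorer(series, options)
    trace: list[TraceStep] = []

    spec = DesignSpec(probability_type=probability_type)
    current = scorer(spec)
    best_spec, best_score = spec, current

    # EXPANSION: probability side first, then dispersion, until no gain.
    while True:
        spec, current, grew_p = _try_expand(
            scorer, spec, "prob", base_predictors, current, options, trace
        )
        spec, current, grew_d = _try_expand(
            scorer, spec, "disp", base_predictors, current, options, trace
        )
        if current > best_score:
            best_spec, best_score = spec, current
        if not (grew_p or grew_d):
            break

    # CONTRACTION: cheapest removal first, while relative loss tolerable.
    while True:
        cands = _removal_candidates(spec)
        if not cands:
            break
        best_rm = None
        for side, label, cand_spec in cands:
            score = scorer(cand_spec)
            if best_rm is None or score > best_rm[3]:
                best_rm = (side, label, cand_spec, score)
        side, label, cand_spec, score = best_rm
        loss = -_rel_gain(score, current)
        if loss < options.tol_contract:
            trace.append(TraceStep("remove", side, label, current, score))
            spec, current = cand_spec, score
            if options.refine_after_removal:
                spec, current = _refine_powers(
                    scorer, spec, current, options, trace
                )
            if current > best_score:
                best_spec, best_score = spec, current
        else:
            break

    final_fit = fit(series, best_spec, options=options.fit_options)
    final_lcv = lcv_score(
        series,
        best_spec,
        k=options.k,
        seed=options.seed,
        fit_options=options.fit_options,
    )
    return AdaptiveResult(
        selected=best_spec, fit=final_fit, lcv=final_lcv, trace=tuple(trace)
    )
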