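"""Core data containers: outcome series, design terms, parameter vectors.

A single subject is observed at distinct integer times within some window;
the outcome at each time takes one of a finite set of ordered numeric
values (the *support*), e.g. daily pain ratings 1-9.  Predictors for the
probability and dispersion models are built from power transforms of
nonnegative covariates (``time`` itself is always available) and from
*geometric combinations* -- products of power-transformed covariates,
optionally raised to a further outer power, which generalize interaction
terms to nonlinear moderation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POWER_BOUND",
    "OutcomeSeries",
    "TermSpec",
    "DesignSpec",
    "ParameterVector",
    "eval_term",
    "build_design",
    "read_series_csv",
    "write_series_csv",
]

#: Upper bound applied to every power-transformed predictor value so that
#: arbitrary powers of arbitrary covariate values cannot overflow doubles.
POWER_BOUND = 1e12

PROBABILITY_TYPES = ("multinomial", "ordinal", "censored_poisson")


@dataclass(frozen=True)
class OutcomeSeries:
    """A single subject's discrete longitudinal outcome.

    Parameters
    ----------
    times
        Strictly increasing distinct integers t(i), i = 1..N.  Integer
        times make the spatial AR(1) correlation rho**|dt| well defined.
    outcomes
        Observed values y_t(i); every value must be a member of ``support``.
    support
        The ordered possible outcome values v_0 < ... < v_K, K >= 1.
    covariates
        Named numeric columns aligned with ``times``.  The name ``time``
        is reserved and always resolves to t(i).
    """

    times: np.ndarray
    outcomes: np.ndarray
    support: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Singleton series arise from fold subsets; model fitting itself
        # requires N >= 2 and enforces it separately.
        times = np.asarray(self.times)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("need at least one observation time")
        if not np.all(np.equal(np.mod(times, 1), 0)):
            raise ValueError("times must be integers")
        times = times.astype(np.int64)
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing and distinct")
        outcomes = np.asarray(self.outcomes, dtype=float)
        if outcomes.shape != times.shape:
            raise ValueError("outcomes and times must have equal length")
        support = np.asarray(self.support, dtype=float)
        if support.ndim != 1 or support.size < 2:
            raise ValueError("support needs at least two values (K >= 1)")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support values must be strictly increasing")
        if not np.all(np.isin(outcomes, support)):
            raise ValueError("every outcome must be a member of the support")
        covs = {}
        for name, col in self.covariates.items():
            if name == "time":
                raise ValueError("'time' is reserved for the observation times")
            col = np.asarray(col, dtype=float)
            if col.shape != times.shape:
                raise ValueError(f"covariate {name!r} misaligned with times")
            covs[name] = col
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "covariates", covs)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_categories(self) -> int:
        """K + 1, the number of support values."""
        return self.support.size

    @property
    def k(self) -> int:
        """K, the number of support values above the reference v_0."""
        return self.support.size - 1

    def category_index(self) -> np.ndarray:
        """Index u of each outcome within the support (0..K)."""
        return np.searchsorted(self.support, self.outcomes)

    def column(self, name: str) -> np.ndarray:
        """Resolve a covariate column; ``time`` maps to the times."""
        if name == "time":
            return self.times.astype(float)
        try:
            return self.covariates[name]
        except KeyError:
            raise KeyError(f"unknown covariate {name!r}") from None

    def subset(self, idx: Sequence[int]) -> "OutcomeSeries":
        """Restrict to observation indices ``idx`` (kept in time order).

        Actual time gaps are preserved, which is what makes fold-deleted
        AR(1) likelihood evaluations coherent.
        """
        idx = np.asarray(sorted(idx), dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be nonempty")
        return OutcomeSeries(
            times=self.times[idx],
            outcomes=self.outcomes[idx],
            support=self.support,
            covariates={k: v[idx] for k, v in self.covariates.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "y": self.outcomes}
        data.update(self.covariates)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TermSpec:
    """One design term: a power transform or a geometric combination.

    A single base gives the plain transform ``base**inner_power`` (with
    ``outer_power`` conventionally 1); several bases give the geometric
    combination ``(b1**p1 * b2**p2 * ...)**outer_power``.
    """

    bases: tuple[str, ...]
    inner_powers: tuple[float, ...]
    outer_power: float = 1.0

    def __post_init__(self) -> None:
        bases = tuple(self.bases)
        powers = tuple(float(p) for p in self.inner_powers)
        if len(bases) == 0:
            raise ValueError("a term needs at least one base covariate")
        if len(bases) != len(powers):
            raise ValueError("one inner power per base is required")
        object.__setattr__(self, "bases", bases)
        object.__setattr__(self, "inner_powers", powers)
        object.__setattr__(self, "outer_power", float(self.outer_power))

    @property
    def is_geometric(self) -> bool:
        return len(self.bases) > 1

    def label(self) -> str:
        inner = "*".join(
            f"{b}^{p:g}" for b, p in zip(self.bases, self.inner_powers)
        )
        if self.is_geometric or self.outer_power != 1.0:
            return f"({inner})^{self.outer_power:g}"
        return inner

    def with_power(self, power: float) -> "TermSpec":
        """Return a copy with the searchable power replaced.

        For a single-base term the inner power is the searchable one; for
        a geometric combination it is the outer power.
        """
        if self.is_geometric:
            return replace(self, outer_power=float(power))
        return replace(self, inner_powers=(float(power),))

    @property
    def search_power(self) -> float:
        return self.outer_power if self.is_geometric else self.inner_powers[0]


def _bounded_power(base: np.ndarray, power: float) -> np.ndarray:
    """base**power with 0**0 := 1, 0**negative := POWER_BOUND, capped above."""
    base = np.asarray(base, dtype=float)
    if np.any(base < 0):
        raise ValueError("negative covariate values cannot be power transformed")
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(
            base == 0.0,
            np.where(power > 0, 0.0, np.where(power == 0, 1.0, POWER_BOUND)),
            np.power(base, power),
        )
    return np.minimum(out, POWER_BOUND)


def eval_term(term: TermSpec, row: Mapping[str, float]) -> float:
    """Evaluate one term at a single covariate row (scalar convenience)."""
    cols = {b: np.asarray([row[b]], dtype=float) for b in term.bases}
    return float(_eval_term_columns(term, cols)[0])


def _eval_term_columns(
    term: TermSpec, columns: Mapping[str, np.ndarray]
) -> np.ndarray:
    inner = np.ones_like(np.asarray(columns[term.bases[0]], dtype=float))
    for base, power in zip(term.bases, term.inner_powers):
        inner = inner * _bounded_power(columns[base], power)
    inner = np.minimum(inner, POWER_BOUND)
    return _bounded_power(inner, term.outer_power)


@dataclass(frozen=True)
class DesignSpec:
    """Probability and dispersion designs plus the probability model type."""

    probability_type: str
    prob_terms: tuple[TermSpec, ...] = ()
    prob_intercept: bool = True
    disp_terms: tuple[TermSpec, ...] = ()
    disp_intercept: bool = True

    def __post_init__(self) -> None:
        if self.probability_type not in PROBABILITY_TYPES:
            raise ValueError(
                f"probability_type must be one of {PROBABILITY_TYPES}"
            )
        object.__setattr__(self, "prob_terms", tuple(self.prob_terms))
        object.__setattr__(self, "disp_terms", tuple(self.disp_terms))
        if not self.prob_intercept and not self.prob_terms:
            raise ValueError("probability design is empty")

    @property
    def n_prob_columns(self) -> int:
        """J, the number of probability design columns."""
        return int(self.prob_intercept) + len(self.prob_terms)

    @property
    def n_disp_columns(self) -> int:
        """J', the number of dispersion design columns."""
        return int(self.disp_intercept) + len(self.disp_terms)

    def n_beta(self, k: int) -> int:
        """Length of the probability coefficient vector for K = ``k``.

        multinomial: K*J (one slope block per non-reference category);
        ordinal: K + J (category intercepts plus shared slopes);
        censored Poisson: J (a single log-rate regression).
        """
        j = self.n_prob_columns
        if self.probability_type == "multinomial":
            return k * j
        if self.probability_type == "ordinal":
            return k + j
        return j

    def n_parameters(self, k: int, include_rho: bool = False) -> int:
        """Total coefficient count (probability + dispersion [+ rho])."""
        return self.n_beta(k) + self.n_disp_columns + int(include_rho)


def _build_matrix(
    series: OutcomeSeries, terms: Sequence[TermSpec], intercept: bool
) -> np.ndarray:
    cols = []
    if intercept:
        cols.append(np.ones(series.n))
    for term in terms:
        columns = {b: series.column(b) for b in term.bases}
        cols.append(_eval_term_columns(term, columns))
    if not cols:
        return np.empty((series.n, 0))
    return np.column_stack(cols)


def build_design(
    series: OutcomeSeries, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the probability (N x J) and dispersion (N x J') matrices.

    The intercept column of ones comes first when the corresponding flag
    is set.  An empty dispersion design is allowed (dispersions then are
    identically 1); an empty probability design is rejected upstream.
    """
    x = _build_matrix(series, spec.prob_terms, spec.prob_intercept)
    xd = _build_matrix(series, spec.disp_terms, spec.disp_intercept)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(xd)):
        raise ValueError("design evaluation produced non-finite values")
    return x, xd


@dataclass(frozen=True)
class ParameterVector:
    """Flat parameter vector theta = (beta, beta', rho) with layout info.

    ``beta`` is laid out per probability type (see
    :meth:`DesignSpec.n_beta`); for the multinomial model the K blocks of
    J slopes are concatenated in category order u = 1..K; for the ordinal
    model the K cumulative-logit intercepts precede the J shared slopes.
    """

    beta: np.ndarray
    beta_disp: np.ndarray
    rho: float = 0.0

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        beta_disp = np.atleast_1d(np.asarray(self.beta_disp, dtype=float)).reshape(-1)
        if abs(self.rho) >= 1.0:
            raise ValueError("|rho| must be < 1")
        object.__setattr__(self, "beta", beta.reshape(-1))
        object.__setattr__(self, "beta_disp", beta_disp)
        object.__setattr__(self, "rho", float(self.rho))

    @classmethod
    def from_flat(
        cls, flat: np.ndarray, spec: DesignSpec, k: int
    ) -> "ParameterVector":
        flat = np.asarray(flat, dtype=float).reshape(-1)
        nb = spec.n_beta(k)
        nd = spec.n_disp_columns
        if flat.size != nb + nd + 1:
            raise ValueError(
                f"flat vector length {flat.size} != {nb}+{nd}+1 for this spec"
            )
        return cls(beta=flat[:nb], beta_disp=flat[nb : nb + nd], rho=flat[-1])

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.beta, self.beta_disp, [self.rho]])

    def validate(self, spec: DesignSpec, k: int) -> None:
        if self.beta.size != spec.n_beta(k):
            raise ValueError(
                f"beta has length {self.beta.size}, expected {spec.n_beta(k)}"
            )
        if self.beta_disp.size != spec.n_disp_columns:
            raise ValueError(
                f"beta_disp has length {self.beta_disp.size}, "
                f"expected {spec.n_disp_columns}"
            )


def read_series_csv(path, support: Sequence[float] | None = None) -> OutcomeSeries:
    """Read a series from CSV with columns ``time``, ``y`` and covariates.

    Missing days are simply absent rows.  When ``support`` is omitted it
    is taken as the sorted distinct observed outcome values.
    """
    frame = pd.read_csv(path)
    for col in ("time", "y"):
        if col not in frame.columns:
            raise ValueError(f"input CSV must contain a {col!r} column")
    frame = frame.sort_values("time")
    if support is None:
        support = np.unique(frame["y"].to_numpy(dtype=float))
    covs = {
        c: frame[c].to_numpy(dtype=float)
        for c in frame.columns
        if c not in ("time", "y")
    }
    return OutcomeSeries(
        times=frame["time"].to_numpy(),
        outcomes=frame["y"].to_numpy(dtype=float),
        support=np.asarray(support, dtype=float),
        covariates=covs,
    )


def write_series_csv(series: OutcomeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
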