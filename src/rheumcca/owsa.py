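"""One-way deterministic sensitivity analysis (OWSA) and tornado ranking.

Every variable parameter is assigned an uncertainty distribution by rule:

* a 95% confidence interval, when supplied, is used directly as the low/high
  evaluation points;
* otherwise a proportion gets a beta distribution with standard deviation
  equal to its mean (method-of-moments shapes);
* otherwise a continuous parameter gets a symmetric triangular distribution
  with standard deviation equal to 30% of its mean.

Parameters with mean zero, and fixed quantities (time horizon, dose schedule,
concomitant drug prices, cohort size, patient weight), are never varied.
"Varied based on the 95% CI" is operationalized as deterministic evaluation at
the 2.5th and 97.5th percentiles of the assigned distribution — one low and
one high model evaluation per parameter, as a tornado diagram requires.

The beta rule (SD = mean) is mathematically infeasible for means >= 0.5
(it would need alpha + beta <= 0); such parameters have their SD clamped to
95% of the maximum feasible SD, sqrt(mean*(1-mean)), with a warning.
Triangular supports that would cross zero for nonnegative-by-nature
parameters are truncated: the half-width is clamped to the mean (lower bound
0, mode = mean, upper = 2*mean), which preserves the mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .exceptions import BetaInfeasibleError, DomainError, NotVariableError


@dataclass(frozen=True)
class ParameterSpec:
    """One model input eligible (or not) for one-way variation."""

    id: str
    value: float
    kind: str  # proportion | continuous | fixed
    ci95: Optional[Tuple[float, float]] = None
    varies: bool = True
    nonnegative: bool = True

    def __post_init__(self):
        if self.kind not in ("proportion", "continuous", "fixed"):
            raise DomainError(f"{self.id}: unknown kind {self.kind!r}")
        if self.kind == "proportion" and not 0.0 <= self.value <= 1.0:
            raise DomainError(f"{self.id}: proportion outside [0,1]: {self.value}")
        if self.kind == "fixed" and self.varies:
            object.__setattr__(self, "varies", False)
        if self.value == 0.0 and self.varies:
            # zero-mean parameters are not allowed to vary
            object.__setattr__(self, "varies", False)


@dataclass(frozen=True)
class TornadoEntry:
    """Incremental-cost results at one parameter's low/high bounds."""

    parameter: str
    low_value: float
    high_value: float
    low_result: float
    high_result: float
    failed: bool = False

    @property
    def range(self) -> float:
        return abs(self.high_result - self.low_result)

    @property
    def crosses_zero(self) -> bool:
        return min(self.low_result, self.high_result) < 0.0 < max(
            self.low_result, self.high_result
        )


# --------------------------------------------------------------------------
# distribution descriptors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectBounds:
    low: float
    high: float


@dataclass(frozen=True)
class BetaSpec:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        ab = self.alpha + self.beta
        return math.sqrt(self.alpha * self.beta / (ab * ab * (ab + 1.0)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size)


@dataclass(frozen=True)
class TriangularSpec:
    lower: float
    mode: float
    upper: float

    @property
    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0

    @property
    def sd(self) -> float:
        a, c, b = self.lower, self.mode, self.upper
        return math.sqrt(
            (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0
        )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.upper == self.lower:
            return np.full(size, self.mode)
        return rng.triangular(self.lower, self.mode, self.upper, size)


Descriptor = Union[DirectBounds, BetaSpec, TriangularSpec]


def beta_from_mean_sd(mean: float, sd: float) -> Tuple[float, float]:
    """Method-of-moments beta shapes for a requested (mean, SD).

    Solves ``alpha + beta = mean*(1-mean)/sd^2 - 1`` and
    ``alpha = mean*(alpha+beta)``; the returned distribution reproduces the
    requested moments exactly.  Raises :class:`BetaInfeasibleError` (carrying
    the documented clamped fallback SD) when ``sd^2 >= mean*(1-mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise DomainError(f"beta mean must be in (0,1), got {mean}")
    if sd <= 0.0:
        raise DomainError(f"beta sd must be > 0, got {sd}")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0.0:
        raise BetaInfeasibleError(
            mean, sd, clamped_sd=0.95 * math.sqrt(mean * (1.0 - mean))
        )
    return mean * nu, (1.0 - mean) * nu


def triangular_from_mean_sd(
    mean: float, sd: float, nonnegative: bool = True
) -> Tuple[float, float, float]:
    """Symmetric triangular (lower, mode, upper) with the requested moments.

    The half-width of a symmetric triangular with standard deviation ``sd``
    is ``sd * sqrt(6)``.  If the support would cross zero for a
    nonnegative-by-nature parameter, the half-width is clamped to the mean
    (support [0, 2*mean]); this truncation preserves the mean but shrinks the
    SD.  ``sd = 0`` degenerates to a point mass at the mean.
    """
    if mean <= 0.0:
        raise DomainError(f"triangular mean must be > 0, got {mean}")
    if sd < 0.0:
        raise DomainError(f"triangular sd must be >= 0, got {sd}")
    w = sd * math.sqrt(6.0)
    if nonnegative and mean - w < 0.0:
        w = mean
    return mean - w, mean, mean + w


def assign_distribution(p: ParameterSpec) -> Descriptor:
    """Apply the distribution-assignment rules to one parameter."""
    if not p.varies or p.kind == "fixed":
        raise NotVariableError(f"parameter {p.id} is fixed or has mean zero")
    if p.ci95 is not None:
        low, high = p.ci95
        if low > high:
            raise DomainError(f"{p.id}: ci95 low > high")
        return DirectBounds(low, high)
    if p.kind == "proportion":
        sd = p.value  # SD equal to the mean
        try:
            alpha, beta = beta_from_mean_sd(p.value, sd)
        except BetaInfeasibleError as e:
            warnings.warn(
                f"{p.id}: beta(mean={p.value}, sd=mean) infeasible; "
                f"clamping sd to {e.clamped_sd:.6g}",
                stacklevel=2,
            )
            alpha, beta = beta_from_mean_sd(p.value, e.clamped_sd)
        return BetaSpec(alpha, beta)
    lower, mode, upper = triangular_from_mean_sd(
        p.value, 0.30 * p.value, nonnegative=p.nonnegative
    )
    return TriangularSpec(lower, mode, upper)


def ci_bounds(descriptor: Descriptor) -> Tuple[float, float]:
    """Low/high evaluation points: direct bounds, or 2.5/97.5 percentiles."""
    if isinstance(descriptor, DirectBounds):
        return descriptor.low, descriptor.high
    if isinstance(descriptor, BetaSpec):
        dist = stats.beta(descriptor.alpha, descriptor.beta)
        return float(dist.ppf(0.025)), float(dist.ppf(0.975))
    if isinstance(descriptor, TriangularSpec):
        a, c, b = descriptor.lower, descriptor.mode, descriptor.upper
        if b == a:
            return a, b
        dist = stats.triang(c=(c - a) / (b - a), loc=a, scale=b - a)
        return float(dist.ppf(0.025)), float(dist.ppf(0.975))
    raise DomainError(f"unknown descriptor {descriptor!r}")


def run_owsa(
    runner: Callable[[Mapping[str, float]], float],
    params: Sequence[ParameterSpec],
) -> List[TornadoEntry]:
    """Evaluate the model at every variable parameter's low and high bound.

    ``runner`` maps an override mapping ``{parameter id: value}`` to the
    deterministic total incremental cost.  One entry per variable parameter,
    sorted by descending result range, ties broken lexicographically by id.
    A model failure at a bound flags the entry and the run continues.
    """
    baseline = runner({})  # must evaluate; propagate failures here
    entries: List[TornadoEntry] = []
    for p in params:
        if not p.varies:
            continue
        try:
            desc = assign_distribution(p)
            low, high = ci_bounds(desc)
            low_result = runner({p.id: low})
            high_result = runner({p.id: high})
            entries.append(
                TornadoEntry(
                    parameter=p.id,
                    low_value=low,
                    high_value=high,
                    low_result=low_result,
                    high_result=high_result,
                )
            )
        except Exception:
            entries.append(
                TornadoEntry(
                    parameter=p.id,
                    low_value=math.nan,
                    high_value=math.nan,
                    low_result=baseline,
                    high_result=baseline,
                    failed=True,
                )
            )
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return entries


__all__ = [
    "ParameterSpec",
    "TornadoEntry",
    "DirectBounds",
    "BetaSpec",
    "TriangularSpec",
    "beta_from_mean_sd",
    "triangular_from_mean_sd",
    "assign_distribution",
    "ci_bounds",
    "run_owsa",
]
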