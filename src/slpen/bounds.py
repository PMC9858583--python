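"""Max-min normalisation bounds for slope entropy.

Raw SlpEn values span tens of thousands of (negative) bits for
deterministic series down at ``-N*log2(N)``, while real physiological
signals cluster within a few tens of bits of zero.  To report values in
the conventional ``[0, 1]`` range this module provides:

* **Analytic bounds** — provable extremes.  The minimum is attained by a
  constant-gradient series (a single pattern, ``k = 1``); the maximum by
  a uniform histogram at the continuous maximiser ``k* = e*sqrt(N)`` of
  ``f(k) = (N/k) * log2(k**2 / N)``, giving ``2*sqrt(N) / (e*ln 2)``
  bits.  Guaranteed never to clip, but real series end up compressed
  near 1.
* **Heuristic bounds** — practical tightenings.  The lower bound models
  a mostly-constant series acquiring one singleton pattern per 100
  samples (see :func:`slpen.core.slpen_constant_model`); deterministic
  series fall below it and are clipped to exactly 0.  The upper bound
  replaces ``k*`` with a regression estimate ``k_hat(m)`` of the pattern
  count observed in random series.
* **The recommended scheme** — heuristic minimum with analytic maximum.
  The heuristic maximum adds little (the logarithmic geometry expands
  mainly the lower part of the interval) and the analytic maximum
  removes any risk of normalised values exceeding 1.

The maximum is stated here in its base-2-consistent form
``2*sqrt(N)/(e*ln 2)``: the natural-log algebra of the maximisation
yields ``2*sqrt(N)/e``, but the entropy itself is computed in bits, and
only the base-2 value is consistent with the rest of the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "BoundsSet",
    "NormalisedResult",
    "analytic_min",
    "exact_min",
    "kstar",
    "analytic_max",
    "heuristic_min",
    "heuristic_max",
    "analytic_bounds",
    "recommended_bounds",
    "heuristic_bounds",
    "normalise",
]

Scheme = Literal["analytic", "heuristic_min_analytic_max", "heuristic_both"]

_E_LN2 = math.e * math.log(2)


@dataclass(frozen=True)
class BoundsSet:
    """A lower/upper pair of normalisation bounds, in bits.

    ``k_lower`` and ``k_upper`` record the pattern count each bound
    assumes (1 for the analytic minimum, ``round(k*)`` for the analytic
    maximum, ``k_h`` / ``k_hat`` for the heuristics).
    """

    lower: float
    upper: float
    scheme: Scheme
    k_lower: int
    k_upper: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"bounds must satisfy lower < upper, got [{self.lower}, {self.upper}]")
        if self.k_lower < 1 or self.k_upper < 1:
            raise ValueError("bound pattern counts must be >= 1")


@dataclass(frozen=True)
class NormalisedResult:
    """A raw SlpEn value and its max-min normalised counterpart."""

    raw: float
    normalised: float
    bounds: BoundsSet
    clipped: bool


def analytic_min(n: int) -> float:
    """Simplified analytic lower bound, ``-N * log2(N)`` bits.

    The exact minimum (a constant-gradient series) is
    ``-(N-m+1) * log2(N-m+1)``; since ``m << N`` the embedding dimension
    is dropped, making the bound independent of ``m``.  This simplified
    form is the one used in the analytic normalisation denominator; use
    :func:`exact_min` for the exact ``k = 1`` value.
    """
    if not (isinstance(n, (int, float)) and n >= 2):
        raise ValueError(f"series length must be >= 2, got {n!r}")
    return -n * math.log2(n)


def exact_min(n_sub: int) -> float:
    """Exact SlpEn lower bound ``-n_sub * log2(n_sub)`` for ``k = 1`` bins."""
    if not n_sub >= 1:
        raise ValueError(f"subsequence count must be >= 1, got {n_sub!r}")
    return -n_sub * math.log2(n_sub)


def kstar(n: int) -> float:
    """Continuous pattern count maximising uniform-histogram SlpEn.

    ``f(k) = (N/k) * log2(k**2/N)`` is maximised at ``k* = e*sqrt(N)``
    (the base of the logarithm only rescales ``f``, not its argmax).
    """
    if not n >= 2:
        raise ValueError(f"series length must be >= 2, got {n!r}")
    return math.e * math.sqrt(n)


def analytic_max(n: int) -> float:
    """Analytic upper bound ``2*sqrt(N) / (e * ln 2)`` bits.

    Value of the uniform-histogram expression at its maximiser
    ``k* = e*sqrt(N)``.  No series of length ``N`` can exceed it: the
    uniform histogram maximises the entropy for fixed ``k``, and ``k*``
    maximises over ``k``.
    """
    if not n >= 2:
        raise ValueError(f"series length must be >= 2, got {n!r}")
    return 2 * math.sqrt(n) / _E_LN2


def _uniform_hist_slpen(n: int, k: int) -> float:
    """Uniform-histogram SlpEn ``(N/k) * log2(k**2/N)`` in bits."""
    return (n / k) * math.log2(k * k / n)


def heuristic_min(n: int, m: int, samples_per_pattern: int = 100) -> float:
    """Heuristic lower bound: one singleton pattern per 100 samples.

    Deterministic series (constant, constant-gradient, periodic) stay
    below this bound and normalise to 0; genuinely noisy series sit well
    above it.  ``k_h = max(1, round(N / samples_per_pattern))`` extra-ish
    patterns are plugged into the near-constant closed-form model.
    """
    if samples_per_pattern < 1:
        raise ValueError("samples_per_pattern must be >= 1")
    if n < m:
        raise ValueError(f"series length {n} shorter than m={m}")
    k_h = max(1, round(n / samples_per_pattern))
    from .core import slpen_constant_model

    return slpen_constant_model(n - (m - 1), k_h)


def _heuristic_k(n: int, m: int, samples_per_pattern: int = 100) -> int:
    return max(1, round(n / samples_per_pattern))


def heuristic_max(n: int, m: int, fit) -> float:
    """Heuristic upper bound from a regression estimate of ``k``.

    ``fit`` is any object with a ``predict(m)`` method returning the
    expected number of unique patterns for embedding dimension ``m``
    (see :mod:`slpen.regression`).  The prediction is clamped to the
    theoretical ceiling ``5**(m-1)`` and to the subsequence count, then
    evaluated through the uniform-histogram expression.
    """
    if n < m:
        raise ValueError(f"series length {n} shorter than m={m}")
    k_hat = min(round(fit.predict(m)), 5 ** (m - 1), n - (m - 1))
    if k_hat < 2:
        raise ValueError(f"regression predicts k={k_hat} < 2 for m={m}; bound undefined")
    return _uniform_hist_slpen(n, k_hat)


def analytic_bounds(n: int) -> BoundsSet:
    """The conservative analytic scheme: ``[-N*log2 N, 2*sqrt(N)/(e ln 2)]``."""
    return BoundsSet(
        lower=analytic_min(n),
        upper=analytic_max(n),
        scheme="analytic",
        k_lower=1,
        k_upper=round(kstar(n)),
    )


def recommended_bounds(n: int, m: int, samples_per_pattern: int = 100) -> BoundsSet:
    """The recommended scheme: heuristic minimum with analytic maximum.

    Tightens the lower end so deterministic series clip to 0, while the
    provable maximum guarantees values never exceed 1.
    """
    return BoundsSet(
        lower=heuristic_min(n, m, samples_per_pattern),
        upper=analytic_max(n),
        scheme="heuristic_min_analytic_max",
        k_lower=_heuristic_k(n, samples_per_pattern=samples_per_pattern, m=m),
        k_upper=round(kstar(n)),
    )


def heuristic_bounds(n: int, m: int, fit, samples_per_pattern: int = 100) -> BoundsSet:
    """Both bounds heuristic: Eq.-style near-constant minimum, regression maximum."""
    k_hat = min(round(fit.predict(m)), 5 ** (m - 1), n - (m - 1))
    return BoundsSet(
        lower=heuristic_min(n, m, samples_per_pattern),
        upper=heuristic_max(n, m, fit),
        scheme="heuristic_both",
        k_lower=_heuristic_k(n, samples_per_pattern=samples_per_pattern, m=m),
        k_upper=max(k_hat, 1),
    )


def normalise(raw: float, bounds: BoundsSet) -> NormalisedResult:
    """Max-min scale a raw SlpEn value into ``[0, 1]``.

    ``(raw - lower) / (upper - lower)``, with values below the lower
    bound clipped to exactly 0 (deterministic series under the heuristic
    minimum).  Under the analytic and recommended schemes the upper
    bound is provable, so values above 1 indicate a misuse; under
    ``heuristic_both`` the regression bound is approximate and values
    are defensively capped at 1 with a warning.
    """
    span = bounds.upper - bounds.lower
    value = (raw - bounds.lower) / span
    clipped = False
    if value < 0:
        value, clipped = 0.0, True
    elif value > 1:
        if bounds.scheme == "heuristic_both":
            warnings.warn(
                f"raw SlpEn {raw:.4g} exceeds the heuristic upper bound {bounds.upper:.4g}; "
                "capping normalised value at 1",
                RuntimeWarning,
                stacklevel=2,
            )
            value, clipped = 1.0, True
        else:
            raise ValueError(
                f"raw SlpEn {raw!r} exceeds the provable upper bound {bounds.upper!r}"
            )
    return NormalisedResult(raw=raw, normalised=value, bounds=bounds, clipped=clipped)
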