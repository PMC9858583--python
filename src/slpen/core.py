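"""Slope entropy (SlpEn) of univariate time series.

SlpEn symbolises the *slopes* of a time series: each overlapping
subsequence of length ``m`` is reduced to the differences between its
consecutive samples, and each difference ``d`` is mapped to one of five
symbols according to two amplitude thresholds ``delta`` (the "flat" band)
and ``gamma`` (the "steep" band)::

    +2  if d > gamma
    +1  if delta < d <= gamma
     0  if |d| <= delta
    -1  if -gamma <= d < -delta
    -2  if d < -gamma

The resulting length-``m-1`` symbol strings are counted into a histogram
of the ``k`` distinct strings actually observed, and a Shannon-form
entropy is computed with relative frequencies ``p_i = c_i / k``.

Two deliberate departures from a textbook Shannon entropy are part of the
method and must not be "fixed":

* The normaliser is ``k`` (patterns found), not the number of
  subsequences, so the ``p_i`` do not sum to 1.  The scarcity of observed
  patterns relative to the theoretical ``5**(m-1)`` carries information
  about determinism, and using ``k`` keeps it.
* As a consequence SlpEn is unbounded below; strongly deterministic
  series yield large negative values (a constant series of length N gives
  ``-(N-m+1)*log2(N-m+1)``).

All logarithms are base 2; values are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SlpEnParams",
    "PatternHistogram",
    "SlpEnResult",
    "as_series",
    "symbolize",
    "encode",
    "slope_entropy",
    "slpen_constant_model",
]

#: Symbol alphabet, steepest positive slope first.
ALPHABET = (2, 1, 0, -1, -2)

SymbolString = Tuple[int, ...]


@dataclass(frozen=True)
class SlpEnParams:
    """Configuration of the slope-entropy computation.

    Parameters
    ----------
    m : int
        Embedding dimension: length of each extracted subsequence.
        Symbol strings have length ``m - 1``.  Must be at least 3.
    delta : float
        Half-width of the "flat" band: differences with ``|d| <= delta``
        map to symbol 0.  Same units as the sample differences.
    gamma : float
        Steepness threshold: ``d > gamma`` maps to +2, ``d < -gamma`` to
        -2.  Must satisfy ``0 <= delta < gamma``.
    """

    m: int = 6
    delta: float = 0.001
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 3):
            raise ValueError(f"embedding dimension m must be an integer >= 3, got {self.m!r}")
        if not (math.isfinite(self.delta) and math.isfinite(self.gamma)):
            raise ValueError("thresholds must be finite")
        if not (0 <= self.delta < self.gamma):
            raise ValueError(
                f"thresholds must satisfy 0 <= delta < gamma, got delta={self.delta}, gamma={self.gamma}"
            )

    @property
    def n_symbols(self) -> int:
        """Length of the symbol strings, ``m - 1``."""
        return self.m - 1

    @property
    def max_patterns(self) -> int:
        """Theoretical number of distinct symbol strings, ``5**(m-1)``."""
        return 5 ** (self.m - 1)


@dataclass(frozen=True)
class PatternHistogram:
    """Histogram of the symbol strings observed in one series.

    ``counts`` maps each observed length-``m-1`` symbol string to its
    occurrence count ``c_i``; ``k`` is the number of distinct strings and
    ``n_sub`` the total number of subsequences, ``N - (m - 1)``.
    """

    counts: Dict[SymbolString, int]
    n_sub: int = field(default=0)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.n_sub == 0:
            object.__setattr__(self, "n_sub", total)
        assert total == self.n_sub, "histogram counts must sum to the subsequence count"
        assert all(c >= 1 for c in self.counts.values())

    @property
    def k(self) -> int:
        """Number of distinct symbol strings found."""
        return len(self.counts)


@dataclass(frozen=True)
class SlpEnResult:
    """Slope entropy of one series.

    ``value`` is in bits and, because the histogram normaliser is ``k``,
    may be negative and is not confined to ``[0, log2 k]``.
    """

    value: float
    k: int
    n_sub: int
    params: SlpEnParams


def as_series(x) -> np.ndarray:
    """Validate ``x`` as a univariate time series.

    Returns a contiguous 1-D float64 array of length >= 2 with all
    samples finite; raises ``ValueError`` otherwise.
    """
    arr = np.ascontiguousarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"time series must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"time series must contain at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("time series contains non-finite samples")
    return arr


def symbolize(d: float, params: SlpEnParams) -> int:
    """Map one consecutive-sample difference to its slope symbol.

    The five threshold conditions partition the real line, so exactly one
    symbol applies to any finite ``d``.  Boundary values follow the
    printed inequalities literally: ``d == gamma`` gives +1, ``d ==
    delta`` gives 0, and symmetrically for the negatives.
    """
    if not math.isfinite(d):
        raise ValueError(f"difference must be finite, got {d!r}")
    if d > params.gamma:
        return 2
    if d > params.delta:  # delta < d <= gamma
        return 1
    if d >= -params.delta:  # |d| <= delta
        return 0
    if d >= -params.gamma:  # -gamma <= d < -delta
        return -1
    return -2


def _symbolize_diffs(d: np.ndarray, params: SlpEnParams) -> np.ndarray:
    """Vectorised symbol rule over an array of differences."""
    out = np.empty(d.shape, dtype=np.int8)
    out[d > params.gamma] = 2
    np.copyto(out, 1, where=(d <= params.gamma) & (d > params.delta))
    np.copyto(out, 0, where=np.abs(d) <= params.delta)
    np.copyto(out, -1, where=(d < -params.delta) & (d >= -params.gamma))
    out[d < -params.gamma] = -2
    return out


def encode(x, params: SlpEnParams) -> PatternHistogram:
    """Build the symbol-string histogram of a time series.

    Every one of the ``N - (m - 1)`` overlapping subsequences of length
    ``m`` contributes one length-``m-1`` symbol string obtained by
    symbolising its consecutive differences ``d = x_j - x_{j+1}``
    (earlier sample minus later sample — the sign convention is fixed).
    """
    arr = as_series(x)
    n = arr.size
    if n < params.m:
        raise ValueError(f"series of length {n} is too short for m={params.m}")
    # Differences are shared between overlapping windows: symbolise the
    # N-1 global differences once, then window the symbol array.
    diffs = arr[:-1] - arr[1:]
    symbols = _symbolize_diffs(diffs, params)
    windows = sliding_window_view(symbols, params.n_symbols)
    uniq, counts = np.unique(windows, axis=0, return_counts=True)
    hist = {tuple(int(s) for s in row): int(c) for row, c in zip(uniq, counts)}
    return PatternHistogram(counts=hist, n_sub=n - (params.m - 1))


def slope_entropy(x, params: SlpEnParams | None = None) -> SlpEnResult:
    """Compute the slope entropy of a time series.

    The value is ``-sum_i p_i * log2(p_i)`` over the ``k`` histogram bins
    with ``p_i = c_i / k``.  Since ``sum_i p_i = n_sub / k`` this is not
    a normalised Shannon entropy; see the module docstring.
    """
    if params is None:
        params = SlpEnParams()
    hist = encode(x, params)
    counts = np.fromiter(hist.counts.values(), dtype=np.float64, count=hist.k)
    p = counts / hist.k
    # all c_i >= 1 so p_i > 0; 0*log(0) cannot arise
    value = float(-(p * np.log2(p)).sum())
    return SlpEnResult(value=value, k=hist.k, n_sub=hist.n_sub, params=params)


def slpen_constant_model(n_sub: int, k: int) -> float:
    """SlpEn of a near-constant-slope series with ``k - 1`` singleton patterns.

    Closed-form model of a constant-gradient series of ``n_sub``
    subsequences perturbed so that ``k - 1`` subsequences each form their
    own singleton histogram bin, the remaining ``n_sub - (k - 1)``
    staying in the dominant bin::

        -((n_sub-(k-1))/k) * log2((n_sub-(k-1))/k) - (k-1) * (1/k) * log2(1/k)

    For ``k = 1`` this reduces to the exact minimum
    ``-n_sub * log2(n_sub)``.  Used both as a cross-check of the full
    pipeline and as the heuristic lower normalisation bound.
    """
    if not (isinstance(n_sub, (int, np.integer)) and n_sub >= 1):
        raise ValueError(f"n_sub must be a positive integer, got {n_sub!r}")
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= n_sub):
        raise ValueError(f"k must satisfy 1 <= k <= n_sub={n_sub}, got {k!r}")
    dominant = (n_sub - (k - 1)) / k
    value = -dominant * math.log2(dominant)
    if k > 1:
        value -= (k - 1) * (1 / k) * math.log2(1 / k)
    return value
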