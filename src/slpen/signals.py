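"""Seeded generators for the synthetic study signals.

The normalisation scheme is validated on signals spanning the
determinism-randomness axis:

* constant and constant-gradient series — the fully deterministic
  extreme, a single slope pattern whatever the thresholds;
* a constant series with one interior outlier — the minimal departure
  from determinism, adding exactly ``m`` new patterns;
* sinusoids — periodic determinism: the symbolic histogram repeats with
  each period, so the pattern count stays small and length-independent;
* Gaussian and uniform noise — the random extreme.

The two labelled datasets mirror the study conditions: *random* is 100
standard-normal (class 0) plus 100 zero-mean unit-variance uniform
(class 1) records of 5000 samples; *periodic* is 100 sinusoids of period 100 (class 0) plus
100 of period 500 (class 1), unit amplitude, uniformly random phase,
5000 samples.  All randomness flows through a single integer seed;
equal seeds give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .core import as_series

__all__ = [
    "DatasetSpec",
    "constant",
    "constant_gradient",
    "constant_with_outlier",
    "sinusoid",
    "gaussian_noise",
    "uniform_noise",
    "random_dataset",
    "periodic_dataset",
    "generate",
    "truncate",
    "decimate",
]

KINDS = ("constant", "constant_gradient", "constant_with_outlier", "sinusoid", "gaussian", "uniform")


@dataclass(frozen=True)
class DatasetSpec:
    """Declarative description of a synthetic dataset.

    ``params`` holds kind-specific settings: ``step`` for
    constant_gradient; ``position`` and ``outlier_value`` for
    constant_with_outlier; ``period``, ``amplitude`` for sinusoid;
    ``loc``/``scale`` for gaussian; ``low``/``high`` for uniform.
    """

    kind: str
    n: int = 5000
    n_records: int = 1
    seed: int = 0
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; expected one of {KINDS}")
        if self.n < 2:
            raise ValueError(f"series length must be >= 2, got {self.n}")
        if self.n_records < 1:
            raise ValueError(f"n_records must be >= 1, got {self.n_records}")


def constant(n: int, value: float = 1.0) -> np.ndarray:
    """A constant series: the most deterministic input, ``k = 1``."""
    return as_series(np.full(n, value))


def constant_gradient(n: int, step: float = 1.0, start: float = 0.0) -> np.ndarray:
    """A constant-slope ramp ``start, start+step, ...``; also ``k = 1``."""
    return as_series(start + step * np.arange(n))


def constant_with_outlier(
    n: int = 66, outlier_value: float = 2.0, position: int | None = None, base: float = 1.0
) -> np.ndarray:
    """A constant series with one interior sample replaced by an outlier.

    With the outlier away from the borders, every embedding window that
    covers it produces a distinct symbol string, so the pattern count
    jumps from 1 to ``m + 1`` — the worked example behind the heuristic
    lower bound.
    """
    if position is None:
        position = n // 2
    x = np.full(n, base)
    m_guard = 1  # interior: at least one clean sample on each side
    if not (m_guard <= position <= n - 1 - m_guard):
        raise ValueError(f"outlier position {position} is not interior for length {n}")
    x[position] = outlier_value
    return as_series(x)


def sinusoid(n: int, period: float, amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """A sampled sinusoid ``A * sin(2*pi*t/T + phase)``, unit-spaced ``t``.

    Consecutive differences are bounded by ``2*A*sin(pi/T)``, so long
    periods keep every slope inside the flat/shallow symbol bands.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    t = np.arange(n)
    return as_series(amplitude * np.sin(2 * math.pi * t / period + phase))


def gaussian_noise(n: int, rng: np.random.Generator, loc: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Standard-normal noise (the default random class-0 signal)."""
    return as_series(rng.normal(loc, scale, n))


#: Half-width of the zero-mean unit-variance uniform distribution.
UNIFORM_HALF_WIDTH = math.sqrt(3)


def uniform_noise(
    n: int,
    rng: np.random.Generator,
    low: float = -UNIFORM_HALF_WIDTH,
    high: float = UNIFORM_HALF_WIDTH,
) -> np.ndarray:
    """Uniform[low, high) noise (the default random class-1 signal).

    The default range is zero-mean with unit variance so the two random
    classes are moment-matched and differ only in distribution shape —
    the regime where entropy features, not amplitude, carry the class
    information.
    """
    return as_series(rng.uniform(low, high, n))


def random_dataset(
    seed: int, n_per_class: int = 100, n: int = 5000
) -> Tuple[List[np.ndarray], np.ndarray]:
    """The labelled random dataset: Gaussian (class 0) vs uniform (class 1).

    Returns the records followed by an integer label array.
    """
    rng = np.random.default_rng(seed)
    series = [gaussian_noise(n, rng) for _ in range(n_per_class)]
    series += [uniform_noise(n, rng) for _ in range(n_per_class)]
    labels = np.repeat([0, 1], n_per_class)
    return series, labels


def periodic_dataset(
    seed: int,
    n_per_class: int = 100,
    n: int = 5000,
    periods: Tuple[float, float] = (100.0, 500.0),
    amplitude: float = 1.0,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """The labelled periodic dataset: period-100 vs period-500 sinusoids.

    Phases are drawn uniformly on ``[0, 2*pi)``; amplitude defaults
    to 1.
    """
    rng = np.random.default_rng(seed)
    series = [
        sinusoid(n, periods[0], amplitude, phase=rng.uniform(0, 2 * math.pi))
        for _ in range(n_per_class)
    ]
    series += [
        sinusoid(n, periods[1], amplitude, phase=rng.uniform(0, 2 * math.pi))
        for _ in range(n_per_class)
    ]
    labels = np.repeat([0, 1], n_per_class)
    return series, labels


def generate(spec: DatasetSpec) -> List[np.ndarray]:
    """Generate ``spec.n_records`` series of the requested kind.

    Deterministic kinds ignore the seed; stochastic kinds (gaussian,
    uniform, sinusoid with unset phase) consume one shared generator so
    the whole dataset is reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    out: List[np.ndarray] = []
    for _ in range(spec.n_records):
        if spec.kind == "constant":
            out.append(constant(spec.n, p.get("value", 1.0)))
        elif spec.kind == "constant_gradient":
            out.append(constant_gradient(spec.n, p.get("step", 1.0), p.get("start", 0.0)))
        elif spec.kind == "constant_with_outlier":
            pos = p.get("position")
            out.append(
                constant_with_outlier(
                    spec.n,
                    p.get("outlier_value", 2.0),
                    int(pos) if pos is not None else None,
                    p.get("base", 1.0),
                )
            )
        elif spec.kind == "sinusoid":
            phase = p.get("phase")
            if phase is None:
                phase = rng.uniform(0, 2 * math.pi)
            out.append(sinusoid(spec.n, p.get("period", 100.0), p.get("amplitude", 1.0), phase))
        elif spec.kind == "gaussian":
            out.append(gaussian_noise(spec.n, rng, p.get("loc", 0.0), p.get("scale", 1.0)))
        elif spec.kind == "uniform":
            out.append(
                uniform_noise(
                    spec.n,
                    rng,
                    p.get("low", -UNIFORM_HALF_WIDTH),
                    p.get("high", UNIFORM_HALF_WIDTH),
                )
            )
    return out


def truncate(x, length: int) -> np.ndarray:
    """Keep the leading ``length`` samples (short-epoch analysis)."""
    arr = as_series(x)
    if not (2 <= length <= arr.size):
        raise ValueError(f"truncation length must be in [2, {arr.size}], got {length}")
    return arr[:length]


def decimate(x, rate: int) -> np.ndarray:
    """Keep every ``rate``-th sample starting at index 0 (downsampling)."""
    arr = as_series(x)
    if rate < 1:
        raise ValueError(f"decimation rate must be >= 1, got {rate}")
    out = arr[::rate]
    if out.size < 2:
        raise ValueError(f"decimation rate {rate} leaves fewer than 2 samples")
    return out
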