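"""Regression models of the unique-pattern count ``k`` versus ``m``.

In random series the number of distinct slope-symbol strings actually
observed grows with the embedding dimension ``m`` far more slowly than
the theoretical ``5**(m-1)``: most long patterns simply never occur at
realistic series lengths (the "forbidden pattern" effect).  Fitting the
observed maxima ``k_max(m)`` gives an a-priori estimate ``k_hat(m)``
usable as a heuristic upper normalisation bound before any entropy has
been computed.

Four families are supported: polynomial fits of degree 1-3 by ordinary
least squares, and a power law ``k = a * m**b`` fitted by least squares
of ``log k`` on ``log m``.  The quality measure ``r`` is the Pearson
correlation between observed and fitted values, which for the linear
family coincides with the ordinary correlation coefficient of the raw
pairs.

A reference set of ``(m, k_max)`` observations — the maxima found over
100 standard-random series of 5000 samples for ``m`` in 3..9 — ships
with the package (:func:`load_reference_observations`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "KObservation",
    "RegressionFit",
    "FAMILIES",
    "fit",
    "predict_k",
    "load_reference_observations",
]

FAMILIES = ("linear", "quadratic", "cubic", "power")

_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}


class KObservation(NamedTuple):
    """One observed (embedding dimension, maximum unique patterns) pair."""

    m: int
    k_max: int


@dataclass(frozen=True)
class RegressionFit:
    """A fitted k-versus-m model.

    ``coefficients`` are ordered highest degree first for the polynomial
    families, and ``(a, b)`` for the power family ``a * m**b``.  ``r``
    is the Pearson correlation between observed and fitted values.
    """

    family: str
    coefficients: Tuple[float, ...]
    r: float

    def __post_init__(self) -> None:
        expected = {"linear": 2, "quadratic": 3, "cubic": 4, "power": 2}[self.family]
        if len(self.coefficients) != expected:
            raise ValueError(
                f"{self.family} fit needs {expected} coefficients, got {len(self.coefficients)}"
            )

    def predict(self, m: float) -> float:
        """Evaluate the fitted model at embedding dimension ``m``."""
        if self.family == "power":
            a, b = self.coefficients
            return a * m**b
        return float(np.polyval(self.coefficients, m))


def fit(observations: Iterable[KObservation | Sequence[float]], family: str) -> RegressionFit:
    """Fit one model family to ``(m, k_max)`` observations.

    Polynomial families use ordinary least squares on the raw pairs; the
    power family is linearised as ``log k = log a + b log m`` and fitted
    by least squares in log-log space (which requires all ``k_max > 0``).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    obs = [(float(mi), float(ki)) for mi, ki in observations]
    n_coef = {"linear": 2, "quadratic": 3, "cubic": 4, "power": 2}[family]
    if len(obs) < n_coef:
        raise ValueError(f"{family} fit needs at least {n_coef} observations, got {len(obs)}")
    m = np.array([o[0] for o in obs])
    k = np.array([o[1] for o in obs])
    if np.ptp(m) == 0:
        raise np.linalg.LinAlgError("degenerate design: all observations share the same m")
    if family == "power":
        if np.any(k <= 0):
            raise ValueError("power fit requires all k_max > 0")
        b, log_a = np.polyfit(np.log(m), np.log(k), 1)
        coefficients = (float(np.exp(log_a)), float(b))
        fitted = coefficients[0] * m ** coefficients[1]
    else:
        coefficients = tuple(float(c) for c in np.polyfit(m, k, _POLY_DEGREE[family]))
        fitted = np.polyval(coefficients, m)
    if np.ptp(fitted) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(k, fitted)[0, 1])
    return RegressionFit(family=family, coefficients=coefficients, r=r)


def predict_k(fit_: RegressionFit, m: int) -> float:
    """Predict the unique-pattern count for embedding dimension ``m``.

    Returns the raw model value; the bounds layer clamps it to
    ``[2, 5**(m-1)]`` (low-degree polynomial fits extrapolate negative
    for small ``m``).
    """
    if m < 3:
        raise ValueError(f"embedding dimension must be >= 3, got {m}")
    return fit_.predict(m)


def load_reference_observations() -> List[KObservation]:
    """Load the packaged reference ``(m, k_max)`` observations."""
    text = resources.files("slpen").joinpath("data/random_kmax.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    return [KObservation(int(row["m"]), int(row["k_max"])) for row in reader]
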