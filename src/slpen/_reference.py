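"""Published reference values used by the ``reproduce`` reports.

These constants are the values reported for this normalisation method
in the literature; the ``slpen reproduce`` command recomputes each
quantity with this package and prints the deviation.  They are
reference points for validation only — nothing in the computational
path reads them.
"""

from __future__ import annotations

# Near-constant-series model (N=5000, m=6, base-2): SlpEn as k-1
# singleton patterns are added to an otherwise constant-gradient series,
# k = 1..10.  Intermediate cells carry known sub-bit rounding residuals
# relative to the closed form.
CONSTANT_MODEL_N5000_M6 = {
    1: -61369.91,
    2: -28180.74,
    3: -17808.36,
    4: -12835.14,
    5: -9943.67,
    6: -8064.59,
    7: -6751.82,
    8: -5786.18,
    9: -5048.07,
    10: -4465.38,
}

# k-versus-m regression constants fitted on the packaged (m, k_max)
# observations; polynomial coefficients highest degree first, power as
# (a, b) of a*m**b, plus the linear correlation coefficient.
REGRESSIONS = {
    "linear": {"coefficients": (650.4643, -2546.2143), "r": 0.9522},
    "quadratic": {"coefficients": (116.5119, -747.6786, 1182.1667)},
    "cubic": {"coefficients": (-13.3056, 356.0119, -2091.5397, 3497.3333)},
    "power": {"coefficients": (0.0998, 4.9136)},
}

# Mean normalised SlpEn of the synthetic datasets (m=6, delta=0.001,
# gamma=0.8, N=5000, 100 records per class).
ANALYTIC_NORMALISED = {"random": 0.99942}
RECOMMENDED_NORMALISED = {"random": 0.95095, "periodic": 0.00000}
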