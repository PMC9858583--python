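"""Single-feature threshold classification of entropy values.

The point of this harness is not the classifier itself but the
invariance claim: max-min normalisation is a strictly increasing affine
map of the raw entropy (above the clip point), so any classifier that
depends on the feature only through value orderings must report the
same sensitivity and specificity before and after normalisation.  The
one place the claim breaks is clipping — once several records collapse
to exactly 0 the ordering is destroyed, which is the intended behaviour
for deterministic series under the heuristic lower bound.

The classifier is an exhaustive single-threshold rule: every midpoint
between consecutive sorted unique feature values is tried with both
polarities, and the (threshold, polarity) pair maximising resubstitution
accuracy is kept, ties broken toward higher sensitivity.  Class 0 is
the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClassificationReport", "threshold_classify", "invariance_check"]

POSITIVE_CLASS = 0


@dataclass(frozen=True)
class ClassificationReport:
    """Sensitivity/specificity of the best single-threshold rule.

    ``polarity`` is "below" when values <= threshold predict the
    positive class, "above" otherwise.
    """

    sensitivity: float
    specificity: float
    threshold: float
    polarity: str
    positive_class: int = POSITIVE_CLASS

    @property
    def accuracy_terms(self) -> tuple[float, float]:
        return (self.sensitivity, self.specificity)


def _rates(pred_positive: np.ndarray, is_positive: np.ndarray) -> tuple[float, float]:
    tp = np.count_nonzero(pred_positive & is_positive)
    tn = np.count_nonzero(~pred_positive & ~is_positive)
    sens = tp / np.count_nonzero(is_positive)
    spec = tn / np.count_nonzero(~is_positive)
    return float(sens), float(spec)


def threshold_classify(values, labels) -> ClassificationReport:
    """Fit the accuracy-maximising single-threshold rule.

    ``values`` are the feature (raw or normalised entropies); ``labels``
    the binary class labels, class 0 positive.  Both classes must be
    represented.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D arrays of equal length")
    is_pos = y == POSITIVE_CLASS
    n_pos = np.count_nonzero(is_pos)
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both classes must be present")

    uniq = np.unique(v)
    # midpoints between neighbours plus sentinels outside the range,
    # so "everything one class" rules are also candidates
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0)
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    best: tuple[float, float, float, float, str] | None = None  # acc, sens, spec, thr, pol
    for thr in candidates:
        for polarity in ("below", "above"):
            pred_pos = v <= thr if polarity == "below" else v > thr
            if not pred_pos.any() and not (~pred_pos).any():
                continue
            sens, spec = _rates(pred_pos, is_pos)
            acc = (sens * n_pos + spec * (y.size - n_pos)) / y.size
            key = (acc, sens)
            if best is None or key > (best[0], best[1]):
                best = (acc, sens, spec, float(thr), polarity)
    assert best is not None
    _, sens, spec, thr, pol = best
    return ClassificationReport(sensitivity=sens, specificity=spec, threshold=thr, polarity=pol)


def invariance_check(raw, normalised, labels) -> bool:
    """True iff raw and normalised features classify identically.

    Holds whenever the normalisation is strictly increasing over the
    observed values (no clipping); fails by design when clipping
    collapses records to the bound.
    """
    raw_report = threshold_classify(raw, labels)
    norm_report = threshold_classify(normalised, labels)
    return (
        raw_report.sensitivity == norm_report.sensitivity
        and raw_report.specificity == norm_report.specificity
    )
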