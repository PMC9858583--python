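# Methods

## The measure

Slope entropy symbolises the differences between consecutive samples of
a univariate series. For an input x₀…x_{N−1} and embedding dimension m,
each of the N−(m−1) overlapping subsequences of length m yields the
m−1 differences d = x_j − x_{j+1} (earlier minus later; the orientation
is part of the definition and not configurable). Each difference maps
to one of five symbols:

| symbol | condition |
|---|---|
| +2 | d > γ |
| +1 | δ < d ≤ γ |
| 0 | \|d\| ≤ δ |
| −1 | −γ ≤ d < −δ |
| −2 | d < −γ |

The five conditions partition the real line; boundary values follow the
inequalities literally (d = γ → +1, d = δ → 0), with no floating-point
epsilon. The histogram of the k distinct symbol strings observed feeds
a Shannon-form sum with relative frequencies pᵢ = cᵢ/k. Two properties
follow that are intentional and must not be "corrected":

- Σpᵢ = n_sub/k ≠ 1, so the value is not a probability-normalised
  entropy; using k preserves the information carried by the scarcity of
  observed patterns relative to the 5^(m−1) theoretically possible.
- The value is unbounded below. A series with a single pattern (any
  constant-gradient series) attains −n_sub·log₂ n_sub exactly.

All logarithms are base 2 and all entropy values are in bits. This is
load-bearing: the closed-form extremes, the near-constant model and the
normalised synthetic means are only mutually consistent in base 2.

## Parameters

- **m** (default 6): subsequence length; symbol strings have length
  m−1. Must be ≥ 3 (m = 2 would leave single-symbol strings and no
  slope structure). The theoretical pattern count 5^(m−1) grows fast;
  the observed k saturates orders of magnitude below it.
- **δ** (default 0.001, in units of the sample differences): half-width
  of the "flat" band. Should exceed the noise floor/quantisation step of
  the signal, otherwise ties split between 0 and ±1.
- **γ** (default 0.8): steep-slope threshold, 0 ≤ δ < γ. For z-scored
  signals 0.8 separates large from moderate excursions.
- **samples_per_pattern** (default 100): the heuristic lower bound
  assumes one extra singleton pattern per this many samples.

The defaults are the configuration under which all reference results in
this package were produced.

## Normalisation bounds

Max–min scaling (SlpEn − lower)/(upper − lower), clipped below at 0.

**Analytic.** lower = −N·log₂N, the simplified form of the exact
constant-gradient minimum −(N−m+1)·log₂(N−m+1) (m ≪ N makes the
difference negligible; the exact form is exposed as `exact_min`).
upper = the uniform-histogram expression f(k) = (N/k)·log₂(k²/N) at its
continuous maximiser k* = e√N, i.e. 2√N/(e·ln 2) bits. Note the
ln 2 factor: the natural-log algebra of the maximisation gives 2√N/e,
but the entropy itself is computed in bits, and only the base-2 value
is consistent with the rest of the pipeline (it is also the value that
reproduces the published normalised results). These bounds are provable,
so nothing clips — but real signals compress into ≈[0.95, 1].

**Heuristic.** lower = the near-constant model
−((n_sub−(k−1))/k)·log₂((n_sub−(k−1))/k) − (k−1)·(1/k)·log₂(1/k) at
k_h = max(1, round(N/100)) — the entropy of a series that is constant
except for one singleton pattern per 100 samples. Python's round()
(banker's at .5 ties) is used; the alternative convention differs by
<0.3% of the bound. N, not n_sub, enters the ratio; n_sub enters the
model. Deterministic series fall below this bound and clip to exactly
0 — intended behaviour, at the cost of classification within the
clipped group. upper = f(k̂) with k̂ from a k-versus-m regression,
clamped to [2, min(5^(m−1), n_sub)].

**Recommended** (default): heuristic lower + analytic upper. The
heuristic upper bound changes little (the logarithmic geometry expands
mainly the lower end of the interval) and forfeiting the provable
maximum risks values above 1; under `heuristic_both` values above 1 are
defensively capped with a warning.

Bounds are evaluated per record with that record's own N, so
mixed-length datasets normalise correctly.

## k-versus-m regressions

Four families approximate the observed maximum pattern count k_max(m)
of random series: polynomials of degree 1–3 by ordinary least squares
and a power law a·mᵇ fitted by OLS of log k on log m. Log-log OLS was
chosen for the power family because it reproduces the published
constants (a = 0.0998, b = 4.9136) exactly on the packaged reference
observations; a direct nonlinear fit would weight large-m points more
heavily and land elsewhere. The correlation coefficient r is defined as
Pearson correlation between observed and fitted values, which for the
linear family equals the raw-pair correlation; for the nonlinear
families other definitions are possible and yield different numbers.
The packaged observations (data/random_kmax.csv) are maxima over 100
random records of length 5000 for m = 3…9; regenerating them from
scratch is not attempted because the generating distribution behind
them is not fully specified.

## Synthetic data

The generators emulate the validation datasets:

- *random*: 100 standard-normal records (class 0) and 100 uniform
  records (class 1), N = 5000. The uniform class is zero-mean with unit
  variance ([−√3, √3]): moment-matching the two classes is the regime
  where the entropy feature, not amplitude, carries class information,
  and it reproduces the reference per-class raw SlpEn (≈39.8 vs ≈39.3
  bits) that a unit-interval uniform does not (≈28 bits).
- *periodic*: 100 sinusoids of period 100 (class 0) and 100 of period
  500 (class 1), unit amplitude, phase uniform on [0, 2π), N = 5000.
  Consecutive differences are bounded by 2A·sin(π/T), so long-period
  unit sinusoids use only the {+1, 0, −1} symbols at the default γ.

What these generators do not emulate: real EEG/consumption records
(nonstationarity, artefacts, 1/f spectra), amplitude heterogeneity, or
noise-contaminated periodicity. Passing tests therefore demonstrate the
algebra and the normalisation behaviour, not field performance on
clinical data.

## Classification harness

The published validation reports sensitivity/specificity without
specifying a classifier; this package uses the simplest rule consistent
with the invariance claim: an exhaustive single-threshold search over
midpoints of sorted unique feature values, both polarities, maximising
resubstitution accuracy with ties broken toward higher sensitivity
(class 0 positive). The invariance of sensitivity/specificity under
normalisation holds for any order-based rule, so the choice of
classifier does not affect the claim being tested. When accuracy ties
occur, the reported (sensitivity, specificity) pair depends on the
tie-break and is not symmetric under label/polarity flips — only the
accuracy and the achievable rate set are.

## Numerical and degenerate-input choices

- Counts are always ≥ 1, so 0·log 0 never arises (asserted, not
  guarded).
- Series must be finite, 1-D, length ≥ 2 (≥ m for entropy); violations
  raise ValueError at the boundary.
- A constant-gradient step within one ulp of δ or γ can symbol-split
  because boundary comparison is exact; the k = 1 guarantee for
  constant-gradient series assumes the step is not on a threshold.
- The near-constant model at (n_sub = 4995, k = 10) evaluates to
  −4465.33 bits; published tabulations of the same quantity carry
  sub-bit rounding residuals in intermediate k cells.

## Problem sizes

The test suite and the acceptance script use the reference problem
sizes throughout: N = 5000 for the synthetic datasets (200 records per
dataset), N = 66 for the worked outlier example, N ≤ 600 series for
randomized bound checks, and brute-force maximiser searches over all
k < N. The full suite runs in seconds on one CPU; nothing is scaled
down.

## Known limitations

- SlpEn and both bound families depend on N; normalisation reduces but
  does not remove length dependence. Length-independent redesign is out
  of scope.
- The heuristic-both scheme's upper bound is approximate; its published
  validation values are not reconstructible from the stated formulas
  and are not used for verification here (the recommended scheme is).
- Loaders for the real EEG/power-consumption benchmark datasets are out
  of scope; the CLI operates on plain-text/CSV series.
- Multiscale variants, alternative alphabets, and the cᵢ/n_sub
  probability normaliser are non-goals.
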