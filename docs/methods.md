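# Methods

## The problem

Granger causality (GC) declares a directed influence `i → j` when the
history of channel `i` reduces the prediction error of channel `j` beyond
what `j`'s own history (and every other channel) already achieves.  The
classical formulation fits linear vector autoregressions and therefore
misses nonlinear couplings and struggles with long or variable
transmission delays — both ubiquitous in neural signals.  This package
replaces the linear regression with recurrent sequence models:

* **bi-LSTM-GC** — a stacked bidirectional LSTM whose regression window
  extends on *both* sides of the prediction position.  This is the only
  estimator here that can represent *forward dependencies*: couplings in
  which a channel's current value is driven by another channel's future
  samples (negative lag).
* **RNN-GC** — a single-layer unidirectional LSTM over the past window.
* **NN-GC** — a one-hidden-layer feed-forward network on the flattened
  lag window (`ceil(2/3 × input width)` hidden units).  Flattening
  deliberately discards temporal structure; the baseline exists to show
  what that costs.
* **linear_gc_oracle** — plain OLS vector autoregression, retained as an
  independent reference implementation of classical GC.

The GC index for every estimator is the classical log error ratio

```
GC(i → j) = ln( err_restricted / err_full ),
```

floored at zero in reported matrices, where the errors are mean-squared
prediction errors on a **held-out tail** of the series (final 20% of
windows).  Training-set errors are never used: with flexible regressors
they reward overfitting and can drive the ratio below zero

## Regression protocol

One full model is trained per target channel.  Windows are built from
all channels:

| estimator       | window                                   | readout |
|-----------------|------------------------------------------|---------|
| bi-LSTM-GC      | positions t−10 … t−1, t+1 … t+10         | forward state at t−1 ⊕ backward state at t+1 |
| RNN-GC          | positions t−20 … t−1                     | terminal state |
| NN-GC / linear  | flattened lags t−p … t−1 (order p)       | — |

The position `t` itself is excluded from every window so no model sees
the value it predicts.  Channels are centred and scaled to unit variance
with statistics from the training range.  The bidirectional stack is
three layers deep; each layer above the first receives the concatenated
forward and backward output sequences of the layer below, and both
directions feed one linear readout.  Boundary positions lacking full
context are dropped, not padded.

Training is mini-batch Adam (batch 256, learning rate 1e-2, 50 epochs)
on mean-squared error, with hand-derived backpropagation-through-time
verified against finite differences in the test suite.  All weights and
the shuffling order derive from one seed, so runs are bit-reproducible.
A full-batch schedule was tried first and rejected: at desk-scale window
counts it yields only a few dozen optimizer steps and visibly underfits
the weak couplings.  Time-critical recurrent loops have a numba-compiled
fast path over time-major arrays; the pure-NumPy path remains and the two
are asserted equal in tests.

**Restriction.** Removing a source channel can mean retraining without it
(`retrain_without_channel`, the strict Granger reading) or zeroing its
input stream at inference (`ablate_input_at_inference`).  The neural
estimators default to ablation — it is O(1) extra cost and makes
multi-trial averaging affordable — the linear oracle to retraining, which
for OLS is cheap and exactly the textbook statistic.  Ablation has a
known redundancy bias in both directions: a network that spreads weight
over correlated inputs loses accuracy when one is zeroed even if the
information is redundant (upward bias), and can compensate a zeroed
channel with correlated proxies (downward bias, visible on the
bidirectional benchmark's weakly coupled forward channels).

**Trial averaging.**  Matrices are averaged over `n_trials` independent
training seeds (default 10; the scaled protocols below use 3–5).  When
the input is a simulator specification rather than a fixed recording,
each trial also draws a fresh realization.

## Detection

Scores are tested against **circular-shift surrogates**: the source
channel is rotated by a random offset of at least one window length,
which preserves its autocorrelation while destroying cross-channel
alignment, and the score is recomputed with the trained models (no
retraining, evaluated on the same held-out windows).  Two rules:

* `detect_edges` screens all ordered pairs and by default thresholds at
  the (1−alpha) quantile of the **across-pair maximum** surrogate score
  (the permutation analogue of family-wise error control, standard in
  neuroimaging).  Per-pair uncorrected thresholds are available
  (`correction="none"`).  Uncorrected per-pair tests at alpha = 0.05
  over the 15–38 null pairs of the benchmarks would admit a false edge
  in roughly half of all runs, which is why the family-wise rule is the
  default.
* `detect_pairs` tests a named set of pairs only (hypothesis-driven),
  each against its own per-pair null; only the targets involved are
  fitted, which makes trial-averaged tests affordable at full series
  length.

In both rules an edge must additionally have a strictly positive score:
a pair whose restricted model outperformed its full model is never an
edge, whatever the null quantile.

## Benchmarks and what they show

Three simulators generate channels×samples matrices with known directed
dependencies: a five-channel linear model (A); the same topology with
the 1→2 coupling made quadratic with a 10-sample delay (B); and model B
plus two forward-dependent channels y1, y2 driven by future samples of
x1, x4, x5 (C).  x1 is an AR(2) with poles of modulus 0.95 and a
pseudo-period near six samples; a 100-sample burn-in is discarded so the
returned window is near-stationary regardless of the zero initial state.
In model C the last two samples of y1/y2 have no future source inside
the window and are filled with standard-normal draws; the generator
records the fill count.  The y1/y2 noise streams are independent by
default; a `shared_as_written` mode reuses the x2/x4 innovation streams
for callers who want the literal equation reading, at the price of
spurious instantaneous correlation.

Scaled protocol sizes used by the tests and the acceptance script
(chosen as desk-scale conditions; all are package defaults, overridable):

* linear oracle: length 5000, 10 seeds — recovers exactly the five true
  edges of model A at the 95% family-wise surrogate threshold.
* model B, bi-LSTM-GC: length 2000, 5 trials.
* model C, forward dependencies: full printed length 5020, pair-level
  tests with 5 trials; the acceptance script uses length 3500 with 3
  trials.
* EEG cohort: 25 subjects, 60 s segments at 128 Hz.

## A structural limit of acausal GC (two-sided windows)

A two-sided regression window conditions on *effects*: if `x4(t+2) =
−0.5·x1(t) + …`, then for target x1 the source x4's future samples are
direct noisy measurements of x1(t), so the reverse score 4→1 carries
genuine conditional information — an independent two-sided OLS check on
model B puts it at the same order as the weakest true coupling.  The
quadratic coupling produces the analogous 2→1 magnitude leak.  These are
not estimation artifacts; any faithful conditional-dependence test in an
acausal design must flag them, because pairwise they are observationally
identical to the forward dependencies of model C (both are "source
future informs target present"; only the position of the innovation in
the generating equations differs, which no pairwise statistic can see).
Consequently bi-LSTM-GC on model B detects all five true couplings but
*also* reports reverse edges of the strong couplings; the corresponding
acceptance test states the no-false-alarm claim and is expected to fail
on its second assertion.  Distinguishing the two cases needs multivariate
structure learning (which equation carries the noise), out of scope here.
On model C the same two-sided window is exactly what makes the four
forward couplings detectable, including the short-lag 4→7 and 5→7
couplings that a causal model provably cannot see (the source innovation
at t+1 is unforecastable from the past) — this asymmetry between
bi-LSTM-GC and RNN-GC is the method's central claim and reproduces
robustly.

## EEG pipeline

Recordings (channels×samples with electrode labels, sampling rate given
by the caller) are decomposed with order-10 Chebyshev type-I bandpass
filters (0.5 dB passband ripple) into delta 0.5–3, theta 4–7, alpha
8–13, beta 13–30 and gamma 31–50 Hz, applied forward–backward so the net
phase is zero and the magnitude response squares.  After filtering, each
band is decimated by `floor(fs / (2.5 × high))` so the passband occupies
a healthy fraction of the new Nyquist rate; without this, narrowband
series are nearly deterministic given their own past and the error
ratios degenerate (held-out errors of order 1e−6 and wildly unstable
scores were observed at 128 Hz without decimation).  Preprocessing is
linear detrend, demean, and an augmented Dickey–Fuller unit-root check
per channel (lag search capped at 10 for speed); failing channels are
first-differenced once, re-tested, and flagged for rejection if still
failing, mirroring the exclusion of non-stationary recordings.

Per (subject, segment, band) unit, a GC estimator (configurable; the
default is the linear oracle with order 5 — per-unit neural training
over cohorts is possible but far from desk-scale) scores every ordered
electrode pair; the signed strength and a per-unit detection flag
(strength > 0) become one `EdgeRecord`.  **Stable dependencies** are
groups of records by (source, target, band) that pass three rules: a
one-sample two-sided t test of the strengths against zero at p < alpha
(0.05), strictly more than `min_count` (10) detections, and positive
mean strength.  The t test is two-sided for fidelity to common practice,
so the positive-mean rule is needed to stop significantly *negative*
groups — restricted models beating full ones — from entering the table.
No multiple-testing correction is applied by default (an optional
Benjamini–Hochberg flag exists), because the occurrence-count rule
already acts as a replication filter.  Stable edges are finally mapped
through the packaged 34-electrode / 10-region extended 10/20 montage and
summarized as fractions of edges flowing between ordered region pairs.

The synthetic cohort generator emulates per-electrode background EEG as
a one-pole-lowpass pink-like process plus a white floor, with planted
band-limited lagged couplings of stated coefficient and lag.  It
reproduces the statistical skeleton the pipeline needs (band-limited
spectra, independent subjects, recoverable couplings) and none of the
physiology: no volume conduction, no shared reference, no artifacts, no
inter-subject variability in coupling strength.  Passing tests therefore
demonstrate that the chain of operations is correct and calibrated on
its stated assumptions — not that real recordings satisfy those
assumptions.

## Numerical choices and degenerate inputs

* Held-out errors below 1e−12 (on standardized data) raise
  `PerfectFitError` instead of producing infinite ratios.
* Constant target channels and series too short for one window are
  rejected with explicit errors.
* Surrogate offsets are drawn from one seeded stream and shared across
  pairs and trials, enabling the max-statistic rule.
* `detect_pairs` evaluates observed and surrogate errors on the same
  (at most 400, evenly spaced) held-out windows, keeping the statistic
  exchangeable while bounding cost at full length.
* All seeds derive from one root via named substreams
  (`simulate/…`, `estimate/…`, `detect/…`); reruns of a manifest are
  byte-identical.
* Forget-gate biases initialize at +1 (remember by default), other
  weights Glorot-uniform; the scalar readout bias trains with Adam like
  every other parameter.

## Known limitations

* Ablation-based restriction inherits redundancy biases (see above);
  retraining is available but multiplies cost by the channel count.
* The acausal false-alarm structure on effect channels is inherent to
  two-sided windows (see the dedicated section).
* The NN-GC baseline underperforms by design; its model order (5 for the
  five-channel benchmarks, 7 for model C) is a protocol constant, not a
  tuned value.
* Whether the bidirectional readout should use every position's states
  rather than the two flanking the prediction gap is an open design
  point; the flanking-states choice keeps the readout position-explicit.
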