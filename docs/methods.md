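# Methods

## Signal model

A session is a randomized sequence of 16 trials from a 2 × 4 × 2 factorial
design (saturation × question × repetition). Each trial runs through four
stages — problem judgment (4 s), picture viewing (6 s), answering (6 s),
fixation/rest (8 s) — laid out back-to-back after a 10 s initial rest, with
a 10 s tail so late responses decay inside the recording.

The simulator generates ΔHbO₂ per channel as a sum of event-related
responses: each stage of each trial contributes
`amplitude(question, stage) × HRF(t − onset)`, where the HRF is the
canonical double-gamma (unit-scale gammas peaking at 6 s with a 16 s
undershoot weighted 1/6), peak-normalized to 1 so a stage's amplitude is
exactly its peak concentration change in µM-equivalent units. ΔHb is
−0.3 × the clean ΔHbO₂ (typical task anticorrelation) plus independent
noise, and ΔHbt = ΔHbO₂ + ΔHb by definition. Noise per channel comprises
white noise (SD 0.1), sinusoidal physiological rhythms with random phase —
cardiac (1 Hz, amp 0.05), respiratory (0.3 Hz, 0.05), Mayer waves (0.1 Hz,
0.05) — and a slow linear drift (5 × 10⁻⁴ µM/s, random sign). Hb noise
amplitudes are scaled by the same 0.3 factor as its response.

Class amplitude patterns are a *study-level* property: one per-channel
vector per (question, stage), drawn once per study (default: positive
values in [0.7, 1.3] for task stages, zero for fixation, so every task
evokes an activation). Between-participant variability enters only through
a multiplicative response gain (default SD 0.2 around 1, floored at 0.1).
Questionnaire scores follow `baseline + coupling × gain + noise`
(5 + 1.0·gain + N(0, 0.1) by default), so higher-responding participants
score higher in expectation.

Raw intensities are emitted through the forward Beer–Lambert model
(I_t = I_b·10^(−ΔOD)) with the baseline intensities carried explicitly, so
inversion is an exact round trip (verified to 1e−9 over 1000 random
concentration pairs; in practice ~1e−14).

Sampling rate defaults to 10 Hz and the answer-stage duration to 6 s; the
acquisition hardware specifies neither, so both are configuration, chosen
as typical values that keep the nominal session near five minutes.

## Beer–Lambert inversion

Optical density uses base-10 logarithms (the optical-density convention).
Extinction coefficients at 760/850 nm are tabulated literature constants in
1/(mM·cm), shipped as overridable configuration; source–detector distance
defaults to 3 cm and DPF to 6 (long-channel values). Because d·DPF is a
common factor, outputs are *relative* concentration changes; every
downstream statistic is invariant to this common scale once normalization
is applied. When a recording carries no explicit baseline, I_b is the mean
intensity over the first 5 s of the session (configurable). The 2×2 solve
uses Cramer's rule; a singular extinction matrix is rejected at
configuration time.

## Filtering, normalization, windowing

The band-pass is a second-order Butterworth applied forward–backward
(zero phase, via second-order sections for stability at the 0.01 Hz edge),
so stage labels stay aligned with the filtered response. Only the lower
cutoff (0.01 Hz) is prescribed by the protocol; the upper edge defaults to
0.5 Hz, which keeps the hemodynamic band and suppresses cardiac pulsation.

Min–max normalization is applied per channel, per signal, over the whole
session, so within-session amplitude structure survives; per-window scope
is available. Constant vectors normalize to zeros with a warning rather
than raising (dead-channel robustness). The original (min, max) are stored,
so normalization is exactly invertible for non-constant vectors.

Windows are half-open `[onset, onset + duration)` against the sample grid;
each sample belongs to at most one window. Two modes: `task_baseline` (per trial,
one task window spanning judgment through answering plus one fixation
baseline window — 32 windows/session) and `per_stage` (one window per
stage — 64/session). The 16-class stage × question analysis uses
`per_stage`; the 4-class question analysis uses `task_baseline` task windows.

## Mutual-information channel screen

Pairwise MI is the plug-in estimator on equal-width 10-bin histograms of
the normalized task-window samples concatenated per question (quantile
binning available, which makes the estimate invariant to monotone
transforms). Base-2 logs make I(X;X) = log₂(bins) exact for uniform data.
Each channel's score is its mean off-diagonal MI; the top k = 7 are
retained per (question, signal), ties broken lexicographically (a
threshold mode exists, since the retention rule could equally be framed as
a cutoff). The per-question "common channels" are the intersection across
the three signals. For the cross-question feature table one channel set is
needed; it is the top 7 by mean off-diagonal MI pooled (averaged) over all
12 question × signal matrices. The plug-in estimator's positive bias on
independent data is ≈ (bins−1)²/(2N ln 2); the screen compares channels at
equal N, so the bias cancels in the ranking.

## Features

Nine per (window, channel, signal): window duration in seconds ("time" —
stages have distinct nominal durations, making this well-defined and
discriminative; a mean-timestamp alternative would be arbitrary under
randomized trial order), mean, median, population variance, range, excess
kurtosis, Fisher–Pearson skewness, Shannon entropy of a 10-bin equal-width
histogram (bits), and approximate entropy (nats; m = 2, r = 0.2 × SD,
Chebyshev distance, self-matches included — the field-standard settings).
Constant windows define variance, kurtosis, skewness, entropy and ApEn as
0. ApEn is computed with a vectorized template-distance matrix and matches
the literal O(N²) definition to 1e−12. Note the estimator is non-monotone
in r at very small tolerances (sparse-match regime); monotone decrease
holds for r ≳ 0.5 SD.

With 7 retained channels the table is 7 × 3 × 9 = 189 feature columns per
window. (The protocol description's "32 × 9" feature count does not factor
against 15 channels × 3 signals; the table's shape here is driven by the
channel selection, and the discrepancy is left documented rather than
forced.)

## Classification

Classes default to the 16 stage × question categories; a 4-question mode
exists. Outer evaluation is stratified 5-fold CV with out-of-fold
predictions only — the full model (standardization, RFE, K selection) is
refit from scratch inside every training fold. RFE eliminates 10% of
features per iteration down to 30, ranked by multinomial
logistic-regression coefficient magnitudes (KNN itself provides no feature
importances, so a deterministic linear ranking model is the standard
surrogate). K is chosen from {1, 3, 5, 7, 9} by an inner stratified 3-fold
grid search; distance is Euclidean on z-scored features (the nine features
live on different scales — seconds, bits, variances — so unstandardized
distances would be dominated by one unit). Metrics are computed one-vs-rest
per class from TP/TN/FP/FN — accuracy (TP+TN)/N, precision TP/(TP+FP),
recall TP/(TP+FN), F1 = 2PR/(P+R), with zero-denominator cases defined as
0 and logged — and summarized as unweighted mean ± SD across classes,
reported in percent to one decimal. Wall-clock time is recorded for
information only.

## Score-group comparison

Scores for a question are split at their mean (ties to the low group; a
degenerate split raises). The unit of analysis is the participant — window
means are averaged within participant before testing — to avoid
pseudoreplication. The per-participant statistic is the *fixation-referenced*
task-window mean: the mean over the question's task windows minus the mean
over the same trials' fixation windows. The referencing matters: zero-phase
high-pass filtering at 0.01 Hz removes the session-mean response level, so
an unreferenced task mean measures only a question's contrast against the
average response across all questions — a quantity that can be near zero on
a channel and is then blind to a global amplitude difference between
participants. Referencing to rest restores the response level, the quantity
the score comparison is about. For the same reason the comparison runs on
the filtered but *unnormalized* series: per-participant min–max scaling
maps every participant onto [0, 1] and would cancel the between-participant
amplitude gap exactly. Groups are compared per channel and signal with
Welch's t-test (Mann–Whitney optional); raw p-values are reported by
default with Benjamini–Hochberg correction behind a flag, matching the
per-channel reporting convention of this literature. Under null coupling
the procedure's type-I error is calibrated (~5%, verified over 200
simulated datasets).

## What the simulator does and does not show

The generator reproduces the design's combinatorics, task-locked
double-gamma responses with Hb anticorrelation, stationary sinusoidal
physiological noise, drift, and score–amplitude coupling. It does **not**
emulate motion artifacts, scalp/superficial contamination (no
short-channel regression is modeled), non-stationary noise, habituation
across trials, spatial correlation between neighboring optodes, or
realistic photon transport. Passing tests therefore demonstrate that the
*analysis chain* is correct and recovers known structure under the stated
noise model — not that real recordings would yield the same accuracies.
In particular, near-perfect 16-class accuracy on synthetic cohorts partly
reflects the distinct per-class amplitude patterns and the discriminative
window-duration feature, both of which are cleaner than reality.

## Problem sizes and numerical choices

The shipped evaluation runs use cohorts of 10 participants (640 per-stage
windows) for the classification benchmark and 20 participants for the
group comparison, sizes at which the statistical structure is already
unambiguous while a full run stays under a minute on one CPU; the
29-participant full-size cohort is available via `make_fixtures(size="task_baseline")`.
All randomness flows from one master seed through named `SeedSequence`
substreams (patterns, gains, per-participant schedule/noise/scores), so
every artifact is bit-reproducible. Floating-point tie-breaks: channel
ranking ties resolve lexicographically; KNN ties resolve by sklearn's
class ordering; half-open windowing assigns boundary samples to the later
window.

## Known limitations

- MI retention compares channels with the plug-in estimator at a fixed bin
  count; very short sessions inflate all estimates (the ranking, not the
  absolute values, is meaningful).
- The logistic-ranking RFE is a surrogate for "features that help KNN";
  a wrapper selection around KNN itself would be slower and noisier but
  more faithful.
- The per-question retained channel identities are data-dependent; only
  the retention count and the intersection logic are design-determined.
- Filtering is applied session-wide before windowing, so window edges
  carry a few samples of filter ringing from neighboring stages; the
  commutation error is confined to window borders.
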