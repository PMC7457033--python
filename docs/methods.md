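# Methods

## Scope and data model

The package analyses longitudinal motor-attempt BCI training sessions:
continuous 31-channel EEG at 200 Hz with cue markers (`Recording`), labelled
fixed-length trial segments (`EpochSet`), per-session decoding accuracies
(`AccuracyRecord`), ERD values and scalp maps, and per-patient clinical
records. Recordings are exchanged as BrainVision triplets
(.vhdr/.vmrk/.eeg; multiplexed binary, IEEE_FLOAT_32 or INT_16 with
per-channel resolution scaling). The montage is the 31-electrode 10–20 cap
(FP1 … FP2) with a 7-channel motor strip (FC1, FC2, C3, CZ, C4, CP1, CP2)
as the reduced decoder input; 2-D positions come from the standard 10–20
template (MNE), sphere-fitted and flattened by an azimuthal-equidistant
projection.

## Synthetic EEG generator

The generator is the package's study bed: it emulates the training protocol
(11-s trials, cue at 3 s, 3 runs × 30 trials, 12 sessions; uniformly
jittered 1–3 s rest intervals) with a known ground truth, so estimator
accuracy can be asserted, not assumed.

Signal model per session, generated continuously to avoid splice artefacts:

- two rhythm sources, one per motor cortex, each the sum of band-limited
  Gaussian noise in the mu (8–13 Hz, amplitude 4 µV) and beta (14–30 Hz,
  2 µV) bands, mixed to the cap through Gaussian spatial profiles centred
  at C3 and C4 (σ = one median inter-electrode spacing, peak weight 1);
- 1/f Gaussian background noise (exponent 1.0, 1 µV per channel, spectrum
  flattened below 0.5 Hz) plus white sensor noise (0.5 µV);
- during task trials the source amplitude is multiplied by √g over
  `[cue+1, cue+4]` s, so in-band power drops to the fraction g of rest and
  the programmed ERD is exactly `E = g − 1`; idle trials are statistically
  identical to rest throughout.

The rhythm dominates the 8–30 Hz band at the profile peak (in-band
signal-to-background ratio ≈ 65:1), so the measured ERD tracks g with a
bias below 2% — well inside the ±0.05 recovery tolerance the tests assert.
Task/idle classes are balanced 15/15 per run (the protocol source does not
state proportions; a single accuracy number presumes balance). The
contralesional mirror channel expresses a configurable fraction (default
0.8) of the ipsilesional effect.

Longitudinal phenotypes set the per-session depth schedule g₁…g₁₂:
*increasing* interpolates linearly 0.9 → 0.3 (ERD deepens with training),
*sustained* holds 0.35, *weak* holds 0.98 (no usable modulation), and
*bilateral-mixed* alternates 0.55/0.9 with full contralesional expression.
The default 7-patient cohort mixes these (2/2/2/1) with two
right-hemisphere lesions, mirroring the phenotype mix such studies report.
Randomness is a counter-based stream keyed by (study seed, patient id,
session), so outputs are byte-identical under a fixed seed and independent
of generation order.

What the generator does **not** emulate: volume-conducted artefacts
(EOG/EMG), non-Gaussian and non-stationary background dynamics, electrode
impedance drift, or a physical head model (no BEM lead field). Passing
tests therefore demonstrate estimator correctness under the stated model,
not clinical performance on real EEG.

## Preprocessing and epoching

Band filtering is a 4th-order Butterworth applied forward–backward (zero
phase); decoding uses the 8–30 Hz band. Epochs are half-open sample windows
`[start, end)` relative to the cue (so `[1, 4)` s at 200 Hz is exactly 600
samples, cue+200 … cue+799); trials whose window would cross a recording
edge are dropped and counted in a logged warning, never zero-padded. For
decoding, the task state is the `[1, 4)` s window after task cues and the
idle state a `[−4, −1)` s rest window around static-trial cues — one epoch
per trial, 90 per session, in acquisition order.

## CSP decoding

Per-trial spatial covariances are trace-normalised before averaging per
class, then shrunk, `C ← (1−γ)C + γ (tr C/n) I` with γ = 1e−4, which keeps
degenerate inputs (flat channels, few trials) positive definite. The
generalised eigenproblem `C_task w = λ (C_task + C_idle) w` is solved
against the composite covariance; eigh's normalisation yields the whitening
property `W (C_task + C_idle) Wᵀ = I`, every λ ∈ [0, 1], and the idle-class
eigenvalue of the same filter is 1 − λ. Filters are sorted by λ descending
and the first/last 3 rows retained (6 features); features are normalised
log-variances, which cancels global amplitude scaling.

Offline accuracy is block-wise cross-validation with the acquisition runs
as folds (3 folds for a standard session), pooled correct/total; a seeded
`shuffle_folds` option provides random thirds instead. The offline
classifier is a 100-tree random forest with a fixed seed (LDA available).
Online accuracy replays the session: run 1 trains the initial CSP + LDA;
every later trial is classified in order, its true label revealed, pushed
into a 30-trial ring buffer (pre-seeded with run 1), and the model refit on
the buffer — skipping the refit (and keeping the prior model) if the buffer
momentarily holds one class. Evaluation covers all post-run-1 trials by
default (60 trials); a `run2` option restricts scoring to the second run,
since protocol descriptions of this design are ambiguous about the scored
range. Session trends report the best session (ties resolve to the *later*
session, so only genuine late peaks land in the "last six" subgroup), the
first-six/last-six subgroup, and the 12-session mean; mean online accuracy
above 0.70 is labelled workable BCI control.

## Time–frequency analysis and ERD

`F(t, f) = Σₙ x(t+n) h(n) e^(−i2πfn/fs)` with h a 200 ms Hanning window
(41 taps at 200 Hz, symmetric, centred on t), evaluated by direct DTFT at
integer frequencies 1–30 Hz — not FFT-bin snapping — on a 5 ms grid over
`[−2000, 6000]` ms (1601 × 30 points). Grid points within half a window of
the epoch edges use the truncated window and carry an edge flag; ERD epochs
are cut at `[−4, 7)` s so all analysis windows stay interior. Power is
`P = |F|²`, averaged across trials *before* the ratio (pooled-power ERD
rather than averaging per-trial ratios; the pooled form has lower variance
and avoids the Jensen bias of per-trial ratios). Then `E = (A − R)/R` with
R the mean over the `[−2, 0]` s baseline and A over the interest window
(`[1, 4]` s for channel ERD, `[1.4, 1.6]` s for topographies), restricted
to the 8–30 Hz band. E is stored as a fraction (−0.5 = 50% suppression);
percent is a formatting option. Per-trial transforms run in single
precision and are accumulated in double — the error is orders of magnitude
below trial-to-trial sampling noise (verified in a test).

Topographies evaluate E per channel and interpolate with inverse-distance
weighting (power 2) on the projected 2-D positions; interpolation is exact
at electrode sites and masked outside the head circle. Rendering is a plain
matplotlib colormesh — values, not publication styling.

## Clinical statistics

Group summaries are mean ± sample SD (n−1), rounded to one decimal for
report parity. The improvement percentage is the mean FMA-UE gain divided
by the 66-point scale maximum × 100 — the only convention that reproduces
both published arm values simultaneously. Responders are gains strictly
greater than 5 points. Paired t-tests are classical two-sided tests on the
differences (df = n−1); zero-variance differences raise rather than return
a fabricated p. The 2×2 fully-within ANOVA (time × channel on ERD) uses
classical sums of squares with subject-by-effect error terms; for 2-level
factors every F provably equals the squared paired t on the subject-wise
contrast, which the tests assert to 1e−10 and cross-check against pingouin.
The mixed ANOVA (time within, group between) uses balanced split-plot sums
of squares (Type II ≡ Type III on balanced data): the group effect tests
against subjects-within-groups, time and the interaction against the
time × subject(group) residual.

The bundled reference dataset (two arms of seven subacute stroke patients:
demographics, pre/post FMA-UE, T1/T12 ERD per hemisphere) drives the worked
examples and parity tests. Note one known quirk: the control arm's
*published* summary cells (age 52.0, time-since-injury 3.9 months) do not
equal the summaries of the listed per-patient entries (52.7, 3.5); the
package always recomputes from raw entries. Recomputed test statistics on
ERD values rounded to 3 decimals differ slightly from statistics computed
on unrounded data (e.g. time F 8.888 vs 8.927); parity checks therefore use
tolerances |Δp| ≤ 0.005 and |ΔF| ≤ 0.1.

## Pipeline and problem sizes

`run_study` chains simulate → decode (online-31, offline-31, offline-7) →
ERD (T1/T12, both hemispheres) → per-session topographies → statistics into
CSVs plus a sorted-key JSON report; a rerun with the same seed is
byte-identical. FMA-UE gains can be co-simulated from the phenotype
(16/8/2/3 points ± 1) to exercise the responder logic. The default full
study (7 patients × 12 sessions, all three decoder configurations) runs in
roughly 3–4 minutes on one CPU; the test suite uses scaled problems
(2-session studies, 10–20 trials per run, 100-trial estimator checks)
chosen so each assertion still has the statistical resolution it needs.

## Known limitations

- The generator's linear-mixing, Gaussian model understates real EEG
  non-stationarity; online-adaptation gains are demonstrated on programmed
  within-session drift, not measured physiology.
- The 2×2 ANOVA implementation is specialised to 2-level within factors
  (the design used here), not a general factorial engine.
- IDW interpolation is a display convenience; no spherical-spline
  interpolation or statistical masking of maps.
- EDF export is not provided; BrainVision and CSV cover interchange.
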