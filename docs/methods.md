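# Methods

This note documents the models, numerical conventions and design choices
behind `emokinetics`, and what the bundled synthetic-data generator does and
does not emulate.

## Time conventions

BOLD sample `i` of a run covers `[i*TR, (i+1)*TR)` seconds (TR = 2.4 s
throughout the defaults). Interpolated rating series are evaluated at the
left edge `t = i*TR` of each interval; this keeps the invariant that the
first sample of every movie clip is exactly zero, matching the convention
that ratings reset at each scene start. Clip intervals are half-open
`[onset, offset)` in seconds from run start; grid points falling outside
every clip (fixation) are zero.

## From segment ratings to design matrices

Raters score each emotion's intensity (0–4) over short segments. Within a
clip, the continuous trace is the polyline through the clip onset (value 0)
and each segment's end-point `(offset_s, intensity)`; after the last
end-point the value is held until the clip ends. Interpolation never
crosses clip boundaries.

The haemodynamic response is a single gamma density, `Gamma(shape=6,
scale=1 s)` truncated at 30 s and renormalised to unit sum. The peak sits
at `(shape-1)*scale = 5 s`, in the canonical range. No undershoot is
modelled: the rating signal is far too slow and smooth for an undershoot
term to be identifiable, and a non-negative kernel preserves the sign and
DC level of the ratings, keeping betas interpretable in rating units. The
parameters are exposed (`hrf_kernel(tr, shape, scale, length_s)`) because
they are a convention, not a measurement. Designs are built by causal
discrete convolution truncated to the run length, after averaging raters
(per-rater designs are retained only for reliability work; for a linear
kernel the order of averaging and convolution is immaterial).

## Reliability screening

Three components per (emotion, task), each computed per run and averaged
over runs with equal weights:

- `pct_raters` — fraction of raters with any non-zero sample;
- `pct_timepoints` — fraction of grid samples where at least one rater is
  non-zero;
- `mean_isc` — mean Pearson correlation over all unordered rater pairs of
  the interpolated (pre-convolution) series. Pairs with a constant series
  are dropped; if all pairs drop, the ISC is 0.

The combined value is the geometric mean, defined as 0 whenever any
component is ≤ 0 (monotone and conservative; a complex or negative root is
never produced). All three components live on [0, 1]-comparable scales —
fractions, with the ISC clamped at zero in the product — because a
geometric mean of mixed-scale quantities would depend on the units chosen.

The chance level shuffles each component vector independently across
emotions (within task), recombines, and pools the null values over
iterations, emotions and both tasks; the threshold is the 95th percentile
(linear interpolation between order statistics). An emotion is retained
when the larger of its two task values exceeds the threshold. An
`exhaustive=True` mode enumerates all `(n!)^3` permutation triples for
small panels; the test suite checks the sampled estimator against it.

**Scope of the screening.** The pooled-percentile threshold detects
emotions that are *jointly* high on all three components relative to
independent recombinations of the component pools. If a fraction `p` of
emotions is consistently rated, a fraction `p^3` of null recombinations
draws all three components from that group, so the procedure can only
separate a planted consistent set when `p^3 < alpha` (about `p < 0.37` at
the 5% level). On data where most emotions are consistent, the threshold
acts as a *definition* of the most reliable subset rather than a detector.
The recovery tests therefore run in the minority-consistent regime, where
sensitivity and specificity are both essentially perfect.

## Signal conditioning

Fixed order: percent signal change → nuisance regression → bandpass.

- Percent signal change: `100*(y - mean)/mean` per ROI; a zero-mean ROI is
  an error naming the ROI.
- Nuisance design: WM, CSF, six motion parameters, their squares, a linear
  trend and an intercept; residuals by least squares. Rank deficiency is an
  error listing the collinear columns.
- Bandpass: linear-phase equiripple (Parks–McClellan/Remez) FIR, passband
  0.005–0.05 Hz (periods 200–20 s, matching emotion event time scales),
  lower transition 0.001–0.005 Hz, upper transition 0.05–0.0613 Hz, at
  sampling rate 1/2.4 Hz. The number of taps is increased until the
  measured single-pass response satisfies, on a ≥4096-point grid: passband
  ripple ≤ 1 dB, upper-stopband attenuation ≥ 40 dB, and ≥ 20 dB at and
  below 0.001 Hz. Full 40 dB rejection at DC is not attainable at this
  sampling rate with a usable order, and demeaning upstream removes DC
  anyway; the requirement at DC is deliberately the weaker 20 dB. The
  order is capped (default 190, roughly a third of a 575-sample run) so
  output is not edge-dominated; the design errors out, reporting the
  achieved response, if the bounds cannot be met under the cap. The default
  design converges at 121 taps with 42.2 dB stopband attenuation and
  0.39 dB passband ripple.
- Application is forward–backward (`filtfilt`), i.e. zero phase: a phase
  lag would misalign regressors and BOLD. Effective attenuation doubles
  relative to the single-pass response on which the bounds are verified.

## Model fitting and cross-validation

All fits are ordinary least squares after column demeaning of predictors
and targets, no intercept; rank-deficient designs fall back to the
minimum-norm solution with a logged flag. Degenerate (zero-variance) series
score correlation 0, flagged, rather than propagating NaN.

"Mean standardized activity" is computed as: demean each participant's ROI
series per run, concatenate the run set, scale to unit std over the
concatenation, then average participants. A single per-ROI scale across
the concatenated run set (rather than per run) is essential for
self-consistency: per-run rescaling makes the concatenation inconsistent
with any single coefficient vector, and the noiseless forward model would
no longer be fit exactly. Test-set activity is scaled with the
*training-set* std (scale is learned on train, applied to test). Reported
encoding betas are multiplied back by the mean per-ROI training std, so
they are in (conditioned) data units and directly comparable to generating
weights; on synthetic data at snr 5 and study-scale dimensions the
between-run fit recovers the generating betas at Pearson r ≈ 0.96.

- Between-run generalisation: all `C(n_runs, n_train)` train/test
  partitions (10 for 5 runs, 3 training). Encoding fits the full reliable
  design to the group-mean standardized activity of the training runs and
  correlates predictions with each participant's held-out-run series, per
  ROI; scores are averaged over splits. Decoding fits the group-mean
  activity to each emotion regressor and correlates predicted with actual
  ratings on held-out runs. The decoding chance level is the maximum, over
  emotions and null iterations, of scores obtained with deranged
  (fixed-point-free) label permutations of the training pairing — a
  uniform permutation has one fixed point on average and would put the
  true model inside its own null.
- Within-run generalisation: participants are split into folds whose sizes
  differ by at most one (seeded shuffle; 50 participants / 10 folds gives
  training sets of 45). Per run split and fold, the model is fitted on the
  held-in participants' mean activity and scored on each held-out
  participant over the same runs.
- Felt-vs-perceived contrast: paired t over participants per ROI on the
  split-averaged test fits; the null randomises each participant's
  felt/perceived order (a sign flip of that participant's difference),
  records the maximum |t| over ROIs per iteration, and thresholds at the
  95th percentile of the maxima.

**Caveat: the sign-flip contrast is anticonservative at this scale.** On
null data (no emotion signal at all), each split's group-mean-trained
predictions align by chance with the *group mean* of the test-run noise.
That alignment is a random offset shared by every participant's test fit
within a split; the offsets differ between splits and survive averaging
over splits, producing positive cross-participant covariance in the
felt-minus-perceived differences (measured: same-split cross-participant
covariance ≈ 0, cross-split covariance > 0, with correlation ρ ≈ 1/P so
that `(P-1)·ρ ≈ 0.5` roughly independently of the number of participants
and timepoints). Sign-flipping treats participants as independent, so the
max-|t| threshold under-covers: the family-wise false-positive rate
measured over 100 null replicates is 0.10–0.27 rather than 0.05, across
8–50 participants, with and without autocorrelated noise and conditioning.
This is a property of the procedure (group-mean training plus
split-averaged fits plus participant sign-flips), not of this
implementation; the corresponding calibration test is left failing by
design, as a documented methodological caveat.

## Per-emotion mapping

Single-emotion Pearson correlations per (participant, ROI, emotion, run),
Fisher-z transformed (variance stabilisation; a raw-r mode exists), tested
with one-sample t-tests per run and for the run average (mean z per
participant across runs before the t). The null builds `n_shift` (default
100) circularly shifted variants per emotion regressor — rotations drawn
uniformly from `[min_shift, n - min_shift]` samples (default 20), which
preserve the value multiset and the circular autocorrelation exactly —
and, per iteration, permutes emotion labels, draws one shifted variant per
emotion, recomputes all t maps, and records the maximum |t| over ROIs,
emotions, runs and the run average. The threshold is the 97.5th percentile
of the maxima (two-tailed 5%), and masks keep the sign of t. The pairing
rule (one variant per emotion per iteration, max over all cells) is one
concrete reading of an ambiguous published recipe and is fixed here for
reproducibility. The full variant pool is precomputed when it fits in
memory and computed on demand otherwise.

Type-I error of this procedure is calibrated (measured 0.05 on 100 null
replicates). Its *power* on synthetic data is intentionally conservative:
the group signal is common to all participants, so a shifted regressor's
chance correlation with that signal is also consistent across participants,
and null t values can rival aligned ones. The sensitivity property that
does hold, and is tested, is ordinal: the emotion driving a ROI carries the
largest positive group t in essentially every ROI it drives.

Activation extent summarises masks as signed ROI counts per emotion and,
given a ROI→macroregion map, signed fractions per macroregion.

## Similarity and clustering

Emotion response patterns are compared strictly across non-overlapping run
sets (training vs test runs of each split) to avoid the circularity of
within-run comparisons; the split-averaged matrix is symmetrised as
`(M + M')/2` (the raw asymmetric average is retained), and its diagonal is
the between-run reliability of each emotion's pattern — not forced to 1.

Two pattern routes exist:

- correlation patterns (default reading): per-emotion group-mean Fisher-z
  maps from the single-regressor correlations;
- beta patterns (`cross_run_beta_similarity`): rows of the full-model OLS
  fit on the run set. Because the joint fit unmixes the temporal
  correlation between emotion regressors, beta patterns isolate each
  emotion's own spatial weights; correlation patterns blend temporally
  co-occurring emotions into each other. Planted pattern blocks are
  recovered exactly (adjusted Rand index 1.0 at snr 5, k = 2–4) through
  the beta route, and only partially through the correlation route — the
  blend, not the clustering, is what differs.

Thresholded maps can instead be compared with the generalized two-sided
Dice index `2(|P_a∩P_b| + |N_a∩N_b|) / (|P_a|+|P_b|+|N_a|+|N_b|)` (0/0
defined as 0).

Clustering is average linkage (UPGMA) on `d = 1 - r` (the simplest
monotone map; scipy's implementation), with optimal leaf ordering
(maximising the sum of adjacent-leaf similarities subject to the tree) and
a cut at 70% of the maximum merge height. Merges at exactly the cut height
are excluded (strict inequality, the MATLAB dendrogram convention), and
single-member clusters are labelled 0, "unclustered". The same code path
serves the rating-space correlation matrix (emotion model time series
concatenated across runs, both tasks as separate conditions) and the
neural similarity matrix.

## The synthetic-data generator

The generator emulates the study design end to end: a rating panel
(default 16 raters × 63 emotions × 2 tasks × 5 runs of back-to-back clips
— 8 per run, 7 in the last — with 4-TR fixation at both ends) and a BOLD
dataset (default 50 participants × 273 ROIs × 575 TRs per run). Ratings
are always emitted at segment resolution and pass through the same
interpolation/convolution path as real data.

Rating model. A designated subset of emotions (default 46, mirroring the
study's reliable count) carries a shared latent profile: in each run the
emotion occurs in `occurrence_rate` (default 0.35) of clips, with
mean-reverting (Ornstein–Uhlenbeck-style) intensities over 3–10 s segment
grids — emotions wax and wane within a scene rather than ramping
monotonically, which also keeps inter-rater correlation honest at zero
agreement. The felt task's latent is coupled to the perceived one at
weight `task_coupling` (default 0.7). Each rater observes
`w*shared + (1-w)*idiosyncratic` with `w = rater_agreement` (default 0.8),
where the idiosyncratic component has its own, independent clip draw, so
`w = 0` yields fully independent raters (occurrence structure included)
and `w = 1` identical ones. Unreliable emotions are reported only by a
Bernoulli(0.3) subset of raters, each sparsely and idiosyncratically —
with 16 raters, union coverage would otherwise saturate and no reliability
contrast would exist.

Forward model. Per participant `p` and ROI `r`:
`y = Σ_task X_task (β_task ⊙ J_p) (1 + g_p) + AR(1) noise + drift +
motion leakage + baseline`, where `g_p ~ N(0, 0.2)` is a scalar gain and
`J_p` is elementwise multiplicative jitter `1 + N(0, participant_beta_std)`
(default 0.2). The jitter exists because a scalar gain is invisible to
Pearson correlations: without it, all participants carry near-identical
correlation values, the across-participant variance collapses, and any
group t-statistic degenerates. Zeros stay zero under both, so null
datasets (`beta ≡ 0`) are pure noise plus confounds. Noise is stationary
AR(1) (default coefficient 0.4 — the minimal model that makes
circular-shift nulls non-trivial) scaled per ROI to the requested
signal-to-noise ratio (std of signal / std of noise; ROIs without signal
get unit noise); `snr = 0` with non-zero betas is rejected as undefined.
Drift is a random per-ROI linear slope; six synthetic motion series
(random walks) leak into the signal with random weights and are returned,
with AR-noise WM/CSF series, as the confound table. Betas are standard
normal with a `beta_sparsity` fraction (default 0.5) forced to zero, drawn
only for the reliable set; an optional block mode assigns reliable
emotions round-robin to `k` blocks whose members share a base ROI pattern
at correlation 0.9, for cluster-recovery experiments.

What the generator does *not* emulate: voxel-level structure and spatial
correlation between ROIs; haemodynamic nonlinearity or per-participant HRF
variation; physiological (cardiac/respiratory) noise; rater drift or
scale-use differences; any systematic difference between the rater panel
and the scanned participants. Passing tests therefore demonstrate the
correctness and calibration of the *procedures* under a plausible
generative model, not the effect sizes or anatomical conclusions one would
obtain from real data.

## Problem sizes in the test suite

Unit and property tests run on toy dimensions (2–10 raters/participants,
4–12 emotions, 8–40 ROIs, 100–400 timepoints). The calibration checks use
100 null replicates at 8–10 participants × 12 ROIs × 4 emotions × 3 runs
of 120 TRs with 200 permutations each; beta recovery runs once at full
study dimensions (50 × 273 × 5 × 575, 46 emotions, snr 5); cluster
recovery uses 8 emotions × 40 ROIs over k ∈ {2, 3, 4} and five seeds. The
whole suite completes in about a minute on one CPU.

## Known limitations

- The felt-vs-perceived sign-flip contrast is structurally anticonservative
  under split-averaged group-mean training (analysis above); treat its
  significance calls on small samples with caution.
- The circular-shift max-|t| procedure is conservative on data whose
  signal is strongly shared across participants; effects are better read
  from the ordinal structure of the t maps than from the FWER mask in that
  regime.
- The reliability threshold defines, rather than detects, a reliable set
  when most emotions are consistently rated.
- The HRF and the equiripple transition-band weights are conventions fixed
  for reproducibility; results depending finely on them should be checked
  against the exposed parameters.
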