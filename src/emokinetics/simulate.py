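"""Synthetic rating panels and ROI BOLD datasets with known ground truth.

The generator emulates the study design: ~16 raters scoring 63 emotions in
short segments over 5 runs of back-to-back movie clips for two tasks
(perceived / felt), and ~50 participants x 273 ROIs x ~575 TRs of BOLD-like
signal.  Reliable emotions share a latent piecewise-linear intensity
profile, mixed per rater with idiosyncratic noise at weight
``rater_agreement``; unreliable emotions get sparser, fully idiosyncratic
profiles.  BOLD is the linear forward model y = X @ beta scaled by a
per-participant gain, plus AR(1) noise at a requested signal-to-noise
ratio, a linear drift, and leakage from six synthetic motion confounds.
Ratings are always emitted at segment resolution and pass through the same
interpolation/convolution path as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import TASKS, RunManifest, ValidationError, contiguous_manifest
from .containers import GroundTruth, RatingPanel, RoiDataset, RATING_COLUMNS
from .design import EmotionDesign, build_designs, hrf_kernel


@dataclass
class SimulationSpec:
    """Dimensions and noise parameters of a synthetic study.

    Defaults are the study's conditions (16 raters, 63 emotions of which 46
    reliable, 5 runs of 575 TRs at TR 2.4 s, 50 participants, 273 ROIs).
    ``rater_agreement`` is the mixing weight of the shared latent rating
    signal; ``occurrence_rate`` the fraction of clips in which a reliable
    emotion occurs; ``snr`` the per-ROI ratio of signal std to noise std;
    ``beta_sparsity`` the fraction of ROI x emotion weights forced to zero.
    """

    n_raters: int = 16
    n_emotions: int = 63
    n_reliable: int = 46
    n_runs: int = 5
    n_timepoints_per_run: int = 575
    n_participants: int = 50
    n_rois: int = 273
    rater_agreement: float = 0.8
    occurrence_rate: float = 0.35
    snr: float = 1.0
    ar_coefficient: float = 0.4
    beta_sparsity: float = 0.5
    rng_seed: int = 0
    tr: float = 2.4
    participant_gain_std: float = 0.2
    participant_beta_std: float = 0.2
    drift_amplitude: float = 0.5
    confound_leak: float = 0.2
    baseline: float = 1000.0
    task_coupling: float = 0.7
    unreliable_reporter_rate: float = 0.3
    n_pattern_blocks: int | None = None
    block_correlation: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.rater_agreement <= 1):
            raise ValidationError("rater_agreement must lie in [0, 1]")
        if not (0 < self.occurrence_rate <= 1):
            raise ValidationError("occurrence_rate must lie in (0, 1]")
        if self.snr < 0:
            raise ValidationError("snr must be nonnegative")
        if not (-1 < self.ar_coefficient < 1):
            raise ValidationError("ar_coefficient must lie in (-1, 1)")
        if not (0 <= self.beta_sparsity <= 1):
            raise ValidationError("beta_sparsity must lie in [0, 1]")
        if self.n_reliable > self.n_emotions:
            raise ValidationError("n_reliable cannot exceed n_emotions")
        for name in ("n_raters", "n_emotions", "n_runs",
                     "n_timepoints_per_run", "n_participants", "n_rois"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def emotions(self) -> list[str]:
        return [f"emotion{i + 1:02d}" for i in range(self.n_emotions)]

    @property
    def rois(self) -> list[str]:
        return [f"roi{i + 1:03d}" for i in range(self.n_rois)]

    @property
    def raters(self) -> list[str]:
        return [f"rater{i + 1:02d}" for i in range(self.n_raters)]

    @property
    def participants(self) -> list[str]:
        return [f"sub{i + 1:02d}" for i in range(self.n_participants)]


def default_manifests(spec: SimulationSpec) -> dict[str, RunManifest]:
    """Back-to-back clips filling each run, 4-TR fixation at both ends.

    Runs 1..4 carry 8 clips and the last run 7, mirroring the study's
    division of 39 scenes over five runs (clip counts shrink with very
    short runs so every clip keeps at least ~20 s).
    """
    manifests = {}
    run_len_s = spec.n_timepoints_per_run * spec.tr
    fix = 4 * spec.tr if run_len_s > 16 * spec.tr else 0.0
    movie_s = run_len_s - 2 * fix
    for i in range(spec.n_runs):
        run_id = f"run{i + 1}"
        n_clips = 7 if (i == spec.n_runs - 1 and spec.n_runs >= 5) else 8
        n_clips = max(1, min(n_clips, int(movie_s // 20) or 1))
        durations = [movie_s / n_clips] * n_clips
        manifests[run_id] = contiguous_manifest(
            run_id, durations, spec.tr, start_s=fix,
            n_timepoints=spec.n_timepoints_per_run,
        )
    return manifests


def _segment_grid(duration: float, rng: np.random.Generator) -> np.ndarray:
    """Cumulative segment end-points with lengths drawn from 3-10 s."""
    ends = []
    t = 0.0
    while t < duration - 1e-9:
        t = min(t + rng.uniform(3.0, 10.0), duration)
        ends.append(t)
    return np.asarray(ends)


def _latent_intensities(n: int, rng: np.random.Generator,
                        scale_max: float = 4.0) -> np.ndarray:
    """Mean-reverting intensity profile on [0, scale_max] over n knots.

    An Ornstein-Uhlenbeck-style walk (emotions wax and wane within a scene
    rather than building monotonically); folded and clipped to the rating
    scale.
    """
    x = rng.normal(0.0, scale_max / 3.0)
    out = np.empty(n)
    for k in range(n):
        x = 0.6 * x + rng.normal(0.0, scale_max / 3.0)
        out[k] = x
    return np.clip(np.abs(out), 0.0, scale_max)


def generate_rating_panel(spec: SimulationSpec,
                          manifests: dict[str, RunManifest] | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[RatingPanel, dict[str, pd.Series]]:
    """Segment-level ratings plus the reliable-emotion mask per task.

    Reliable emotions: one shared latent profile per (emotion, run, clip)
    (present in ``occurrence_rate`` of clips), the felt task's latent
    coupled to the perceived one at weight ``task_coupling``; each rater
    observes ``agreement * latent + (1 - agreement) * idiosyncratic``.
    Unreliable emotions: per-rater sparse idiosyncratic profiles at a third
    of the occurrence rate.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if manifests is None:
        manifests = default_manifests(spec)
    emotions = spec.emotions
    reliable = emotions[: spec.n_reliable]
    rows: list[tuple] = []
    w = spec.rater_agreement

    for emotion in emotions:
        is_reliable = emotion in reliable
        # an unreliable emotion is only ever reported by a small, fixed
        # subset of raters (low rater coverage by construction)
        reporters = {
            task: [r for r in spec.raters
                   if rng.random() < spec.unreliable_reporter_rate]
            for task in TASKS
        }
        for run_id, manifest in manifests.items():
            n_clips = len(manifest.clips)
            if is_reliable:
                # shared latent: the emotion occurs in occurrence_rate of
                # the run's clips, with a piecewise profile per task (felt
                # coupled to perceived)
                k = min(max(1, round(spec.occurrence_rate * n_clips)),
                        n_clips)
                shared_clips = set(rng.choice(n_clips, size=k,
                                              replace=False).tolist())
                shared: dict[int, dict] = {}
                for ci in sorted(shared_clips):
                    clip = manifest.clips[ci]
                    ends = _segment_grid(clip.duration_s, rng)
                    lat_p = _latent_intensities(len(ends), rng)
                    lat_f = np.clip(spec.task_coupling * lat_p
                                    + (1 - spec.task_coupling)
                                    * _latent_intensities(len(ends), rng),
                                    0.0, 4.0)
                    shared[ci] = {"ends": ends,
                                  "perceived": lat_p, "felt": lat_f}
                for task in TASKS:
                    for rater in spec.raters:
                        # idiosyncratic occurrence: the rater's own clip
                        # draw, so agreement 0 means fully independent
                        # series (occurrence structure included)
                        own = {ci for ci in range(n_clips)
                               if rng.random() < spec.occurrence_rate}
                        for ci in sorted(shared_clips | own):
                            clip = manifest.clips[ci]
                            if ci in shared_clips:
                                ends = shared[ci]["ends"]
                                sh = shared[ci][task]
                            else:
                                ends = _segment_grid(clip.duration_s, rng)
                                sh = np.zeros(len(ends))
                            idio = (_latent_intensities(len(ends), rng)
                                    if ci in own else np.zeros(len(ends)))
                            vals = np.clip(w * sh + (1 - w) * idio,
                                           0.0, 4.0)
                            _emit(rows, rater, run_id, clip, task, emotion,
                                  ends, vals)
            else:
                for ci, clip in enumerate(manifest.clips):
                    for task in TASKS:
                        for rater in reporters[task]:
                            if rng.random() >= spec.occurrence_rate / 3.0:
                                continue
                            ends = _segment_grid(clip.duration_s, rng)
                            vals = np.clip(
                                _latent_intensities(len(ends), rng) * 0.5,
                                0.0, 4.0)
                            _emit(rows, rater, run_id, clip, task, emotion,
                                  ends, vals)
    panel = RatingPanel(pd.DataFrame(rows, columns=RATING_COLUMNS))
    mask = {
        task: pd.Series([e in reliable for e in emotions], index=emotions)
        for task in TASKS
    }
    return panel, mask


def _emit(rows, rater, run_id, clip, task, emotion, ends, vals) -> None:
    start = clip.onset_s
    for end, val in zip(ends, vals):
        if val > 0:
            rows.append((rater, run_id, clip.clip_id, task, emotion,
                         start, clip.onset_s + end, float(val)))
        start = clip.onset_s + end


def generate_ground_truth(spec: SimulationSpec,
                          reliable_mask: dict[str, pd.Series],
                          rng: np.random.Generator | None = None,
                          null: bool = False) -> GroundTruth:
    """ROI x emotion weights per task; zero outside the reliable set.

    With ``n_pattern_blocks`` set, reliable emotions are assigned to blocks
    round-robin and block members share a base ROI pattern at correlation
    ``block_correlation`` (for cluster-recovery experiments); block labels
    are stored in ``noise['block_labels']``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 1)
    emotions = spec.emotions
    rois = spec.rois
    beta = {}
    noise: dict = {}
    for task in TASKS:
        B = np.zeros((spec.n_rois, spec.n_emotions))
        if not null:
            rel_idx = np.flatnonzero(reliable_mask[task].to_numpy())
            if spec.n_pattern_blocks:
                k = spec.n_pattern_blocks
                rho = spec.block_correlation
                bases = rng.normal(size=(k, spec.n_rois))
                labels = np.array([i % k for i in range(len(rel_idx))])
                for j, e in enumerate(rel_idx):
                    own = rng.normal(size=spec.n_rois)
                    B[:, e] = (np.sqrt(rho) * bases[labels[j]]
                               + np.sqrt(1 - rho) * own)
                noise.setdefault("block_labels", {})[task] = pd.Series(
                    labels, index=[emotions[e] for e in rel_idx])
            else:
                for e in rel_idx:
                    vals = rng.normal(size=spec.n_rois)
                    keep = rng.random(spec.n_rois) >= spec.beta_sparsity
                    B[:, e] = np.where(keep, vals, 0.0)
        beta[task] = pd.DataFrame(B, index=rois, columns=emotions)
    noise.update(snr=spec.snr, ar_coefficient=spec.ar_coefficient)
    return GroundTruth(beta=beta, reliable_mask=reliable_mask, noise=noise)


def _ar1(shape: tuple, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) noise along axis 0, stationary (burn-in 100)."""
    n = shape[0]
    innov = rng.normal(size=(n + 100,) + shape[1:])
    out = sps.lfilter([1.0], [1.0, -phi], innov, axis=0)[100:]
    return out * np.sqrt(1.0 - phi ** 2)


def generate_bold_dataset(spec: SimulationSpec,
                          designs: dict[tuple[str, str], EmotionDesign],
                          truth: GroundTruth,
                          manifests: dict[str, RunManifest],
                          rng: np.random.Generator | None = None
                          ) -> RoiDataset:
    """Forward model: y = sum_task X_task @ beta_task * (1 + gain_p)
    + AR(1) noise at the requested snr + drift + motion leakage."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed + 2)
    runs = sorted(manifests)
    tasks = sorted({t for _, t in designs})
    any_beta = any(np.abs(truth.beta[t].to_numpy()).sum() > 0 for t in tasks)
    if spec.snr == 0 and any_beta:
        raise ValidationError("snr = 0 with nonzero beta: noise scaling "
                              "undefined")
    gains = rng.normal(0.0, spec.participant_gain_std,
                       size=spec.n_participants)
    signals: dict[tuple[str, str], pd.DataFrame] = {}
    confounds: dict[tuple[str, str], pd.DataFrame] = {}
    conf_cols = ["wm", "csf"] + [f"motion{i}" for i in range(1, 7)]

    # per-participant elementwise beta jitter: individuals express the same
    # effects at individually varying strengths (zeros stay zero, so null
    # datasets stay pure noise); a scalar gain alone would be invisible to
    # correlation-based group statistics
    jitter = {
        task: 1.0 + rng.normal(0.0, spec.participant_beta_std,
                               size=(spec.n_participants,)
                               + truth.beta[task].shape)
        for task in tasks
    }
    for run in runs:
        n_t = manifests[run].n_timepoints
        X_total = np.zeros((n_t, spec.n_rois))
        per_task = {}
        for task in tasks:
            d = designs[(run, task)]
            X = d.values()
            B = truth.beta[task][d.emotions].to_numpy().T  # emotion x roi
            per_task[task] = X
            X_total += X @ B
        sig_std = X_total.std(axis=0)
        if np.isinf(spec.snr):
            noise_std = np.zeros(spec.n_rois)
        else:
            noise_std = np.where(sig_std > 0, sig_std / max(spec.snr, 1e-12),
                                 1.0)
            if spec.snr == 0:
                noise_std = np.ones(spec.n_rois)
        for p, part in enumerate(spec.participants):
            motion = np.cumsum(rng.normal(0.0, 0.05, size=(n_t, 6)), axis=0)
            wmcsf = _ar1((n_t, 2), 0.5, rng)
            conf = pd.DataFrame(np.hstack([wmcsf, motion]), columns=conf_cols)
            y = np.zeros((n_t, spec.n_rois))
            for task in tasks:
                d = designs[(run, task)]
                cols = [truth.beta[task].columns.get_loc(e)
                        for e in d.emotions]
                B_p = (truth.beta[task].to_numpy()[:, cols]
                       * jitter[task][p][:, cols]).T
                y += per_task[task] @ B_p
            y *= 1.0 + gains[p]
            if noise_std.any():
                y = y + _ar1((n_t, spec.n_rois), spec.ar_coefficient,
                             rng) * noise_std
            if spec.drift_amplitude:
                slopes = rng.normal(0.0, spec.drift_amplitude,
                                    size=spec.n_rois)
                y = y + np.linspace(-1.0, 1.0, n_t)[:, None] * slopes
            if spec.confound_leak:
                wts = rng.normal(0.0, spec.confound_leak,
                                 size=(6, spec.n_rois))
                y = y + motion @ wts
            y = y + spec.baseline
            signals[(part, run)] = pd.DataFrame(y, columns=spec.rois)
            confounds[(part, run)] = conf
    return RoiDataset(signals=signals, confounds=confounds,
                      roi_labels=spec.rois, manifests=manifests,
                      ground_truth=truth)


@dataclass
class SimulatedStudy:
    """A complete synthetic study: ratings, designs, truth and BOLD."""

    spec: SimulationSpec
    panel: RatingPanel
    manifests: dict[str, RunManifest]
    designs: dict[tuple[str, str], EmotionDesign]
    truth: GroundTruth
    dataset: RoiDataset


def simulate_study(spec: SimulationSpec, null: bool = False,
                   tasks: tuple[str, ...] = TASKS,
                   emotions: list[str] | None = None) -> SimulatedStudy:
    """Generate ratings, run them through the design path, then BOLD.

    ``null=True`` zeroes every beta (pure noise + confounds), the harness
    for false-positive-rate checks.  ``emotions`` restricts the designs
    (and betas) entering the forward model, e.g. to the reliable set.
    """
    rng = np.random.default_rng(spec.rng_seed)
    manifests = default_manifests(spec)
    panel, mask = generate_rating_panel(spec, manifests, rng)
    kernel = hrf_kernel(spec.tr)
    designs = build_designs(panel, manifests, spec.tr, kernel,
                            tasks=list(tasks), emotions=emotions)
    truth = generate_ground_truth(spec, mask, rng, null=null)
    if emotions is not None:
        truth = GroundTruth(
            beta={t: truth.beta[t][emotions].copy() for t in truth.beta},
            reliable_mask=truth.reliable_mask, noise=truth.noise,
        )
    used = {(r, t): d for (r, t), d in designs.items() if t in tasks}
    dataset = generate_bold_dataset(spec, used, truth, manifests, rng)
    return SimulatedStudy(spec, panel, manifests, designs, truth, dataset)


def generate_null_dataset(spec: SimulationSpec) -> RoiDataset:
    """Dataset generated with beta identically zero."""
    return simulate_study(spec, null=True).dataset
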