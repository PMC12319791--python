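"""From sparse segment ratings to HRF-convolved design matrices.

Raters scored each emotion's intensity over short (3-10 s) segments of each
movie clip.  Within a clip the continuous rating trace is reconstructed by
linear interpolation between successive segment end-points, anchored at zero
at the start of every clip (a new scene resets the rating), and held at the
last end-point value until the clip ends.  Outside clips (fixation) the trace
is zero.  The trace is sampled on the TR grid and convolved with a single
positive gamma haemodynamic response function (no undershoot): the rating
sampling is far too slow and smooth for the undershoot to be identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunManifest, ValidationError
from .containers import RatingPanel


@dataclass
class HrfKernel:
    """Single-gamma haemodynamic impulse response sampled on the TR grid.

    The continuous density is ``Gamma(shape, scale)``; its mode (response
    peak) sits at ``(shape - 1) * scale`` seconds.  Samples are renormalised
    to unit sum so convolution preserves the DC level of the rating scale and
    betas stay interpretable in rating units.
    """

    shape: float
    scale: float
    length_s: float
    tr: float
    samples: np.ndarray
    normalization: str = "sum"

    @property
    def peak_s(self) -> float:
        return (self.shape - 1.0) * self.scale

    def params(self) -> dict:
        return {"shape": self.shape, "scale": self.scale,
                "length_s": self.length_s, "tr": self.tr,
                "normalization": self.normalization}


def hrf_kernel(tr: float, shape: float = 6.0, scale: float = 1.0,
               length_s: float = 30.0) -> HrfKernel:
    """Gamma-density HRF samples at t = 0, TR, 2*TR, ... <= length_s."""
    if shape <= 1:
        raise ValidationError(
            "hrf shape must exceed 1 (shape <= 1 has no interior peak)"
        )
    if scale <= 0 or tr <= 0 or length_s <= 0:
        raise ValidationError("hrf scale, tr and length must be positive")
    t = np.arange(0.0, length_s + 1e-9, tr)
    samples = stats.gamma.pdf(t, a=shape, scale=scale)
    total = samples.sum()
    if total <= 0:
        raise ValidationError("degenerate HRF: all samples zero")
    return HrfKernel(shape, scale, length_s, tr, samples / total)


@dataclass
class RaterSeries:
    """Interpolated rating series: (rater, time, emotion) for one run/task."""

    run_id: str
    task: str
    values: np.ndarray
    raters: list[str]
    emotions: list[str]
    tr: float

    def mean_over_raters(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def frame(self, rater: str) -> pd.DataFrame:
        i = self.raters.index(rater)
        return pd.DataFrame(self.values[i], columns=self.emotions)


def piecewise_linear(t: np.ndarray, knot_t: np.ndarray,
                     knot_v: np.ndarray) -> np.ndarray:
    """Evaluate the polyline through (knot_t, knot_v); edges held constant."""
    return np.interp(t, knot_t, knot_v)


def interpolate_to_grid(panel: RatingPanel, manifest: RunManifest, tr: float,
                        task: str, emotions: list[str] | None = None,
                        raters: list[str] | None = None) -> RaterSeries:
    """Reconstruct each rater's continuous rating trace on the TR grid.

    Knots of the polyline within a clip are the clip onset (value 0) and each
    rated segment's offset with its intensity; the value is held after the
    last knot until the clip ends.  Emotions a rater never rated are all-zero.
    """
    if tr <= 0:
        raise ValidationError("tr must be positive")
    manifest.validate_against_tr(tr)
    rows = panel.select(run=manifest.run_id, task=task)
    if raters is None:
        raters = panel.raters
    if emotions is None:
        emotions = panel.emotions
    grid = manifest.grid_seconds(tr)
    values = np.zeros((len(raters), len(grid), len(emotions)))
    clip_by_id = {c.clip_id: c for c in manifest.clips}
    rater_idx = {r: i for i, r in enumerate(raters)}
    emo_idx = {e: i for i, e in enumerate(emotions)}

    for (rater, emotion, clip_id), grp in rows.groupby(
            ["rater", "emotion", "clip"], sort=False):
        if rater not in rater_idx or emotion not in emo_idx:
            continue
        clip = clip_by_id.get(clip_id)
        if clip is None:
            raise ValidationError(
                f"segment references unknown clip {clip_id!r} in run "
                f"{manifest.run_id}"
            )
        on = grp["onset_s"].to_numpy(dtype=float)
        off = grp["offset_s"].to_numpy(dtype=float)
        if (on < clip.onset_s - 1e-9).any() or (off > clip.offset_s + 1e-9).any():
            raise ValidationError(
                f"segment outside clip {clip_id} bounds for rater {rater}, "
                f"emotion {emotion}"
            )
        order = np.argsort(off)
        knot_t = np.concatenate(([clip.onset_s], off[order]))
        knot_v = np.concatenate(([0.0], grp["intensity"].to_numpy(float)[order]))
        in_clip = (grid >= clip.onset_s - 1e-9) & (grid < clip.offset_s - 1e-9)
        values[rater_idx[rater], in_clip, emo_idx[emotion]] = piecewise_linear(
            grid[in_clip], knot_t, knot_v
        )
    return RaterSeries(manifest.run_id, task, values, list(raters),
                       list(emotions), tr)


@dataclass
class EmotionDesign:
    """TR-gridded, HRF-convolved emotion regressors for one run and task."""

    run_id: str
    task: str
    matrix: pd.DataFrame          # time x emotion
    hrf_params: dict = field(default_factory=dict)
    aggregate: str = "mean"

    @property
    def emotions(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_timepoints(self) -> int:
        return len(self.matrix)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def subset(self, emotions: list[str]) -> "EmotionDesign":
        return EmotionDesign(self.run_id, self.task, self.matrix[emotions],
                             self.hrf_params, self.aggregate)


def convolve_causal(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution truncated to the input length (per column)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.convolve(x, kernel)[: len(x)]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], kernel)[: x.shape[0]]
    return out


def build_design(series: RaterSeries, kernel: HrfKernel,
                 aggregate: str = "mean") -> EmotionDesign:
    """Convolve interpolated ratings with the HRF.

    ``aggregate='mean'`` averages raters before convolution (the group-level
    emotion model fitted downstream); ``'per-rater'`` keeps one convolved
    series per rater for reliability work.  Columns are not demeaned here —
    demeaning belongs to the fitting stage.
    """
    if abs(series.tr - kernel.tr) > 1e-9:
        raise ValidationError(
            f"TR mismatch: series {series.tr} vs kernel {kernel.tr}"
        )
    if aggregate == "mean":
        mat = convolve_causal(series.mean_over_raters(), kernel.samples)
        matrix = pd.DataFrame(mat, columns=series.emotions)
        return EmotionDesign(series.run_id, series.task, matrix,
                             kernel.params(), aggregate)
    if aggregate == "per-rater":
        stacked = np.stack([
            convolve_causal(series.values[i], kernel.samples)
            for i in range(len(series.raters))
        ])
        matrix = pd.DataFrame(
            stacked.mean(axis=0), columns=series.emotions
        )
        design = EmotionDesign(series.run_id, series.task, matrix,
                               kernel.params(), aggregate)
        design.per_rater = stacked  # type: ignore[attr-defined]
        return design
    raise ValidationError(f"unknown aggregate mode {aggregate!r}")


def build_designs(panel: RatingPanel, manifests: dict[str, RunManifest],
                  tr: float, kernel: HrfKernel | None = None,
                  tasks: list[str] | None = None,
                  emotions: list[str] | None = None,
                  ) -> dict[tuple[str, str], EmotionDesign]:
    """Designs for every (run, task): the group-level emotion models."""
    if kernel is None:
        kernel = hrf_kernel(tr)
    if tasks is None:
        tasks = panel.tasks
    out: dict[tuple[str, str], EmotionDesign] = {}
    for run_id, manifest in manifests.items():
        for task in tasks:
            series = interpolate_to_grid(panel, manifest, tr, task,
                                         emotions=emotions)
            out[(run_id, task)] = build_design(series, kernel)
    return out
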