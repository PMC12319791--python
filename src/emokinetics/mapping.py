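"""Per-emotion, per-ROI correlation mapping with circular-shift nulls.

Single-emotion regressors are correlated with every ROI series, per
participant and run, and group significance is assessed with one-sample
t-tests on Fisher-z correlations.  Because both regressors and BOLD are
strongly autocorrelated, the null model circularly shifts each regressor by
at least ``min_shift`` samples (preserving its marginal distribution and
circular autocorrelation exactly) and additionally permutes emotion labels;
the family-wise error rate is controlled by the 97.5th percentile of the
maximum |t| over ROIs, emotions and runs across permutation iterations
(two-tailed p < .05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ValidationError
from .containers import RoiDataset
from .design import EmotionDesign
from .fitting import zscore_time

__all__ = [
    "EmotionRoiMap", "emotion_roi_correlation", "circular_shift",
    "shiftnull_fwer_test", "activation_extent",
]


def emotion_roi_correlation(dataset: RoiDataset,
                            designs: dict[str, EmotionDesign]) -> np.ndarray:
    """Pearson r per (participant, ROI, emotion, run).

    Each emotion enters as a single regressor (not the full model).
    Degenerate (constant) series give r = 0.
    """
    participants = dataset.participants
    runs = dataset.runs
    emotions = designs[runs[0]].emotions
    r = np.zeros((len(participants), len(dataset.roi_labels),
                  len(emotions), len(runs)))
    for k, run in enumerate(runs):
        X = zscore_time(designs[run].values())            # T x E
        data = dataset.run_array(run)                     # P x T x R
        n_t = X.shape[0]
        if data.shape[1] != n_t:
            raise ValidationError(
                f"design and data lengths differ in run {run}"
            )
        for p in range(len(participants)):
            Z = zscore_time(data[p])                      # T x R
            r[p, :, :, k] = Z.T @ X / n_t
    return np.clip(r, -1.0, 1.0)


def circular_shift(series: np.ndarray, min_shift: int,
                   rng: np.random.Generator,
                   shift: int | None = None) -> np.ndarray:
    """Rotate a series by k samples, k uniform on [min_shift, n - min_shift].

    The rotation preserves the multiset of values and the circular
    autocorrelation while destroying alignment with the data.  ``shift``
    overrides the random draw (test hook).
    """
    series = np.asarray(series)
    n = series.shape[0]
    if n <= 2 * min_shift:
        raise ValidationError(
            f"series length {n} must exceed 2 * min_shift ({2 * min_shift})"
        )
    if shift is None:
        shift = int(rng.integers(min_shift, n - min_shift + 1))
    return np.roll(series, shift, axis=0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def one_sample_t(z: np.ndarray, axis: int = 0) -> np.ndarray:
    """One-sample t across participants; zero-variance cells give t = 0."""
    n = z.shape[axis]
    m = z.mean(axis=axis)
    s = z.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


@dataclass
class EmotionRoiMap:
    """Observed t maps, two-tailed FWER threshold and signed mask."""

    rois: list[str]
    emotions: list[str]
    runs: list[str]
    r: np.ndarray                  # participant x ROI x emotion x run
    t_per_run: np.ndarray          # ROI x emotion x run
    t_mean: pd.DataFrame           # ROI x emotion, run-averaged
    threshold: float
    mask: pd.DataFrame             # signed {-1, 0, +1}, run-averaged stat
    mask_per_run: np.ndarray       # ROI x emotion x run, signed
    null_max: np.ndarray

    @property
    def any_run_mask(self) -> pd.DataFrame:
        """Signed union over runs: sign of the largest-|t| significant run."""
        sig = self.mask_per_run
        any_sig = (sig != 0).any(axis=2)
        best = np.take_along_axis(
            sig, np.abs(self.t_per_run).argmax(axis=2)[..., None], axis=2
        )[..., 0]
        return pd.DataFrame(np.where(any_sig, best, 0), index=self.rois,
                            columns=self.emotions)


def shiftnull_fwer_test(dataset: RoiDataset,
                        designs: dict[str, EmotionDesign],
                        n_shift: int = 100, n_perm: int = 1000,
                        min_shift: int = 20, seed: int = 0,
                        alpha: float = 0.05,
                        use_fisher_z: bool = True) -> EmotionRoiMap:
    """Per-emotion t maps with circular-shift + label-permutation FWER.

    Null construction: ``n_shift`` circularly shifted variants of each
    emotion regressor per run; each permutation iteration permutes the
    emotion labels and draws one shifted variant per emotion, recomputes the
    group t for every (ROI, emotion, run) and the run average, and records
    the maximum |t| over all of them.  The threshold is the
    ``1 - alpha/2`` quantile of the ``n_perm`` maxima.
    """
    if n_perm < 40:
        warnings.warn("n_perm < 40: the 97.5th-percentile threshold is "
                      "unstable", stacklevel=2)
    if n_shift < 1:
        raise ValidationError("n_shift must be >= 1")
    participants = dataset.participants
    if len(participants) < 2:
        raise ValidationError("group t-test needs >= 2 participants")
    runs = dataset.runs
    emotions = designs[runs[0]].emotions
    rois = dataset.roi_labels
    rng = np.random.default_rng(seed)

    r_obs = emotion_roi_correlation(dataset, designs)
    stat = fisher_z(r_obs) if use_fisher_z else r_obs
    t_per_run = one_sample_t(stat, axis=0)                  # R x E x K
    t_mean = one_sample_t(stat.mean(axis=3), axis=0)        # R x E

    # Shifted-variant pool: one set of draws per (emotion, variant, run).
    P, R, E, K = r_obs.shape
    z_data = {}
    z_shifted = {}                     # (run, e, v) -> z-scored regressor
    for k, run in enumerate(runs):
        X = designs[run].values()
        n_t = X.shape[0]
        if n_t <= 2 * min_shift:
            raise ValidationError(
                f"run {run} too short ({n_t}) for min_shift {min_shift}"
            )
        z_data[run] = np.stack([zscore_time(a)
                                for a in dataset.run_array(run)])
        Zx = zscore_time(X)
        for v in range(n_shift):
            for e in range(E):
                s = int(rng.integers(min_shift, n_t - min_shift + 1))
                z_shifted[(run, e, v)] = np.roll(Zx[:, e], s)

    def null_cell(run: str, e: int, v: int) -> np.ndarray:
        """Correlations (participant x ROI) of ROI data with one shifted
        variant of one emotion regressor."""
        zx = z_shifted[(run, e, v)]
        rs = np.einsum("ptr,t->pr", z_data[run], zx) / zx.shape[0]
        rs = np.clip(rs, -1.0, 1.0)
        return fisher_z(rs) if use_fisher_z else rs

    # Pool the full tensor only when it fits comfortably in memory;
    # otherwise compute cells on demand inside the permutation loop.
    pooled = None
    if P * R * E * n_shift * K <= 2e8:
        pooled = np.zeros((P, R, E, n_shift, K))
        for k, run in enumerate(runs):
            for v in range(n_shift):
                for e in range(E):
                    pooled[:, :, e, v, k] = null_cell(run, e, v)

    null_max = np.empty(n_perm)
    sel = np.empty((P, R, E, K))
    for it in range(n_perm):
        label = rng.permutation(E)
        variant = rng.integers(0, n_shift, size=E)
        if pooled is not None:
            sel[:] = pooled[:, :, label, variant, :]
        else:
            for e in range(E):
                for k, run in enumerate(runs):
                    sel[:, :, e, k] = null_cell(run, int(label[e]),
                                                int(variant[e]))
        t_null = one_sample_t(sel, axis=0)
        t_null_mean = one_sample_t(sel.mean(axis=3), axis=0)
        null_max[it] = max(np.abs(t_null).max(), np.abs(t_null_mean).max())
    threshold = float(np.quantile(null_max, 1.0 - alpha / 2.0))

    mask_mean = np.sign(t_mean) * (np.abs(t_mean) > threshold)
    mask_per_run = (np.sign(t_per_run)
                    * (np.abs(t_per_run) > threshold)).astype(int)
    return EmotionRoiMap(
        rois=list(rois), emotions=list(emotions), runs=list(runs), r=r_obs,
        t_per_run=t_per_run,
        t_mean=pd.DataFrame(t_mean, index=rois, columns=emotions),
        threshold=threshold,
        mask=pd.DataFrame(mask_mean.astype(int), index=rois,
                          columns=emotions),
        mask_per_run=mask_per_run, null_max=null_max,
    )


def activation_extent(mask: pd.DataFrame,
                      roi_groups: pd.Series | dict | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Spatial extent of significant effects.

    Returns per-emotion counts of positively / negatively significant ROIs
    and, if a ROI -> macroregion mapping is given, the signed fraction of
    each macroregion's ROIs that is significant per emotion.
    """
    vals = mask.to_numpy()
    if not np.isin(vals, (-1, 0, 1)).all():
        raise ValidationError("mask must be ternary {-1, 0, +1}")
    by_emotion = pd.DataFrame({
        "n_positive": (vals > 0).sum(axis=0),
        "n_negative": (vals < 0).sum(axis=0),
        "n_total": (vals != 0).sum(axis=0),
    }, index=mask.columns)
    if roi_groups is None:
        return by_emotion, None
    groups = pd.Series(roi_groups)
    missing = [r for r in mask.index if r not in groups.index]
    if missing:
        raise ValidationError(f"ROIs without macroregion group: {missing}")
    rows = []
    for group, members in groups.groupby(groups):
        sub = mask.loc[members.index]
        for emo in mask.columns:
            col = sub[emo]
            rows.append((group, emo,
                         float((col > 0).mean()), float((col < 0).mean())))
    by_region = pd.DataFrame(
        rows, columns=["macroregion", "emotion", "frac_positive",
                       "frac_negative"]
    ).set_index(["macroregion", "emotion"])
    return by_emotion, by_region
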