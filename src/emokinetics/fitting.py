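"""Least-squares encoding/decoding with run-wise cross-validation,
felt-vs-perceived contrast and max-statistic permutation inference.

The encoding model predicts ROI activity from the HRF-convolved emotion
regressors; the decoding model predicts the emotion regressors from the ROI
activity.  Both use ordinary least squares after column demeaning (no
intercept) — regularised alternatives were found not to generalise better
for this problem, so the simple linear fit is the model.  Generalisation is
evaluated two ways: between runs (fit on the across-participant mean of
z-scored activity on 3 of 5 runs, test on individual participants' series in
the held-out runs, over all 10 train/test combinations) and within runs
(10-fold cross-validation across participants).  The felt-vs-perceived
contrast is a paired t-test over participants per ROI, with family-wise
error controlled by the permutation distribution of the maximum |t| under
random swapping of each participant's felt/perceived values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .config import ValidationError
from .containers import RoiDataset
from .design import EmotionDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSplit:
    """One train/test partition of the runs."""

    train: tuple[str, ...]
    test: tuple[str, ...]


def enumerate_run_splits(run_ids: list[str] | int,
                         n_train: int) -> list[RunSplit]:
    """All C(n_runs, n_train) partitions, lexicographic in the train set."""
    if isinstance(run_ids, int):
        run_ids = [f"run{i + 1}" for i in range(run_ids)]
    run_ids = list(run_ids)
    if not (0 < n_train < len(run_ids)):
        raise ValidationError(
            f"n_train ({n_train}) must be in (0, n_runs={len(run_ids)})"
        )
    splits = []
    for train in combinations(run_ids, n_train):
        test = tuple(r for r in run_ids if r not in train)
        splits.append(RunSplit(train, test))
    return splits


class LinearEncodingModel(BaseEstimator, RegressorMixin):
    """Multi-target OLS after column demeaning of predictors and targets.

    ``coef_`` is the (n_predictors x n_targets) weight matrix; rank-deficient
    designs fall back to the minimum-norm solution (flagged in ``rank_``).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < X.shape[1]:
            raise ValidationError(
                f"need at least as many timepoints ({X.shape[0]}) as "
                f"predictors ({X.shape[1]})"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean(axis=0)
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        coef, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        self.coef_ = coef
        self.rank_ = rank
        if rank < X.shape[1]:
            logger.warning("rank-deficient design (rank %d < %d); "
                           "minimum-norm solution used", rank, X.shape[1])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def score(self, X, y):
        """Mean Pearson correlation between predictions and targets."""
        pred = self.predict(X)
        return float(np.nanmean(columnwise_correlation(
            pred, np.asarray(y, dtype=float))))


def fit_linear_map(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS beta (p x q) after demeaning both X and Y; no intercept."""
    return LinearEncodingModel().fit(X, Y).coef_


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation without fixed points.

    A shuffled-label null pairing must be a *wrong* pairing everywhere: a
    fixed point would put the true model into its own null distribution
    (with few conditions, nearly every draw would).  For n = 1 the identity
    is returned (no derangement exists).
    """
    if n < 2:
        return np.zeros(n, dtype=int)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def columnwise_correlation(A: np.ndarray, B: np.ndarray,
                           degenerate: float = 0.0) -> np.ndarray:
    """Pearson correlation of matching columns; degenerate columns scored
    ``degenerate`` (default 0) with a logged flag."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac ** 2).sum(axis=0))
    sb = np.sqrt((Bc ** 2).sum(axis=0))
    denom = sa * sb
    bad = denom == 0
    if bad.any():
        logger.debug("%d degenerate series scored as r=%g", bad.sum(),
                     degenerate)
    denom = np.where(bad, 1.0, denom)
    r = (Ac * Bc).sum(axis=0) / denom
    r[bad] = degenerate
    return r


def zscore_time(arr: np.ndarray) -> np.ndarray:
    """z-score each column over time; constant columns map to zero."""
    m = arr.mean(axis=0)
    s = arr.std(axis=0)
    s = np.where(s == 0, 1.0, s)
    return (arr - m) / s


@dataclass
class FitResult:
    """Cross-validated fit of one task's emotion model."""

    direction: str                       # encode | decode
    scheme: str                          # between-runs | within-run
    task: str
    beta: pd.DataFrame                   # mean over splits
    test_fit: pd.DataFrame               # encode: participant x ROI
    per_split: np.ndarray                # raw per-split scores
    splits: list[RunSplit]
    null_max: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold: float = np.nan
    significant: pd.Series | None = None

    @property
    def mean_fit(self) -> pd.Series:
        return self.test_fit.mean(axis=0)


def _stack_runs(dataset: RoiDataset, runs: tuple[str, ...],
                std: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Standardized (participant, time, ROI) series over a run set.

    Each participant's series is demeaned per run, concatenated along time,
    and scaled to unit std over the concatenation.  A single per-ROI scale
    across the run set keeps the forward model self-consistent (a per-run
    rescale would make the concatenated series inconsistent with any single
    beta).  Passing ``std`` applies a previously learned scale (e.g. the
    training-set scale to test data).  Returns the z-scored stack and the
    (participant, ROI) stds used.
    """
    parts = []
    for run in runs:
        arr = dataset.run_array(run)
        parts.append(arr - arr.mean(axis=1, keepdims=True))
    cat = np.concatenate(parts, axis=1)
    if std is None:
        std = cat.std(axis=1)
    std_safe = np.where(std == 0, 1.0, std)
    return cat / std_safe[:, None, :], std


def _design_matrix(designs: dict[str, EmotionDesign],
                   runs: tuple[str, ...]) -> np.ndarray:
    """Concatenate per-run demeaned design matrices along time."""
    mats = []
    for run in runs:
        m = designs[run].values()
        mats.append(m - m.mean(axis=0))
    return np.concatenate(mats, axis=0)


def between_run_cv(dataset: RoiDataset, designs: dict[str, EmotionDesign],
                   direction: str = "encode", n_train: int | None = None,
                   n_null: int = 0, seed: int = 0,
                   task: str | None = None) -> FitResult:
    """Between-runs generalisation of the emotion model.

    encode: fit the full design to the across-participant mean of z-scored
    activity on the training runs; correlate the predicted test-run series
    with every individual participant's series, per ROI; average over all
    train/test combinations.

    decode: fit the across-participant mean activity to each emotion
    regressor on the training runs and correlate predicted with actual
    ratings on the test runs, per emotion.  ``n_null`` label-shuffle
    iterations give the max-over-emotions null used as the chance line.
    """
    runs = dataset.runs
    if len(runs) < 2:
        raise ValidationError("between-run CV needs at least 2 runs")
    if n_train is None:
        n_train = max(1, len(runs) - 2)
    if task is None:
        task = designs[runs[0]].task
    splits = enumerate_run_splits(runs, n_train)
    participants = dataset.participants
    emotions = designs[runs[0]].emotions
    rois = dataset.roi_labels
    rng = np.random.default_rng(seed)

    betas = []
    if direction == "encode":
        per_split = np.zeros((len(splits), len(participants), len(rois)))
        for s, split in enumerate(splits):
            z_train, std_train = _stack_runs(dataset, split.train)
            train_Y = z_train.mean(axis=0)
            train_Y = train_Y - train_Y.mean(axis=0)
            train_X = _design_matrix(designs, split.train)
            model = LinearEncodingModel().fit(train_X, train_Y)
            # report betas in (conditioned) data units: undo the per-ROI
            # standardization scale of the training activity
            betas.append(model.coef_ * std_train.mean(axis=0))
            test_X = _design_matrix(designs, split.test)
            pred = model.predict(test_X)
            test_data, _ = _stack_runs(dataset, split.test)
            for p in range(len(participants)):
                per_split[s, p] = columnwise_correlation(pred, test_data[p])
        test_fit = pd.DataFrame(per_split.mean(axis=0), index=participants,
                                columns=rois)
        beta = pd.DataFrame(np.mean(betas, axis=0), index=emotions,
                            columns=rois)
        return FitResult("encode", "between-runs", task, beta, test_fit,
                         per_split, splits)

    if direction == "decode":
        per_split = np.zeros((len(splits), len(emotions)))
        cross = []                       # per split: pred-emotion x actual
        for s, split in enumerate(splits):
            z_train, std_train = _stack_runs(dataset, split.train)
            train_X = z_train.mean(axis=0)
            train_X = train_X - train_X.mean(axis=0)
            train_Y = _design_matrix(designs, split.train)
            model = LinearEncodingModel().fit(train_X, train_Y)
            betas.append(model.coef_)
            # test activity scaled with the training-set per-ROI scale
            test_X = _stack_runs(dataset, split.test, std=std_train)[0]
            test_X = test_X.mean(axis=0)
            test_X = test_X - test_X.mean(axis=0)
            pred = model.predict(test_X)
            actual = _design_matrix(designs, split.test)
            C = np.zeros((len(emotions), len(emotions)))
            for i in range(len(emotions)):
                C[i] = columnwise_correlation(
                    np.repeat(pred[:, i:i + 1], len(emotions), axis=1), actual
                )
            cross.append(C)
            per_split[s] = np.diag(C)
        null_max = np.empty(n_null)
        for it in range(n_null):
            scores = np.zeros(len(emotions))
            for C in cross:
                perm = _derangement(len(emotions), rng)
                scores += C[perm, np.arange(len(emotions))]
            null_max[it] = (scores / len(cross)).max()
        mean_scores = per_split.mean(axis=0)
        threshold = float(null_max.max()) if n_null else np.nan
        significant = (pd.Series(mean_scores > threshold, index=emotions)
                       if n_null else None)
        test_fit = pd.DataFrame(per_split, columns=emotions)
        beta = pd.DataFrame(np.mean(betas, axis=0), index=rois,
                            columns=emotions)
        return FitResult("decode", "between-runs", task, beta, test_fit,
                         per_split, splits, null_max, threshold, significant)

    raise ValidationError(f"unknown direction {direction!r}")


def participant_folds(participants: list[str], n_folds: int,
                      rng: np.random.Generator) -> list[list[str]]:
    """Seeded shuffle into folds whose sizes differ by at most one."""
    if n_folds > len(participants):
        raise ValidationError("more folds than participants")
    order = [participants[i] for i in rng.permutation(len(participants))]
    folds = [order[i::n_folds] for i in range(n_folds)]
    return folds


def within_run_cv(dataset: RoiDataset, designs: dict[str, EmotionDesign],
                  n_folds: int = 10, n_train: int | None = None,
                  seed: int = 0, task: str | None = None) -> FitResult:
    """Within-run generalisation across participants.

    Per run split and fold: fit the design to the mean z-scored activity of
    held-in participants on the training runs, predict those same runs, and
    score the prediction against each held-out participant's series.
    """
    runs = dataset.runs
    participants = dataset.participants
    if n_train is None:
        n_train = max(1, len(runs) - 2)
    if task is None:
        task = designs[runs[0]].task
    splits = enumerate_run_splits(runs, n_train)
    rng = np.random.default_rng(seed)
    folds = participant_folds(participants, n_folds, rng)
    rois = dataset.roi_labels
    p_index = {p: i for i, p in enumerate(participants)}

    per_split = np.zeros((len(splits), len(participants), len(rois)))
    betas = []
    for s, split in enumerate(splits):
        data, _ = _stack_runs(dataset, split.train)    # P x T x R
        X = _design_matrix(designs, split.train)
        for fold in folds:
            held_out = [p_index[p] for p in fold]
            held_in = [i for i in range(len(participants))
                       if i not in held_out]
            train_Y = data[held_in].mean(axis=0)
            train_Y = train_Y - train_Y.mean(axis=0)
            model = LinearEncodingModel().fit(X, train_Y)
            betas.append(model.coef_)
            pred = model.predict(X)
            for p in held_out:
                per_split[s, p] = columnwise_correlation(pred, data[p])
    test_fit = pd.DataFrame(per_split.mean(axis=0), index=participants,
                            columns=rois)
    beta = pd.DataFrame(np.mean(betas, axis=0),
                        index=designs[runs[0]].emotions, columns=rois)
    return FitResult("encode", "within-run", task, beta, test_fit, per_split,
                     splits)


@dataclass
class ContrastResult:
    """Felt-vs-perceived paired contrast with max-|t| FWER threshold."""

    t: pd.Series                    # per ROI
    threshold: float
    mask: pd.Series                 # signed {-1, 0, +1}
    null_max: np.ndarray


def paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic per column of a (participant x ROI) difference
    matrix; columns with zero variance give t = 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    s = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def contrast_tasks(felt: FitResult, perceived: FitResult,
                   n_perm: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> ContrastResult:
    """Paired t per ROI on participant-level fits; FWER by sign-flip maxima.

    The null randomises the felt/perceived order per participant, which for
    a paired t is a sign flip of that participant's difference.
    """
    if not felt.test_fit.index.equals(perceived.test_fit.index) or \
            not felt.test_fit.columns.equals(perceived.test_fit.columns):
        raise ValidationError("contrast inputs must share participants and "
                              "ROIs")
    diffs = felt.test_fit.to_numpy() - perceived.test_fit.to_numpy()
    n = diffs.shape[0]
    if n < 2:
        raise ValidationError("contrast needs at least 2 participants")
    t_obs = paired_t(diffs)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for it in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        null_max[it] = np.abs(paired_t(diffs * signs[:, None])).max()
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    mask = np.sign(t_obs) * (np.abs(t_obs) > threshold)
    rois = felt.test_fit.columns
    return ContrastResult(pd.Series(t_obs, index=rois), threshold,
                          pd.Series(mask.astype(int), index=rois), null_max)
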