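"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import TASKS, RunManifest, ValidationError

RATING_COLUMNS = ["rater", "run", "clip", "task", "emotion",
                  "onset_s", "offset_s", "intensity"]


@dataclass
class RatingPanel:
    """Sparse segment-level intensity ratings.

    One row per rated segment: a rater judged one emotion's intensity over
    ``[onset_s, offset_s)`` seconds (run time) within a clip, on a 0..scale_max
    scale, separately for the ``perceived`` and ``felt`` tasks.  A (rater,
    emotion, run, task) combination with no rows means the rater never
    reported that emotion there, i.e. an all-zero rating series.
    """

    segments: pd.DataFrame
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        missing = [c for c in RATING_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValidationError(f"rating table missing columns: {missing}")
        seg = self.segments
        bad_task = set(seg["task"].unique()) - set(TASKS)
        if bad_task:
            raise ValidationError(f"unknown task labels: {sorted(bad_task)}")
        inten = seg["intensity"].to_numpy(dtype=float)
        if len(inten) and (inten.min() < 0 or inten.max() > self.scale_max):
            bad = seg.index[(inten < 0) | (inten > self.scale_max)][0]
            raise ValidationError(
                f"intensity out of [0, {self.scale_max}] at row {bad}"
            )
        if len(seg) and (seg["offset_s"].to_numpy()
                         <= seg["onset_s"].to_numpy()).any():
            raise ValidationError("segment offset must exceed onset")

    @property
    def raters(self) -> list[str]:
        return sorted(self.segments["rater"].unique())

    @property
    def emotions(self) -> list[str]:
        return sorted(self.segments["emotion"].unique())

    @property
    def runs(self) -> list[str]:
        return sorted(self.segments["run"].unique())

    @property
    def tasks(self) -> list[str]:
        return [t for t in TASKS if t in set(self.segments["task"])]

    def select(self, **keys) -> pd.DataFrame:
        """Rows matching the given column=value filters."""
        seg = self.segments
        for col, val in keys.items():
            seg = seg[seg[col] == val]
        return seg

    def equals(self, other: "RatingPanel") -> bool:
        a = self.segments.sort_values(RATING_COLUMNS).reset_index(drop=True)
        b = other.segments.sort_values(RATING_COLUMNS).reset_index(drop=True)
        return a[RATING_COLUMNS].equals(b[RATING_COLUMNS])


@dataclass
class RoiDataset:
    """Per-participant, per-run ROI time series with confounds.

    ``signals[(participant, run)]`` is a (time x ROI) DataFrame;
    ``confounds[(participant, run)]`` holds the six motion parameters plus
    white-matter and CSF signals for the same timepoints.  ``ground_truth``
    carries the generating betas when the dataset is synthetic.
    """

    signals: dict[tuple[str, str], pd.DataFrame]
    confounds: dict[tuple[str, str], pd.DataFrame]
    roi_labels: list[str]
    manifests: dict[str, RunManifest] = field(default_factory=dict)
    ground_truth: "GroundTruth | None" = None
    conditioned: bool = False

    def __post_init__(self) -> None:
        for key, sig in self.signals.items():
            conf = self.confounds.get(key)
            if conf is None:
                raise ValidationError(f"no confounds for {key}")
            if len(sig) != len(conf):
                raise ValidationError(
                    f"signals ({len(sig)} rows) and confounds ({len(conf)} "
                    f"rows) misaligned for {key}"
                )
            if list(sig.columns) != list(self.roi_labels):
                raise ValidationError(f"ROI labels mismatch for {key}")

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.signals})

    @property
    def runs(self) -> list[str]:
        return sorted({r for _, r in self.signals})

    def run_array(self, run: str) -> np.ndarray:
        """Stack one run as (participant, time, ROI), participants sorted."""
        return np.stack([
            self.signals[(p, run)].to_numpy(dtype=float)
            for p in self.participants
        ])

    def map_signals(self, fn, conditioned: bool | None = None) -> "RoiDataset":
        """Apply ``fn(df, confounds_df) -> df`` to every (participant, run)."""
        new = {k: fn(v, self.confounds[k]) for k, v in self.signals.items()}
        return RoiDataset(
            signals=new,
            confounds=self.confounds,
            roi_labels=self.roi_labels,
            manifests=self.manifests,
            ground_truth=self.ground_truth,
            conditioned=self.conditioned if conditioned is None else conditioned,
        )


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset.

    ``beta[task]`` is the (ROI x emotion) weight matrix used in the forward
    model; ``reliable_mask[task]`` flags the emotions generated with a shared
    across-rater profile.
    """

    beta: dict[str, pd.DataFrame]
    reliable_mask: dict[str, pd.Series]
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for task, b in self.beta.items():
            if not np.isfinite(b.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite beta for task {task}")
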