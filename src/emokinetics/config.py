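"""Pipeline configuration and run/clip timing metadata.

The time convention used throughout the package: BOLD sample ``i`` of a run
covers the half-open interval ``[i*TR, (i+1)*TR)`` seconds, and interpolated
rating series are evaluated at the left edge ``t = i*TR`` of each interval.
Clip onsets/offsets are in seconds from run start and are half-open
``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

TASKS = ("perceived", "felt")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class PipelineConfig:
    """Parameters shared across pipeline stages.

    Defaults mirror the study design: TR of 2.4 s, five runs with three used
    for training in the between-run cross-validation, a 0.005-0.05 Hz
    passband matched to the time scale of the emotion events, ratings on a
    0-4 intensity scale, and a 70 %-of-maximum-linkage dendrogram cutoff.
    """

    tr_seconds: float = 2.4
    n_runs: int = 5
    n_train_runs: int = 3
    passband_hz: tuple[float, float] = (0.005, 0.05)
    rating_scale_max: float = 4.0
    n_permutations: int = 1000
    n_shift_null: int = 100
    min_shift_samples: int = 20
    alpha: float = 0.05
    rng_seed: int = 0
    linkage_cutoff_fraction: float = 0.70

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        lo, hi = self.passband_hz
        if not (0 < lo < hi < nyquist):
            raise ValidationError(
                f"passband {self.passband_hz} must satisfy 0 < lower < upper "
                f"< Nyquist ({nyquist:.4g} Hz)"
            )
        if not (0 < self.n_train_runs < self.n_runs):
            raise ValidationError(
                f"n_train_runs ({self.n_train_runs}) must be in (0, n_runs="
                f"{self.n_runs})"
            )
        for name in ("n_runs", "n_permutations", "n_shift_null",
                     "min_shift_samples"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0 < self.linkage_cutoff_fraction <= 1):
            raise ValidationError("linkage_cutoff_fraction must lie in (0, 1]")
        if self.rating_scale_max <= 0:
            raise ValidationError("rating_scale_max must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passband_hz"] = list(self.passband_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "passband_hz" in d:
            d["passband_hz"] = tuple(d["passband_hz"])
        return cls(**d)


@dataclass
class Clip:
    """A movie scene within a run; ``[onset_s, offset_s)`` in run time."""

    clip_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValidationError(
                f"clip {self.clip_id}: offset must exceed onset"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class RunManifest:
    """Timing of one functional run: ordered non-overlapping clips."""

    run_id: str
    clips: list[Clip]
    n_timepoints: int
    participants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_timepoints <= 0:
            raise ValidationError("n_timepoints must be positive")
        prev_end = 0.0
        for clip in self.clips:
            if clip.onset_s < prev_end - 1e-9:
                raise ValidationError(
                    f"run {self.run_id}: clips overlap or are out of order "
                    f"at {clip.clip_id}"
                )
            prev_end = clip.offset_s

    def validate_against_tr(self, tr: float) -> None:
        run_end = self.n_timepoints * tr
        for clip in self.clips:
            if clip.offset_s > run_end + 1e-9:
                raise ValidationError(
                    f"run {self.run_id}: clip {clip.clip_id} extends past the "
                    f"run end ({run_end:.1f} s)"
                )

    def grid_seconds(self, tr: float):
        import numpy as np

        return np.arange(self.n_timepoints) * tr


def contiguous_manifest(run_id: str, clip_durations_s: Sequence[float],
                        tr: float, start_s: float = 0.0,
                        n_timepoints: int | None = None) -> RunManifest:
    """Build a manifest of back-to-back clips (movies played without gaps)."""
    import math

    clips = []
    t = start_s
    for i, dur in enumerate(clip_durations_s):
        clips.append(Clip(f"{run_id}_clip{i + 1:02d}", t, t + dur))
        t += dur
    if n_timepoints is None:
        n_timepoints = math.ceil(t / tr)
    return RunManifest(run_id, clips, n_timepoints)
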