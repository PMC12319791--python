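"""ROI time-series conditioning: percent signal change, nuisance regression,
and equiripple FIR bandpass filtering.

The fixed order of operations is percent signal change -> nuisance
regression -> bandpass.  The bandpass matches the frequency content of the
slowly evolving emotion regressors (events of roughly 20-100 s): passband
0.005-0.05 Hz at a 2.4 s sampling interval, designed as a linear-phase
equiripple (Parks-McClellan) FIR with < 1 dB passband ripple and >= 40 dB
attenuation in the upper stopband starting at 0.0613 Hz.  Full 40 dB
rejection at DC is not attainable at this sampling rate with a usable filter
order, so the design requires only >= 20 dB at and below 0.001 Hz; the
demeaning steps upstream remove the DC component anyway.  The filter is
applied forward-backward (zero phase) so regressors and BOLD stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .config import ValidationError
from .containers import RoiDataset

MOTION_COLUMNS = [f"motion{i}" for i in range(1, 7)]
CONFOUND_COLUMNS = ["wm", "csf"] + MOTION_COLUMNS


def percent_signal_change(series: np.ndarray | pd.DataFrame,
                          roi_labels=None):
    """100 * (y - mean) / mean per column."""
    arr = np.asarray(series, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    mean = arr.mean(axis=0)
    zero = np.flatnonzero(mean == 0)
    if zero.size:
        if roi_labels is None and isinstance(series, pd.DataFrame):
            roi_labels = list(series.columns)
        names = ([roi_labels[i] for i in zero] if roi_labels is not None
                 else list(zero))
        raise ValidationError(f"zero temporal mean in ROI(s) {names}; percent "
                              "signal change undefined")
    out = 100.0 * (arr - mean) / mean
    if squeeze:
        out = out[:, 0]
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(out, index=series.index, columns=series.columns)
    return out


def nuisance_design(confounds: pd.DataFrame) -> np.ndarray:
    """Confound design: WM, CSF, 6 motion, squared motion, linear trend,
    intercept."""
    missing = [c for c in CONFOUND_COLUMNS if c not in confounds.columns]
    if missing:
        raise ValidationError(f"confound table missing columns: {missing}")
    n = len(confounds)
    motion = confounds[MOTION_COLUMNS].to_numpy(dtype=float)
    cols = [
        confounds[["wm", "csf"]].to_numpy(dtype=float),
        motion,
        motion ** 2,
        np.linspace(-1.0, 1.0, n)[:, None],
        np.ones((n, 1)),
    ]
    return np.hstack(cols)


def nuisance_regress(series: np.ndarray | pd.DataFrame,
                     confounds: pd.DataFrame):
    """Residualise the series against the augmented confound design."""
    X = nuisance_design(confounds)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate collinear columns by greedy QR-style elimination
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = kept + [j]
            if np.linalg.matrix_rank(X[:, cand]) == len(cand):
                kept.append(j)
            else:
                bad.append(j)
        raise ValidationError(
            f"confound design is rank deficient; collinear columns at "
            f"indices {bad}"
        )
    arr = np.asarray(series, dtype=float)
    squeeze = arr.ndim == 1
    Y = arr[:, None] if squeeze else arr
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if squeeze:
        resid = resid[:, 0]
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(resid, index=series.index, columns=series.columns)
    return resid


@dataclass
class FilterSpec:
    """A designed FIR bandpass with its verified magnitude response."""

    sampling_rate_hz: float
    passband_hz: tuple[float, float]
    lower_stop_edge_hz: float
    upper_stop_edge_hz: float
    passband_ripple_db: float           # bound the design must meet
    stopband_atten_db: float            # bound for the upper stopband
    dc_atten_db: float                  # bound at/below the lower stop edge
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    order: int = 0
    measured: dict = field(default_factory=dict)

    @property
    def nyquist_hz(self) -> float:
        return self.sampling_rate_hz / 2.0


def measure_response(taps: np.ndarray, spec: FilterSpec,
                     n_grid: int = 8192) -> dict:
    """Single-pass magnitude response summary on a dense frequency grid."""
    f, h = signal.freqz(taps, worN=n_grid, fs=spec.sampling_rate_hz)
    mag = np.abs(h)
    lo, hi = spec.passband_hz
    pb = (f >= lo) & (f <= hi)
    upper = f >= spec.upper_stop_edge_hz
    lower = f <= spec.lower_stop_edge_hz
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    return {
        "passband_ripple_db": float(db[pb].max() - db[pb].min()),
        "stopband_atten_db": float(-db[upper].max()),
        "dc_atten_db": float(-db[lower].max()),
        "grid_hz": f,
        "magnitude": mag,
    }


def design_bandpass(sampling_rate_hz: float = 1.0 / 2.4,
                    passband_hz: tuple[float, float] = (0.005, 0.05),
                    lower_stop_edge_hz: float = 0.001,
                    upper_stop_edge_hz: float = 0.0613,
                    passband_ripple_db: float = 1.0,
                    stopband_atten_db: float = 40.0,
                    dc_atten_db: float = 20.0,
                    max_order: int | None = 190,
                    n_grid: int = 8192) -> FilterSpec:
    """Design the equiripple bandpass and verify it against its bounds.

    The number of taps is increased until the measured single-pass response
    satisfies all three bounds on a dense grid, or until ``max_order`` (kept
    at roughly one third of a run length so the output is not dominated by
    edge effects).
    """
    nyq = sampling_rate_hz / 2.0
    lo, hi = passband_hz
    if not (0 <= lower_stop_edge_hz < lo < hi < upper_stop_edge_hz < nyq):
        raise ValidationError("filter band edges must be ordered and below "
                              "Nyquist")
    spec = FilterSpec(sampling_rate_hz, (lo, hi), lower_stop_edge_hz,
                      upper_stop_edge_hz, passband_ripple_db,
                      stopband_atten_db, dc_atten_db)
    bands = [0.0, lower_stop_edge_hz, lo, hi, upper_stop_edge_hz, nyq]
    # weights inversely proportional to the allowed linear-scale ripple
    delta_pass = (10 ** (passband_ripple_db / 40.0) - 1) / \
                 (10 ** (passband_ripple_db / 40.0) + 1)
    weights = [1.0 / 10 ** (-dc_atten_db / 20.0),
               1.0 / delta_pass,
               1.0 / 10 ** (-stopband_atten_db / 20.0)]
    if max_order is None:
        max_order = 190
    achieved = None
    candidates = list(range(91, max_order + 2, 10)) or [max_order + 1]
    for numtaps in candidates:
        taps = signal.remez(numtaps, bands, [0.0, 1.0, 0.0], weight=weights,
                            fs=sampling_rate_hz, maxiter=100)
        meas = measure_response(taps, spec, n_grid)
        achieved = meas
        if (meas["passband_ripple_db"] <= passband_ripple_db
                and meas["stopband_atten_db"] >= stopband_atten_db
                and meas["dc_atten_db"] >= dc_atten_db):
            spec.coefficients = taps
            spec.order = numtaps - 1
            spec.measured = {k: v for k, v in meas.items()
                             if not isinstance(v, np.ndarray)}
            return spec
    raise ValidationError(
        "bandpass specs unattainable below order "
        f"{max_order}: achieved stopband {achieved['stopband_atten_db']:.1f} "
        f"dB, ripple {achieved['passband_ripple_db']:.2f} dB, DC "
        f"{achieved['dc_atten_db']:.1f} dB"
    )


def apply_bandpass(series: np.ndarray | pd.DataFrame, spec: FilterSpec):
    """Zero-phase (forward-backward) application of the designed filter.

    Effective attenuation doubles relative to the single-pass response the
    design was verified on.  The series must be longer than the filter order.
    """
    if spec.coefficients.size == 0:
        raise ValidationError("FilterSpec has no coefficients; run "
                              "design_bandpass first")
    arr = np.asarray(series, dtype=float)
    n = arr.shape[0]
    if n <= spec.order:
        raise ValidationError(
            f"series length {n} must exceed filter order {spec.order}"
        )
    padlen = min(n - 1, 3 * len(spec.coefficients))
    out = signal.filtfilt(spec.coefficients, [1.0], arr, axis=0,
                          padlen=padlen)
    if isinstance(series, pd.DataFrame):
        return pd.DataFrame(out, index=series.index, columns=series.columns)
    return out


class PercentSignalChange(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`percent_signal_change` (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return percent_signal_change(X)


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Residualises input against a confound table supplied at construction."""

    def __init__(self, confounds: pd.DataFrame | None = None):
        self.confounds = confounds

    def fit(self, X, y=None):
        if self.confounds is None:
            raise ValidationError("NuisanceRegressor needs a confound table")
        self.design_ = nuisance_design(self.confounds)
        return self

    def transform(self, X):
        return nuisance_regress(X, self.confounds)


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase equiripple FIR bandpass as an sklearn transformer."""

    def __init__(self, sampling_rate_hz: float = 1.0 / 2.4,
                 passband_hz: tuple[float, float] = (0.005, 0.05),
                 upper_stop_edge_hz: float = 0.0613):
        self.sampling_rate_hz = sampling_rate_hz
        self.passband_hz = passband_hz
        self.upper_stop_edge_hz = upper_stop_edge_hz

    def fit(self, X=None, y=None):
        self.spec_ = design_bandpass(self.sampling_rate_hz, self.passband_hz,
                                     upper_stop_edge_hz=self.upper_stop_edge_hz)
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            self.fit()
        return apply_bandpass(X, self.spec_)


def condition_dataset(dataset: RoiDataset,
                      spec: FilterSpec | None = None,
                      bandpass: bool = True) -> RoiDataset:
    """PSC -> nuisance regression -> bandpass over every (participant, run)."""
    if bandpass and spec is None:
        n_time = min(len(v) for v in dataset.signals.values())
        spec = design_bandpass(max_order=max(90, n_time // 3))

    def fn(sig: pd.DataFrame, conf: pd.DataFrame) -> pd.DataFrame:
        out = percent_signal_change(sig)
        out = nuisance_regress(out, conf)
        if bandpass:
            out = apply_bandpass(out, spec)
        return out

    return dataset.map_signals(fn, conditioned=True)
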