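"""Rating-reliability screening and felt/perceived temporal similarity.

An emotion enters the downstream models only if it was rated consistently.
Consistency is summarised per (emotion, task) by three run-averaged
components — the fraction of raters who ever reported the emotion, the
fraction of timepoints where at least one rater reported it, and the mean
pairwise intersubject correlation (ISC) of the interpolated rating series —
combined as their geometric mean.  All three components live on comparable
[0, 1] scales (fractions; ISC clamped at 0 before the product) so the
geometric mean is scale-consistent.  The chance level is the 95th percentile
of combined values recomputed after independently shuffling each component
across emotions, pooled over iterations, emotions and both tasks; an emotion
is kept when the larger of its two task values exceeds that threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunManifest, ValidationError
from .containers import RatingPanel
from .design import RaterSeries, interpolate_to_grid

COMPONENTS = ["pct_raters", "pct_timepoints", "mean_isc"]


def rater_coverage(series: RaterSeries) -> pd.Series:
    """Fraction of raters with any non-zero sample, per emotion."""
    if series.values.shape[0] == 0:
        raise ValidationError("rater coverage undefined with zero raters")
    any_nonzero = (series.values > 0).any(axis=1)          # rater x emotion
    return pd.Series(any_nonzero.mean(axis=0), index=series.emotions)


def timepoint_coverage(series: RaterSeries) -> pd.Series:
    """Fraction of grid samples where at least one rater is non-zero."""
    if series.values.shape[1] == 0:
        raise ValidationError("timepoint coverage undefined on an empty grid")
    any_rater = (series.values > 0).any(axis=0)            # time x emotion
    return pd.Series(any_rater.mean(axis=0), index=series.emotions)


def pairwise_isc(series: RaterSeries) -> pd.Series:
    """Mean Pearson correlation over all unordered rater pairs, per emotion.

    Pairs where either series is constant are dropped (Pearson undefined);
    if every pair drops, the ISC is 0.
    """
    n_raters = series.values.shape[0]
    if n_raters < 2:
        raise ValidationError("pairwise ISC requires at least 2 raters")
    x = series.values - series.values.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)                                     # rater x emotion
    out = np.zeros(len(series.emotions))
    for e in range(len(series.emotions)):
        vals = []
        for i in range(n_raters):
            for j in range(i + 1, n_raters):
                if sd[i, e] == 0 or sd[j, e] == 0:
                    continue
                num = (x[i, :, e] * x[j, :, e]).mean()
                vals.append(num / (sd[i, e] * sd[j, e]))
        out[e] = np.mean(vals) if vals else 0.0
    return pd.Series(out, index=series.emotions)


def combined_reliability(pct_raters, pct_timepoints, mean_isc):
    """Geometric mean of the three components; 0 if any component <= 0."""
    a, b, c = np.broadcast_arrays(
        np.asarray(pct_raters, dtype=float),
        np.asarray(pct_timepoints, dtype=float),
        np.asarray(mean_isc, dtype=float),
    )
    ok = (a > 0) & (b > 0) & (c > 0)
    out = np.zeros(a.shape)
    out[ok] = np.cbrt(a[ok] * b[ok] * c[ok])
    return float(out) if out.ndim == 0 else out


@dataclass
class ReliabilityTable:
    """Per (emotion, task) reliability components and the screening outcome."""

    table: pd.DataFrame            # index (emotion, task); components+combined
    selection: pd.Series           # per emotion: max over tasks of combined
    threshold: float
    reliable: pd.Series            # per emotion, bool
    null_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def reliable_emotions(self) -> list[str]:
        return sorted(self.selection.index[self.reliable])

    def frame(self) -> pd.DataFrame:
        df = self.table.reset_index()
        df["selection"] = df["emotion"].map(self.selection)
        df["threshold"] = self.threshold
        df["reliable"] = df["emotion"].map(self.reliable)
        return df


def component_table(panel: RatingPanel,
                    manifests: dict[str, RunManifest],
                    tr: float) -> pd.DataFrame:
    """Run-averaged components per (emotion, task).

    Components are computed per run and averaged with equal run weights
    (arithmetic mean) before the geometric combination.
    """
    emotions = panel.emotions
    rows = []
    for task in panel.tasks:
        per_run = []
        for run_id, manifest in manifests.items():
            series = interpolate_to_grid(panel, manifest, tr, task,
                                         emotions=emotions)
            per_run.append(pd.DataFrame({
                "pct_raters": rater_coverage(series),
                "pct_timepoints": timepoint_coverage(series),
                "mean_isc": pairwise_isc(series),
            }))
        mean = sum(per_run) / len(per_run)
        mean["emotion"] = mean.index
        mean["task"] = task
        rows.append(mean)
    df = pd.concat(rows).set_index(["emotion", "task"]).sort_index()
    return df


def reliability_threshold(components: pd.DataFrame, n_perm: int,
                          rng: np.random.Generator | None = None,
                          alpha: float = 0.05,
                          exhaustive: bool = False
                          ) -> tuple[float, np.ndarray]:
    """Chance level of the combined measure under component shuffling.

    Per iteration and task, each component vector (over emotions) is permuted
    independently and the geometric mean recomputed; the threshold is the
    (1 - alpha) quantile (linear interpolation between order statistics) of
    the null values pooled across iterations, emotions and tasks.

    ``exhaustive=True`` enumerates every (n!)^3 triple of component
    permutations per task instead of sampling (small panels only);
    ``n_perm`` is ignored in that mode.
    """
    tasks = components.index.get_level_values("task").unique()
    nulls = []
    if exhaustive:
        from itertools import permutations
        for task in tasks:
            sub = components.xs(task, level="task")
            a, b, c = (sub[col].to_numpy() for col in COMPONENTS)
            n = len(a)
            if math.factorial(n) ** 3 > 2_000_000:
                raise ValueError("exhaustive enumeration infeasible for "
                                 f"{n} emotions")
            idx = list(permutations(range(n)))
            for pa in idx:
                for pb in idx:
                    for pc in idx:
                        nulls.append(combined_reliability(
                            a[list(pa)], b[list(pb)], c[list(pc)]))
    else:
        if rng is None:
            raise ValueError("rng required unless exhaustive=True")
        if n_perm < 20:
            warnings.warn("n_perm < 20: the 95th-percentile threshold is "
                          "unstable", stacklevel=2)
        for _ in range(n_perm):
            for task in tasks:
                sub = components.xs(task, level="task")
                cols = [rng.permutation(sub[c].to_numpy())
                        for c in COMPONENTS]
                nulls.append(combined_reliability(*cols))
    pooled = np.concatenate(nulls)
    return float(np.quantile(pooled, 1.0 - alpha)), pooled


def compute_reliability(panel: RatingPanel,
                        manifests: dict[str, RunManifest], tr: float,
                        n_perm: int = 1000, seed: int = 0,
                        alpha: float = 0.05) -> ReliabilityTable:
    """Full screening: components, combined value, permutation threshold."""
    comps = component_table(panel, manifests, tr)
    comps["combined"] = combined_reliability(
        comps["pct_raters"], comps["pct_timepoints"], comps["mean_isc"]
    )
    rng = np.random.default_rng(seed)
    threshold, nulls = reliability_threshold(comps[COMPONENTS], n_perm, rng,
                                             alpha)
    selection = comps["combined"].groupby(level="emotion").max()
    reliable = selection > threshold
    return ReliabilityTable(comps, selection, threshold, reliable, nulls)


def felt_perceived_similarity(panel: RatingPanel,
                              manifests: dict[str, RunManifest],
                              tr: float) -> pd.DataFrame:
    """Temporal correlation of felt vs perceived mean rating series.

    Mean-over-raters interpolated series of the two tasks, concatenated
    across runs, correlated per emotion; shared variance reported as r^2.
    Emotions with a constant series in either task are flagged undefined.
    """
    if set(panel.tasks) != {"perceived", "felt"}:
        raise ValidationError("both tasks required for felt/perceived "
                              "similarity")
    emotions = panel.emotions
    concat = {}
    for task in ("perceived", "felt"):
        parts = [
            interpolate_to_grid(panel, m, tr, task,
                                emotions=emotions).mean_over_raters()
            for m in manifests.values()
        ]
        concat[task] = np.concatenate(parts, axis=0)
    rows = []
    for e, emo in enumerate(emotions):
        x, y = concat["perceived"][:, e], concat["felt"][:, e]
        if x.std() == 0 or y.std() == 0:
            rows.append((emo, np.nan, np.nan, False))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((emo, r, r * r, True))
    return pd.DataFrame(rows, columns=["emotion", "r", "shared_variance",
                                       "defined"]).set_index("emotion")
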