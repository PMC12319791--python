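"""Plain-text (TSV/JSON) input and output.

All tabular I/O is tab-separated UTF-8 text with '.' decimals and header
rows; the pipeline operates on ROI-level series after external
preprocessing, so no binary imaging formats are handled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, RunManifest, ValidationError
from .containers import RATING_COLUMNS, RatingPanel, RoiDataset
from .conditioning import CONFOUND_COLUMNS


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def read_ratings(path, config: PipelineConfig | None = None) -> RatingPanel:
    """Read a long-format segment rating table (TSV)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:             # pragma: no cover - pandas detail
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("onset_s", "offset_s", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2    # header + 1-based
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = coerced
    scale_max = config.rating_scale_max if config else 4.0
    return RatingPanel(df[RATING_COLUMNS], scale_max=scale_max)


def write_ratings(panel: RatingPanel, path) -> None:
    panel.segments[RATING_COLUMNS].to_csv(path, sep="\t", index=False)


def read_roi_timeseries(path, confounds_path,
                        manifest: RunManifest | None = None,
                        participant: str = "sub01",
                        run: str | None = None) -> RoiDataset:
    """Read one (participant, run) time x ROI matrix plus its confounds."""
    path, confounds_path = Path(path), Path(confounds_path)
    sig = pd.read_csv(path, sep="\t")
    conf = pd.read_csv(confounds_path, sep="\t")
    for name, df in (("signals", sig), ("confounds", conf)):
        nonnum = df.columns[~df.apply(
            lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(nonnum):
            raise ParseError(
                f"non-numeric cell(s) in {name} column(s) {list(nonnum)}"
            )
    if len(sig) != len(conf):
        raise ValidationError(
            f"signals ({len(sig)} rows) and confounds ({len(conf)} rows) "
            "are misaligned"
        )
    missing = [c for c in CONFOUND_COLUMNS if c not in conf.columns]
    if missing:
        raise ParseError(f"{confounds_path}: missing confound columns "
                         f"{missing}")
    if run is None:
        run = manifest.run_id if manifest else "run1"
    manifests = {run: manifest} if manifest else {}
    return RoiDataset(
        signals={(participant, run): sig},
        confounds={(participant, run): conf[CONFOUND_COLUMNS]},
        roi_labels=list(sig.columns),
        manifests=manifests,
    )


def write_matrix(df: pd.DataFrame, path, index_label: str = "") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_dataset(dataset: RoiDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (part, run), sig in dataset.signals.items():
        sig.to_csv(out / f"bold_{part}_{run}.tsv", sep="\t", index=False)
        dataset.confounds[(part, run)].to_csv(
            out / f"confounds_{part}_{run}.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2,
                                     sort_keys=True))


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())
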