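"""End-to-end pipeline: ratings -> designs -> reliability -> conditioning
-> cross-validated fits -> felt/perceived contrast -> per-emotion maps ->
similarity clustering, with all stage outputs written as TSV/JSON."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import EmotionClusterer, cross_run_similarity, \
    rating_similarity
from .conditioning import condition_dataset, design_bandpass
from .config import PipelineConfig, ValidationError
from .containers import RoiDataset
from .design import build_designs, hrf_kernel
from .fitting import between_run_cv, contrast_tasks
from .io import write_matrix, write_summary
from .mapping import activation_extent, shiftnull_fwer_test
from .reliability import compute_reliability, felt_perceived_similarity
from .simulate import SimulationSpec, simulate_study

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> tuple[PipelineConfig, SimulationSpec | None, dict]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig.from_dict(raw.get("pipeline", {}))
    sim = None
    if "synthetic" in raw:
        sim_kwargs = dict(raw["synthetic"] or {})
        sim_kwargs.setdefault("rng_seed", cfg.rng_seed)
        sim_kwargs.setdefault("n_runs", cfg.n_runs)
        sim_kwargs.setdefault("tr", cfg.tr_seconds)
        sim = SimulationSpec(**sim_kwargs)
    return cfg, sim, raw


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run every stage on the configured (synthetic) inputs.

    Writes, per stage: the reliability table and its null distribution, CV
    fit maps and betas per task, the felt-vs-perceived contrast, per-emotion
    significance maps and extents, rating- and brain-space similarity
    matrices with dendrogram and clusters, filter audit files, and a JSON
    summary echoing configuration, seed and thresholds.
    """
    cfg, sim, raw = load_config(config_path)
    if sim is None:
        raise ValidationError("config needs a `synthetic:` block (external "
                              "data ingestion goes through the io module)")
    out = Path(out_dir if out_dir is not None
               else raw.get("output_dir", "emokinetics_out"))
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "rng_seed": cfg.rng_seed,
                     "stages": {}}

    def stage(name):
        logger.info("stage %s (seed %d)", name, cfg.rng_seed)
        return name

    try:
        name = stage("simulate")
        study = simulate_study(sim)
        dataset = study.dataset
        summary["stages"][name] = {"n_participants": sim.n_participants,
                                   "n_rois": sim.n_rois,
                                   "n_emotions": sim.n_emotions}
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        name = stage("reliability")
        rel = compute_reliability(study.panel, study.manifests, cfg.tr_seconds,
                                  n_perm=cfg.n_permutations,
                                  seed=cfg.rng_seed, alpha=cfg.alpha)
        write_matrix(rel.frame().set_index(["emotion", "task"]),
                     out / "reliability.tsv", index_label="emotion\ttask")
        pd.DataFrame({"null_combined": rel.null_values}).to_csv(
            out / "reliability_null.tsv", sep="\t", index=False)
        sim_fp = felt_perceived_similarity(study.panel, study.manifests,
                                           cfg.tr_seconds)
        write_matrix(sim_fp, out / "felt_perceived_similarity.tsv",
                     index_label="emotion")
        summary["stages"][name] = {"threshold": rel.threshold,
                                   "n_reliable": int(rel.reliable.sum())}
        reliable = rel.reliable_emotions
        if len(reliable) < 2:
            reliable = sorted(rel.selection.nlargest(2).index)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reliability", exc) from exc

    try:
        name = stage("conditioning")
        n_time = sim.n_timepoints_per_run
        spec = design_bandpass(sampling_rate_hz=1.0 / cfg.tr_seconds,
                               passband_hz=cfg.passband_hz,
                               max_order=max(90, n_time // 3))
        conditioned = condition_dataset(dataset, spec=spec)
        pd.DataFrame({"tap": spec.coefficients}).to_csv(
            out / "filter_taps.tsv", sep="\t", index=False)
        pd.DataFrame(spec.measured, index=[0]).to_csv(
            out / "filter_response.tsv", sep="\t", index=False)
        summary["stages"][name] = {"filter_order": spec.order,
                                   **spec.measured}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("conditioning", exc) from exc

    try:
        name = stage("fit")
        fits = {}
        for task in ("perceived", "felt"):
            designs = {r: study.designs[(r, task)].subset(reliable)
                       for r in dataset.runs}
            fits[task] = between_run_cv(conditioned, designs,
                                        direction="encode",
                                        n_train=cfg.n_train_runs,
                                        seed=cfg.rng_seed, task=task)
            write_matrix(fits[task].beta, out / f"beta_{task}.tsv",
                         index_label="emotion")
            write_matrix(fits[task].test_fit,
                         out / f"cv_fit_between-runs_{task}.tsv",
                         index_label="participant")
        contrast = contrast_tasks(fits["felt"], fits["perceived"],
                                  n_perm=cfg.n_permutations,
                                  seed=cfg.rng_seed, alpha=cfg.alpha)
        write_matrix(pd.DataFrame({"t": contrast.t, "mask": contrast.mask}),
                     out / "contrast_t.tsv", index_label="roi")
        write_summary({"threshold": contrast.threshold,
                       "n_perm": cfg.n_permutations},
                      out / "contrast_threshold.json")
        summary["stages"][name] = {
            "mean_fit": {t: float(f.test_fit.to_numpy().mean())
                         for t, f in fits.items()},
            "contrast_threshold": contrast.threshold,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fit", exc) from exc

    try:
        name = stage("map")
        task = "perceived"
        designs = {r: study.designs[(r, task)].subset(reliable)
                   for r in dataset.runs}
        emomap = shiftnull_fwer_test(
            conditioned, designs, n_shift=cfg.n_shift_null,
            n_perm=cfg.n_permutations, min_shift=cfg.min_shift_samples,
            seed=cfg.rng_seed, alpha=cfg.alpha)
        write_matrix(emomap.t_mean, out / "emotion_roi_t.tsv",
                     index_label="roi")
        write_matrix(emomap.mask, out / "emotion_roi_mask.tsv",
                     index_label="roi")
        extent, _ = activation_extent(emomap.mask)
        write_matrix(extent, out / "extent_by_emotion.tsv",
                     index_label="emotion")
        summary["stages"][name] = {"threshold": emomap.threshold,
                                   "n_significant":
                                       int((emomap.mask != 0).sum().sum())}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("map", exc) from exc

    try:
        name = stage("cluster")
        sim_ratings = rating_similarity(study.designs, reliable)
        neural_sym, neural_raw = cross_run_similarity(
            emomap.r, dataset.runs, cfg.n_train_runs, reliable)
        clusterer = EmotionClusterer(cfg.linkage_cutoff_fraction)
        for label, mat in (("ratings", sim_ratings), ("neural", neural_sym)):
            struct = clusterer.structure(mat)
            write_matrix(mat, out / f"similarity_{label}.tsv",
                         index_label="condition")
            link = pd.DataFrame(struct.linkage,
                                columns=["left", "right", "height", "size"])
            link.to_csv(out / f"linkage_{label}.tsv", sep="\t", index=False)
            pd.DataFrame({"condition": struct.conditions,
                          "cluster": struct.labels.to_numpy()}).to_csv(
                out / f"clusters_{label}.tsv", sep="\t", index=False)
            (out / f"dendrogram_{label}.nwk").write_text(struct.to_newick())
            summary["stages"].setdefault(name, {})[label] = {
                "n_clusters": struct.n_clusters,
            }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    write_summary(summary, out / "summary.json")
    return out


def write_report(results: dict, out_dir) -> Path:
    """Write any mapping of names to DataFrames/dicts as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            write_matrix(obj, out / f"{name}.tsv")
        elif isinstance(obj, pd.Series):
            obj.to_frame(name).to_csv(out / f"{name}.tsv", sep="\t")
        elif isinstance(obj, np.ndarray):
            pd.DataFrame(obj).to_csv(out / f"{name}.tsv", sep="\t",
                                     index=False)
        else:
            write_summary(obj if isinstance(obj, dict) else {"value": obj},
                          out / f"{name}.json")
    return out
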