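"""End-to-end orchestration: simulate -> prewhiten -> parcellate ->
graph features -> double-CV classification -> selection-frequency
significance -> report.

The functional atlas is always built from control-group scans only, so
group differences cannot leak into the region definitions. A
reference-label mode accepts an external integer labeling instead
(the anatomical-atlas arm of the design).

Every stage output is persisted under the run directory together with a
manifest (config echo, seeds, SHA-256 of each output), so a re-run with
the same config reproduces every deterministic output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features, parcellation, prewhiten, selection_stats
from .classify import ClassifierSpec
from .features import RegistryConfig
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "run_condition_grid"]


@dataclass
class PipelineConfig:
    """Nested configuration of every pipeline stage."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    atlas_mode: str = "functional"  # or "reference-label"
    reference_labels: np.ndarray | None = None
    n_regions: int = 4              # dendrogram cut K
    prewhiten: bool = True
    connectivity: int = 6
    density: float = 0.30
    registry: RegistryConfig = field(default_factory=RegistryConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_outer_folds: int = 5
    n_inner_shuffles: int = 4
    n_partitions: int = 10
    screen_threshold: float = 0.60
    max_features: int = 40
    alpha: float = 0.001
    n_chance_shuffles: int = 10
    chance_partitions: int = 1
    community_seed: int = 0
    out_dir: str = "netmark_run"

    def validate(self) -> None:
        self.synthetic.validate()
        if self.atlas_mode not in ("functional", "reference-label"):
            raise ValueError("atlas_mode must be 'functional' or 'reference-label'")
        if self.atlas_mode == "reference-label" and self.reference_labels is None:
            raise ValueError("reference-label mode requires reference_labels")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_atlas(config: PipelineConfig, datasets) -> parcellation.Atlas:
    coords = datasets[0].coords
    if config.atlas_mode == "reference-label":
        labels = np.asarray(config.reference_labels, dtype=int)
        return parcellation.Atlas(labels, int(labels.max()), coords)
    controls = [d for d in datasets if d.group_label == "control"]
    if not controls:
        raise ValueError("functional atlas requires control-group scans")
    group = parcellation.concatenate_group(controls)
    corr = parcellation.correlation_matrix(group.series)
    dist = parcellation.correlation_distance(corr)
    dendro = parcellation.constrained_ward(dist, coords, config.connectivity)
    return parcellation.cut_dendrogram(dendro, config.n_regions, coords)


def _features_for(config: PipelineConfig, datasets, atlas) -> features.FeatureTable:
    graphs = {}
    for d in datasets:
        ts = features.region_timeseries(d, atlas)
        g = features.weighted_graph(ts)
        features.binarize_density(g, config.density)
        features.detect_communities(g, seed=config.community_seed)
        graphs[d.subject_id] = g
    return features.assemble_features(graphs, config.registry)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and persist outputs; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    logger.info("stage simulate: generating cohort")
    try:
        datasets, truth = generate_cohort(config.synthetic)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if config.prewhiten:
        logger.info("stage prewhiten")
        try:
            datasets = [prewhiten.prewhiten_dataset(d) for d in datasets]
        except Exception as exc:
            raise RuntimeError(f"stage 'prewhiten' failed: {exc}") from exc

    logger.info("stage parcellate (%s atlas)", config.atlas_mode)
    try:
        atlas = _build_atlas(config, datasets)
    except Exception as exc:
        raise RuntimeError(f"stage 'parcellate' failed: {exc}") from exc
    pd.DataFrame({"voxel": np.arange(len(atlas.voxel_region_labels)),
                  "region": atlas.voxel_region_labels}).to_csv(
        out / "atlas_labels.csv", index=False)

    logger.info("stage features")
    try:
        table = _features_for(config, datasets, atlas)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc
    table.frame.to_csv(out / "features.csv", index_label="subject_id")

    logger.info("stage classify: %d features, %d subjects",
                table.frame.shape[1], table.frame.shape[0])
    labels = np.array([1 if d.group_label == "patient" else 0 for d in datasets])
    ids = [d.subject_id for d in datasets]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = classify.make_cv_plan(ids, labels, config.n_outer_folds,
                                         config.n_inner_shuffles,
                                         config.n_partitions,
                                         seed=config.synthetic.seed)
            results = classify.run_double_cv(
                table.frame.to_numpy(), labels, list(table.frame.columns), plan,
                config.classifier, config.screen_threshold, config.max_features)
            results.chance_accuracies = classify.estimate_chance(
                table.frame.to_numpy(), labels, list(table.frame.columns),
                config.classifier, config.n_chance_shuffles,
                config.n_outer_folds, config.n_inner_shuffles,
                config.chance_partitions, config.screen_threshold,
                config.max_features, seed=config.synthetic.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    trace_rows = []
    for t in results.traces:
        trace_rows.append({
            "partition": t.partition, "fold": t.fold,
            "n_screened": len(t.screened_features),
            "sfs_order": ";".join(t.sfs_order),
            "inner_accuracy": ";".join(f"{a:.6f}" for a in t.inner_accuracy_by_step),
            "test_accuracy": ";".join(f"{a:.6f}" for a in t.test_accuracy_by_step),
            "best_step": t.best_step,
            "tp": t.tp, "tn": t.tn, "fp": t.fp, "fn": t.fn})
    pd.DataFrame(trace_rows).to_csv(out / "traces.csv", index=False)
    mr = classify.misclassification_rate(results)
    pd.DataFrame({"subject_id": list(mr), "mr": list(mr.values()),
                  "group": ["patient" if l else "control" for l in labels]}
                 ).to_csv(out / "mr.csv", index=False)

    logger.info("stage significance")
    try:
        sig = selection_stats.significant_features(results, config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'significance' failed: {exc}") from exc
    sig.to_csv(out / "significance.csv", index=False)
    null = sig.attrs["null"]

    summary = {
        "accuracy": results.accuracy,
        "sensitivity": results.sensitivity,
        "specificity": results.specificity,
        "single_cv_curve": results.single_cv_curve.tolist(),
        "double_cv_curve": results.double_cv_curve.tolist(),
        "chance_accuracies": results.chance_accuracies,
        "mean_screened_count": results.mean_screened_count,
        "n_traces": len(results.traces),
        "n_features": int(table.frame.shape[1]),
        "n_dropped_features": len(table.dropped),
        "null": {"F": null.f_total, "S": null.set_size,
                 "n_sets": null.n_sets, "alpha": null.alpha,
                 "p_select": null.p_select},
        "planted_pairs": _jsonable(truth.planted_pairs),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "config": _jsonable(config),
        "seed": config.synthetic.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name not in ("manifest.json",) and p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete in %.1fs", time.perf_counter() - t0)
    return out


def make_report(run_dir: str | Path) -> list[Path]:
    """Figures and tables from a completed run: accuracy-vs-features
    curves, the selection-frequency histogram with its expected-null
    overlay, and the misclassification-rate distribution."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"incomplete run: {summary_path} missing")
    summary = json.loads(summary_path.read_text())
    sig = pd.read_csv(run_dir / "significance.csv")
    mr = pd.read_csv(run_dir / "mr.csv")
    outputs = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    steps = np.arange(1, len(summary["single_cv_curve"]) + 1)
    ax.plot(steps, summary["single_cv_curve"], "o-", label="single CV")
    ax.plot(steps, summary["double_cv_curve"], "s-", label="double CV")
    if summary["chance_accuracies"]:
        ax.axhline(np.mean(summary["chance_accuracies"]), ls="--", color="gray",
                   label="chance")
    ax.set_xlabel("number of features")
    ax.set_ylabel("accuracy")
    ax.legend()
    fig.tight_layout()
    p = run_dir / "accuracy_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs.append(p)

    null = selection_stats.FrequencyNull(
        summary["null"]["F"], summary["null"]["S"], summary["null"]["n_sets"],
        summary["null"]["alpha"])
    freqs = sig["frequency"].to_numpy()
    observed = np.bincount(freqs, minlength=null.n_sets + 1)
    expected = selection_stats.expected_histogram(null, summary["n_features"])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs = np.arange(null.n_sets + 1)
    ax.bar(xs, observed, width=0.8, label="observed")
    ax.plot(xs, expected, "r.-", label="expected under null")
    ax.set_xlabel("appearances in selected sets")
    ax.set_ylabel("number of features")
    ax.set_yscale("symlog")
    ax.legend()
    fig.tight_layout()
    p = run_dir / "selection_frequency.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(mr["mr"], bins=np.linspace(0, 1, 11), edgecolor="k")
    ax.set_xlabel("misclassification rate")
    ax.set_ylabel("subjects")
    fig.tight_layout()
    p = run_dir / "mr_distribution.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs.append(p)

    hist = pd.DataFrame({"appearances": xs, "observed": observed,
                         "expected": expected})
    p = run_dir / "selection_frequency.csv"
    hist.to_csv(p, index=False)
    outputs.append(p)
    return outputs


def run_condition_grid(config: PipelineConfig) -> pd.DataFrame:
    """The 2 x 2 design: prewhitened/raw time series crossed with the
    functional vs reference-label atlas. The reference labeling is the
    generator's ground truth when none is supplied. Returns a summary
    table of double-CV accuracy per condition."""
    config.validate()
    ref = config.reference_labels
    if ref is None:
        _, truth = generate_cohort(config.synthetic)
        ref = truth.voxel_region_labels
    rows = []
    for prew in (True, False):
        for mode in ("functional", "reference-label"):
            sub = replace(config, prewhiten=prew, atlas_mode=mode,
                          reference_labels=ref,
                          out_dir=str(Path(config.out_dir) /
                                      f"{'prewhitened' if prew else 'raw'}_{mode}"))
            run_dir = run_pipeline(sub)
            summary = json.loads((run_dir / "summary.json").read_text())
            rows.append({"prewhiten": "prewhitened" if prew else "raw",
                         "atlas": mode,
                         "accuracy": summary["accuracy"],
                         "sensitivity": summary["sensitivity"],
                         "specificity": summary["specificity"]})
    return pd.DataFrame(rows)
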