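"""End-to-end synthetic benchmark and demo.

Builds a cell-wise medium-level dataset with the real pipeline (render ->
morphometry -> filter -> K-means pseudo-labels), a benign/malignant
"high-level" proxy task whose classes share the clusters' morphology
(benign: few/large nuclei; malignant: many/small), then trains and evaluates
the baseline one-stage and the proposed two-stage schedules with the small
CNN backbone.  Everything is driven by one seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import datasets, morphometry, synth
from .config import RunConfig, derive_seed
from .evaluation import NEGATIVE, POSITIVE, EvalReport, ScoredPatch, evaluate
from .training import Stage, StageData, StageSchedule, run_stepwise

__all__ = ["BenchmarkResult", "stepwise_benchmark", "run_demo"]

#: Cluster morphologies scaled to 64 px patches.
_C1_SMALL = synth.ClusterParams(count_mean=5.0, radius_range=(5.0, 8.0))
_C2_SMALL = synth.ClusterParams(count_mean=20.0, radius_range=(2.0, 3.5))


def _desk_threshold_params(cfg: RunConfig) -> morphometry.PhansalkarParams:
    # Shrink the window in step with the patch so the local statistics stay local.
    radius = max(3, int(round(cfg.threshold.window_radius * cfg.demo.patch_size / 256)))
    return morphometry.PhansalkarParams(
        k=cfg.threshold.k,
        r=cfg.threshold.r,
        p=cfg.threshold.p,
        q=cfg.threshold.q,
        window_radius=radius,
        bright_nuclei=cfg.threshold.bright_nuclei,
    )


def _desk_watershed_params(cfg: RunConfig) -> morphometry.WatershedParams:
    scale = cfg.demo.patch_size / 256
    return morphometry.WatershedParams(
        min_seed_separation=max(2, int(round(cfg.watershed.min_seed_separation * scale))),
        min_area=max(4, int(round(cfg.watershed.min_area * scale**2))),
    )


def _stack(patches, downsample: int) -> np.ndarray:
    return np.stack([p.patch[::downsample, ::downsample] for p in patches])


def _high_population(n_per_class: int, seed: int, shape) -> tuple[np.ndarray, np.ndarray]:
    """Benign/malignant proxy patches; labels 0 = benign, 1 = malignant."""
    pop = synth.generate_cellwise_population(
        n_per_class, _C1_SMALL, _C2_SMALL, seed=seed, shape=shape
    )
    y = np.array([0 if p.cluster_id == 1 else 1 for p in pop])
    return pop, y


@dataclass
class BenchmarkResult:
    auc_one_stage: float
    auc_two_stage: float
    report_one_stage: EvalReport
    report_two_stage: EvalReport
    n_medium: int
    cluster_sizes: tuple[int, int]


def build_medium_cellwise(cfg: RunConfig, seed: int):
    """Generate patches, measure nuclei, filter, and pseudo-label by K-means.

    Returns (kept patches, pseudo labels in {1, 2}, measured features).
    """
    shape = (cfg.demo.patch_size, cfg.demo.patch_size)
    pop = synth.generate_cellwise_population(
        cfg.demo.n_medium_per_cluster, _C1_SMALL, _C2_SMALL, seed=seed, shape=shape
    )
    tparams = _desk_threshold_params(cfg)
    wparams = _desk_watershed_params(cfg)
    dmat = np.asarray(cfg.stain.deconvolution_matrix)
    features = []
    mean_h = []
    from .stains import separate_stains

    for p in pop:
        m = morphometry.measure(p.patch, tparams, wparams, dmat)
        features.append(datasets.FeatureVector(total_area=m.total_area, count=m.count))
        h = np.maximum(separate_stains(p.patch, dmat).hematoxylin, 0.0)
        mean_h.append(float(h.mean()))
    policy = datasets.FilterPolicy(
        min_count=min(cfg.filter.min_count, 2), min_mean_h=cfg.filter.min_mean_h
    )
    kept, _ = datasets.filter_patches(features, mean_h, policy)
    kept_features = [features[i] for i in kept]
    labels = datasets.cluster_cellwise(kept_features, k=cfg.cluster.k, seed=seed)
    return [pop[i] for i in kept], labels, kept_features


def stepwise_benchmark(seed: int, cfg: RunConfig | None = None) -> BenchmarkResult:
    """Train one-stage and two-stage schedules on the synthetic benchmark."""
    if cfg is None:
        cfg = RunConfig()
    shape = (cfg.demo.patch_size, cfg.demo.patch_size)
    ds = cfg.demo.train_downsample

    med_patches, med_labels, _ = build_medium_cellwise(cfg, derive_seed(seed, 1))
    x_med = _stack(med_patches, ds)
    y_med = (np.asarray(med_labels) - 1).astype(int)
    rng = np.random.default_rng(derive_seed(seed, 1))
    order = rng.permutation(len(x_med))
    n_train, _ = datasets.split_train_val(len(x_med), cfg.split.train_fraction)
    tr, va = order[:n_train], order[n_train:]
    med_data = StageData(x_med[tr], y_med[tr], x_med[va], y_med[va])

    pops = {}
    for name, n, idx in (
        ("train", cfg.demo.n_high_train_per_class, 2),
        ("val", cfg.demo.n_high_val_per_class, 3),
        ("test", cfg.demo.n_high_test_per_class, 4),
    ):
        pop, y = _high_population(n, derive_seed(seed, idx), shape)
        pops[name] = (_stack(pop, ds), y)
    high_data = StageData(
        pops["train"][0], pops["train"][1], pops["val"][0], pops["val"][1]
    )

    def high_stage(stage_seed: int) -> Stage:
        return Stage(
            name="high",
            n_classes=2,
            data=high_data,
            epochs=cfg.demo.high_epochs,
            learning_rate=cfg.demo.learning_rate,
            batch_size=cfg.training.batch_size,
            seed=stage_seed,
        )

    one = StageSchedule(init_seed=seed, stages=[high_stage(derive_seed(seed, 2))])
    two = StageSchedule(
        init_seed=seed,
        stages=[
            Stage(
                name="medium_cell",
                n_classes=2,
                data=med_data,
                epochs=cfg.demo.medium_epochs,
                learning_rate=cfg.demo.learning_rate,
                batch_size=cfg.training.batch_size,
                seed=derive_seed(seed, 1),
            ),
            high_stage(derive_seed(seed, 2)),
        ],
    )

    x_test, y_test = pops["test"]
    reports = {}
    for name, schedule in (("one", one), ("two", two)):
        model, _ = run_stepwise(schedule)
        probs = model.network.predict_proba(x_test)
        scored = [
            ScoredPatch(score=float(p[1]), truth=POSITIVE if t == 1 else NEGATIVE)
            for p, t in zip(probs, y_test)
        ]
        reports[name] = evaluate(scored, cfg.evaluation.threshold)

    n1 = int((np.asarray(med_labels) == 1).sum())
    n2 = int((np.asarray(med_labels) == 2).sum())
    return BenchmarkResult(
        auc_one_stage=reports["one"].auc,
        auc_two_stage=reports["two"].auc,
        report_one_stage=reports["one"],
        report_two_stage=reports["two"],
        n_medium=len(med_patches),
        cluster_sizes=(n1, n2),
    )


def run_demo(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Full synthetic demo: datasets, manifests, both schedules, reports.

    Writes the medium-level manifests, per-scheme evaluation reports, and a
    comparison summary to ``out_dir``; deterministic per ``cfg.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = cfg.seed

    shape = (cfg.demo.patch_size, cfg.demo.patch_size)
    tissue = synth.generate_tissuewise_population(
        cfg.demo.n_tissue_per_class, seed=derive_seed(seed, 0), shape=shape
    )
    records = []
    for i, p in enumerate(tissue):
        split = "validation" if i % cfg.demo.n_tissue_per_class == 0 else "train"
        records.append(
            datasets.PatchRecord(
                path=f"tissue_{i:04d}.png",
                level="medium_tissue",
                label=p.tissue_class,
                split=split,
            )
        )
    manifests = datasets.build_manifests(records)
    datasets.write_manifests(manifests, out / "manifests")

    result = stepwise_benchmark(seed, cfg)
    result.report_one_stage.to_json(out / "report_one_stage.json")
    result.report_two_stage.to_json(out / "report_two_stage.json")

    summary = {
        "seed": seed,
        "auc_one_stage": result.auc_one_stage,
        "auc_two_stage": result.auc_two_stage,
        "auc_gain": result.auc_two_stage - result.auc_one_stage,
        "n_medium_patches": result.n_medium,
        "medium_cluster_sizes": list(result.cluster_sizes),
        "n_tissue_records": len(records),
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out / "summary.json"
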