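"""Run configuration schema, YAML round-tripping, and seed derivation.

Every parameter defaults to the value the corresponding module declares;
unknown keys are rejected.  One global seed fans out deterministically to
per-stage seeds via :func:`derive_seed` (global seed + stage index), giving
reproducible yet distinct random streams.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

DEFAULT_DECONVOLUTION_ROWS = [
    [1.88, -0.07, -0.60],
    [-1.02, 1.13, -0.48],
    [-0.55, -0.13, 1.57],
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StainBlock(_Block):
    deconvolution_matrix: list[list[float]] = Field(
        default_factory=lambda: [row[:] for row in DEFAULT_DECONVOLUTION_ROWS]
    )


class ThresholdBlock(_Block):
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    window_radius: int = 15
    bright_nuclei: bool = True


class WatershedBlock(_Block):
    min_seed_separation: int = 7
    min_area: int = 15


class FilterBlock(_Block):
    min_count: int = 5
    min_mean_h: float = 0.02


class ClusterBlock(_Block):
    k: int = 2


class SplitBlock(_Block):
    train_fraction: float = 0.9
    purity: float = 0.9
    patch_size: int = 256


class TrainingBlock(_Block):
    backbone: str = "small-cnn"
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16


class EvaluationBlock(_Block):
    threshold: float = 0.5


class DemoBlock(_Block):
    """Desk-scale sizes for the end-to-end synthetic demo."""

    patch_size: int = 64
    train_downsample: int = 2
    n_medium_per_cluster: int = 60
    n_tissue_per_class: int = 6
    n_high_train_per_class: int = 12
    n_high_val_per_class: int = 12
    n_high_test_per_class: int = 40
    medium_epochs: int = 6
    high_epochs: int = 12
    learning_rate: float = 0.05


class RunConfig(_Block):
    seed: int = 0
    stain: StainBlock = Field(default_factory=StainBlock)
    threshold: ThresholdBlock = Field(default_factory=ThresholdBlock)
    watershed: WatershedBlock = Field(default_factory=WatershedBlock)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    cluster: ClusterBlock = Field(default_factory=ClusterBlock)
    split: SplitBlock = Field(default_factory=SplitBlock)
    training: TrainingBlock = Field(default_factory=TrainingBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    demo: DemoBlock = Field(default_factory=DemoBlock)


def derive_seed(global_seed: int, stage_index: int) -> int:
    """Per-stage seed: global seed plus stage index."""
    return global_seed + stage_index


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config (defaults when ``path`` is None); unknown keys reject."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
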