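"""Medium-level dataset builders: tissue patches, filtering, clustering, splits.

Two "medium-level" datasets can be produced cheaply:

* tissue-wise — grid patches cut from an annotated image, labeled
  background / epithelium / stroma when at least ``purity`` of their pixels
  carry one class;
* cell-wise — patches pseudo-labeled by K-means on the per-patch
  (total nucleus area, nucleus count) feature vector, after excluding
  patches with too few nuclei or too little hematoxylin signal.

Manifests record (path, level, label, split) and are checked for the
disjointness the experimental design requires: no patch in two levels, no
patch in two splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "PatchRecord",
    "FeatureVector",
    "FilterPolicy",
    "TISSUE_CLASSES",
    "extract_tissue_patches",
    "filter_patches",
    "cluster_cellwise",
    "split_train_val",
    "build_manifests",
    "ManifestIntegrityError",
]

TISSUE_CLASSES = ("background", "epithelium", "stroma")
LEVELS = ("medium_tissue", "medium_cell", "high")
SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class PatchRecord:
    path: str
    level: str
    label: str
    split: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")


@dataclass(frozen=True)
class FeatureVector:
    """The 2-D morphometry feature: total nucleus area and nucleus count."""

    total_area: float
    count: int

    def __post_init__(self) -> None:
        if self.total_area < 0 or self.count < 0:
            raise ValueError("features must be nonnegative")


@dataclass(frozen=True)
class FilterPolicy:
    """Exclusion policy: too few nuclei, or too weak hematoxylin signal."""

    min_count: int = 5
    min_mean_h: float = 0.02

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def extract_tissue_patches(
    image: np.ndarray,
    class_mask: np.ndarray,
    patch_size: int = 256,
    purity: float = 0.9,
    level: str = "medium_tissue",
    path_prefix: str = "patch",
) -> list[tuple[PatchRecord, np.ndarray]]:
    """Cut non-overlapping grid patches and label them by mask majority.

    ``class_mask`` holds integer codes 0 = background, 1 = epithelium,
    2 = stroma.  A patch is kept with class ``c`` iff at least ``purity`` of
    its pixels carry ``c``; boundary-straddling patches are discarded.
    Returns (record, pixel array) pairs; split assignment is left to the
    caller (records default to "train").
    """
    image = np.asarray(image)
    class_mask = np.asarray(class_mask)
    if image.shape[:2] != class_mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {class_mask.shape} shapes differ"
        )
    if not np.isin(class_mask, np.arange(len(TISSUE_CLASSES))).all():
        raise ValueError("mask contains codes outside {0, 1, 2}")
    out: list[tuple[PatchRecord, np.ndarray]] = []
    n_rows = image.shape[0] // patch_size
    n_cols = image.shape[1] // patch_size
    for i in range(n_rows):
        for j in range(n_cols):
            sl = (
                slice(i * patch_size, (i + 1) * patch_size),
                slice(j * patch_size, (j + 1) * patch_size),
            )
            tile_mask = class_mask[sl]
            counts = np.bincount(tile_mask.ravel(), minlength=len(TISSUE_CLASSES))
            top = int(counts.argmax())
            if counts[top] / tile_mask.size >= purity:
                record = PatchRecord(
                    path=f"{path_prefix}_r{i}_c{j}.png",
                    level=level,
                    label=TISSUE_CLASSES[top],
                    split="train",
                )
                out.append((record, image[sl]))
    return out


def filter_patches(
    features: list[FeatureVector],
    mean_h: list[float],
    policy: FilterPolicy | None = None,
) -> tuple[list[int], list[tuple[int, list[str]]]]:
    """Partition patch indices into kept / excluded under the policy.

    A patch is kept iff ``count >= min_count`` and ``mean H >= min_mean_h``;
    every excluded patch carries its reasons.
    """
    if policy is None:
        policy = FilterPolicy()
    if len(features) != len(mean_h):
        raise ValueError("features and mean_h lengths differ")
    kept: list[int] = []
    excluded: list[tuple[int, list[str]]] = []
    for i, (feat, h) in enumerate(zip(features, mean_h)):
        reasons = []
        if feat.count < policy.min_count:
            reasons.append("too_few_nuclei")
        if h < policy.min_mean_h:
            reasons.append("stain_inconformity")
        if reasons:
            excluded.append((i, reasons))
        else:
            kept.append(i)
    return kept, excluded


def cluster_cellwise(
    features: list[FeatureVector], k: int = 2, seed: int = 0
) -> np.ndarray:
    """Pseudo-label patches by K-means on z-scored (total_area, count).

    Cluster ids are renumbered by mean nucleus count ascending (ties broken
    by mean total area), so cluster 1 is the fewer/larger-nuclei cluster and
    cluster 2 the more/smaller one.  Returns labels in {1, ..., k}.
    """
    x = np.array([[f.total_area, float(f.count)] for f in features])
    if len(x) < k or len(np.unique(x, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct feature vectors")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(z)
    order = sorted(
        range(k),
        key=lambda c: (x[raw == c, 1].mean(), x[raw == c, 0].mean()),
    )
    relabel = {c: rank + 1 for rank, c in enumerate(order)}
    return np.array([relabel[c] for c in raw])


def split_train_val(n_items: int, train_fraction: float = 0.9) -> tuple[int, int]:
    """Round-half-up 90/10 (by default) split of ``n_items``.

    Returns (n_train, n_validation) with n_train = ⌊f·n + 0.5⌋.
    """
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in [0, 1]")
    n_train = int(np.floor(train_fraction * n_items + 0.5))
    return n_train, n_items - n_train


class ManifestIntegrityError(ValueError):
    """A patch appears in more than one level or more than one split."""


def build_manifests(records: list[PatchRecord]) -> dict[str, pd.DataFrame]:
    """Group records into per-level manifests, asserting disjointness.

    Raises :class:`ManifestIntegrityError` listing offending paths if any
    path occurs in two levels or two splits.  Empty input yields empty
    manifests without error.
    """
    df = pd.DataFrame(
        [(r.path, r.level, r.label, r.split) for r in records],
        columns=["path", "level", "label", "split"],
    )
    if not df.empty:
        by_path = df.groupby("path")
        multi_level = by_path["level"].nunique()
        offenders = multi_level[multi_level > 1].index.tolist()
        if offenders:
            raise ManifestIntegrityError(f"paths in multiple levels: {offenders}")
        multi_split = by_path["split"].nunique()
        offenders = multi_split[multi_split > 1].index.tolist()
        if offenders:
            raise ManifestIntegrityError(f"paths in multiple splits: {offenders}")
        dupes = by_path.size()
        offenders = dupes[dupes > 1].index.tolist()
        if offenders:
            raise ManifestIntegrityError(f"duplicate records: {offenders}")
    return {
        level: df[df["level"] == level].reset_index(drop=True) for level in LEVELS
    }


def write_manifests(
    manifests: dict[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for level, df in manifests.items():
        p = out / f"{level}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
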