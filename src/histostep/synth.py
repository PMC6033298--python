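"""Synthetic H&E-like patch generator with per-patch ground truth.

Patches are rendered with a Beer-Lambert forward model: each stain ``s``
contributes optical density ``A_s * b_{s,c}`` in RGB channel ``c``, so the
transmitted intensity is ``I_c = 10 ** (-sum_s A_s * b_{s,c})``.  Nuclei are
filled ellipses carrying hematoxylin; the background carries eosin.  The
default absorption basis is the exact inverse of the default deconvolution
matrix, which makes rendering and unmixing adjoint and round trips exact.

Three populations are supported:

* single patches from explicit nucleus specs (:func:`render_patch`),
* a two-cluster "cell-wise" population (few/large vs many/small nuclei),
* a three-class "tissue-wise" population (background / epithelium / stroma),
  where epithelium nuclei sit on parallel bands and stroma nuclei are
  scattered uniformly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .stains import DEFAULT_DECONVOLUTION_MATRIX, StainConfigError

__all__ = [
    "StainBasis",
    "NucleusSpec",
    "SyntheticPatchTruth",
    "ClusterParams",
    "render_patch",
    "generate_cellwise_population",
    "generate_tissuewise_population",
    "write_population",
]


@dataclass(frozen=True)
class StainBasis:
    """Per-stain RGB absorption factors; row ``s`` is stain ``s``'s OD vector."""

    absorption_matrix: np.ndarray = field(
        default_factory=lambda: np.linalg.inv(DEFAULT_DECONVOLUTION_MATRIX).T
    )

    def __post_init__(self) -> None:
        mat = np.asarray(self.absorption_matrix, dtype=float)
        if mat.shape != (3, 3):
            raise StainConfigError(f"absorption matrix must be 3x3, got {mat.shape}")
        if not np.isfinite(mat).all():
            raise StainConfigError("absorption matrix contains non-finite entries")
        if abs(np.linalg.det(mat)) < 1e-12:
            raise StainConfigError("absorption matrix is singular")
        object.__setattr__(self, "absorption_matrix", mat)


@dataclass(frozen=True)
class NucleusSpec:
    """A single elliptical nucleus: center (row, col), semi-axes, orientation."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0
    hematoxylin_amount: float = 0.7

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if self.hematoxylin_amount < 0:
            raise ValueError("hematoxylin_amount must be nonnegative")


@dataclass
class SyntheticPatchTruth:
    """A rendered patch plus everything a downstream stage could be tested on."""

    patch: np.ndarray
    nuclei: list[NucleusSpec]
    true_count: int
    true_total_area: int
    tissue_class: str = "none"
    cluster_id: int | None = None


def _ellipse_mask(shape: tuple[int, int], spec: NucleusSpec) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    dy = rows - spec.center[0]
    dx = cols - spec.center[1]
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a, b = spec.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_patch(
    nuclei: Sequence[NucleusSpec],
    basis: StainBasis | None = None,
    background_eosin: float = 0.25,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
) -> SyntheticPatchTruth:
    """Render nuclei over an eosin background with the Beer-Lambert model.

    Overlapping nuclei add their hematoxylin concentrations, but overlapping
    pixels are counted once in ``true_total_area`` (what a segmenter can see).
    Gaussian intensity noise of standard deviation ``noise_sd`` is added
    after rendering and the result clipped to [0, 1].
    """
    if basis is None:
        basis = StainBasis()
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if min(shape) <= 0:
        raise ValueError("patch shape must be positive")

    h_map = np.zeros(shape)
    union = np.zeros(shape, dtype=bool)
    for spec in nuclei:
        if not (0 <= spec.center[0] < shape[0] and 0 <= spec.center[1] < shape[1]):
            raise ValueError(f"nucleus center {spec.center} outside patch bounds {shape}")
        mask = _ellipse_mask(shape, spec)
        h_map += spec.hematoxylin_amount * mask
        union |= mask

    conc = np.stack(
        [h_map, np.full(shape, float(background_eosin)), np.zeros(shape)], axis=-1
    )
    od = conc @ basis.absorption_matrix
    patch = 10.0 ** (-od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        patch = patch + rng.normal(0.0, noise_sd, size=patch.shape)
    patch = np.clip(patch, 0.0, 1.0)

    return SyntheticPatchTruth(
        patch=patch,
        nuclei=list(nuclei),
        true_count=len(nuclei),
        true_total_area=int(union.sum()),
    )


@dataclass(frozen=True)
class ClusterParams:
    """Sampling distribution for one cell-wise cluster."""

    count_mean: float
    radius_range: tuple[float, float]
    hematoxylin_range: tuple[float, float] = (0.5, 0.9)
    eccentricity_range: tuple[float, float] = (0.7, 1.0)


#: Cluster 1: fewer, larger nuclei.  Cluster 2: more, smaller nuclei.
DEFAULT_CLUSTER1 = ClusterParams(count_mean=8.0, radius_range=(10.0, 16.0))
DEFAULT_CLUSTER2 = ClusterParams(count_mean=40.0, radius_range=(3.0, 6.0))


def _sample_nuclei(
    rng: np.random.Generator,
    n: int,
    params: ClusterParams,
    shape: tuple[int, int],
    margin: float,
) -> list[NucleusSpec]:
    nuclei = []
    for _ in range(n):
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        a = rng.uniform(*params.radius_range)
        b = a * rng.uniform(*params.eccentricity_range)
        nuclei.append(
            NucleusSpec(
                center=(cy, cx),
                semi_axes=(a, b),
                orientation=rng.uniform(0, np.pi),
                hematoxylin_amount=rng.uniform(*params.hematoxylin_range),
            )
        )
    return nuclei


def generate_cellwise_population(
    n_per_cluster: int,
    cluster1_params: ClusterParams = DEFAULT_CLUSTER1,
    cluster2_params: ClusterParams = DEFAULT_CLUSTER2,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    background_eosin_range: tuple[float, float] = (0.2, 0.35),
) -> list[SyntheticPatchTruth]:
    """Generate ``2 * n_per_cluster`` patches with cluster ground truth.

    Cluster 1 patches carry fewer, larger nuclei than cluster 2 patches; the
    background eosin level jitters between patches to emulate global stain
    intensity variation.
    """
    if n_per_cluster < 0:
        raise ValueError("n_per_cluster must be nonnegative")
    rng = np.random.default_rng(seed)
    patches: list[SyntheticPatchTruth] = []
    for cluster_id, params in ((1, cluster1_params), (2, cluster2_params)):
        margin = params.radius_range[1]
        for _ in range(n_per_cluster):
            count = max(1, int(rng.poisson(params.count_mean)))
            nuclei = _sample_nuclei(rng, count, params, shape, margin)
            truth = render_patch(
                nuclei,
                background_eosin=rng.uniform(*background_eosin_range),
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                shape=shape,
            )
            truth.cluster_id = cluster_id
            patches.append(truth)
    return patches


def sample_nonoverlapping_nuclei(
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[float, float],
    shape: tuple[int, int],
    spacing: float = 2.0,
    max_tries: int = 5000,
) -> list[NucleusSpec]:
    """Rejection-sample nuclei whose bounding circles stay disjoint.

    Useful for building non-touching fixtures with exactly recoverable
    counts; gives up (returning fewer nuclei) after ``max_tries`` draws.
    """
    nuclei: list[NucleusSpec] = []
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(nuclei) < n and tries < max_tries:
        tries += 1
        a = rng.uniform(*radius_range)
        b = a * rng.uniform(0.7, 1.0)
        margin = a + spacing
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        if any(np.hypot(cy - oy, cx - ox) < a + r + spacing for oy, ox, r in placed):
            continue
        placed.append((cy, cx, a))
        nuclei.append(
            NucleusSpec(
                center=(cy, cx),
                semi_axes=(a, b),
                orientation=rng.uniform(0, np.pi),
                hematoxylin_amount=rng.uniform(0.5, 0.9),
            )
        )
    return nuclei


def generate_tissuewise_population(
    n_per_class: int,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
) -> list[SyntheticPatchTruth]:
    """Generate background / epithelium / stroma patches, ``n_per_class`` each.

    Background patches are near-blank (faint eosin, no nuclei).  Epithelium
    nuclei line up on two parallel horizontal bands with small vertical
    jitter; stroma nuclei are scattered uniformly and sparsely.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be nonnegative")
    rng = np.random.default_rng(seed)
    height, width = shape
    radius = max(2.0, min(shape) / 24.0)
    params = ClusterParams(count_mean=0, radius_range=(0.8 * radius, 1.2 * radius))
    patches: list[SyntheticPatchTruth] = []

    for _ in range(n_per_class):
        truth = render_patch(
            [],
            background_eosin=rng.uniform(0.02, 0.06),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            shape=shape,
        )
        truth.tissue_class = "background"
        patches.append(truth)

    for _ in range(n_per_class):
        nuclei = []
        band_rows = (0.35 * height, 0.65 * height)
        per_band = max(3, int(width / (3.0 * radius)))
        for band in band_rows:
            for _ in range(per_band):
                cy = float(np.clip(band + rng.normal(0, 0.35 * radius), 1, height - 2))
                cx = rng.uniform(1.2 * radius, width - 1.2 * radius)
                a = rng.uniform(*params.radius_range)
                nuclei.append(
                    NucleusSpec(
                        center=(cy, cx),
                        semi_axes=(a, a * rng.uniform(0.7, 1.0)),
                        orientation=rng.uniform(0, np.pi),
                        hematoxylin_amount=rng.uniform(0.5, 0.9),
                    )
                )
        truth = render_patch(
            nuclei,
            background_eosin=rng.uniform(0.2, 0.35),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            shape=shape,
        )
        truth.tissue_class = "epithelium"
        patches.append(truth)

    for _ in range(n_per_class):
        count = max(2, int(rng.poisson(0.6 * 2 * max(3, int(width / (3.0 * radius))))))
        nuclei = _sample_nuclei(rng, count, params, shape, 1.2 * radius)
        truth = render_patch(
            nuclei,
            background_eosin=rng.uniform(0.2, 0.35),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            shape=shape,
        )
        truth.tissue_class = "stroma"
        patches.append(truth)

    return patches


def write_population(
    patches: Sequence[SyntheticPatchTruth], out_dir: str | Path
) -> Path:
    """Write patches as 8-bit PNGs plus a TSV manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["path", "tissue_class", "cluster_id", "true_count", "true_total_area"])
        for i, truth in enumerate(patches):
            name = f"patch_{i:05d}.png"
            img = np.clip(np.rint(truth.patch * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(img).save(out / name)
            writer.writerow(
                [
                    name,
                    truth.tissue_class,
                    "" if truth.cluster_id is None else truth.cluster_id,
                    truth.true_count,
                    truth.true_total_area,
                ]
            )
    return manifest


def read_patch(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image file into a float patch in [0, 1]."""
    img = np.asarray(Image.open(path).convert("RGB"), dtype=float)
    return img / 255.0
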