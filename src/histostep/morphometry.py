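"""Nuclei morphometry: local thresholding, watershed splitting, contour tracing.

The pipeline binarizes the normalized hematoxylin concentration map with the
Phansalkar adaptive local threshold

    T = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1)),

splits touching nuclei by watershed on the negated distance transform, traces
one outer boundary per nucleus by Moore-neighbor border following, and emits
the per-patch feature vector (total area, nucleus count).

Polarity note: nuclei are *bright* in the concentration map, so foreground is
``value > T`` by default (the original formulation targets dark nuclei in
bright images; flip ``bright_nuclei`` to recover that behavior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from . import stains

__all__ = [
    "PhansalkarParams",
    "WatershedParams",
    "NucleusContour",
    "NucleiMorphometry",
    "phansalkar_threshold",
    "binarize",
    "split_touching",
    "trace_contours",
    "measure",
]


@dataclass(frozen=True)
class PhansalkarParams:
    """Constants of the adaptive local threshold; defaults are the recommended values."""

    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    window_radius: int = 15
    bright_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.r == 0:
            raise ValueError("r must be nonzero")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass(frozen=True)
class WatershedParams:
    min_seed_separation: int = 7
    min_area: int = 15


def phansalkar_threshold(
    mean: np.ndarray | float, sd: np.ndarray | float, params: PhansalkarParams | None = None
) -> np.ndarray | float:
    """Threshold ``T = mu * (1 + p*exp(-q*mu) + k*(sigma/r - 1))``, elementwise."""
    if params is None:
        params = PhansalkarParams()
    mu = np.asarray(mean, dtype=float)
    sigma = np.asarray(sd, dtype=float)
    t = mu * (1.0 + params.p * np.exp(-params.q * mu) + params.k * (sigma / params.r - 1.0))
    return t if t.ndim else float(t)


def _disk_kernel(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2 <= radius**2).astype(float)


def local_mean_sd(image: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population SD over a circular window, edge-replicated."""
    kernel = _disk_kernel(radius)
    kernel /= kernel.sum()
    img = np.asarray(image, dtype=float)
    mean = ndi.correlate(img, kernel, mode="nearest")
    mean_sq = ndi.correlate(img * img, kernel, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def binarize(h_map: np.ndarray, params: PhansalkarParams | None = None) -> np.ndarray:
    """Binarize a normalized hematoxylin map with the local threshold.

    Foreground is ``value > T`` (bright nuclei) computed over a circular
    window of ``window_radius`` pixels with edge replication at borders.
    """
    if params is None:
        params = PhansalkarParams()
    img = np.asarray(h_map, dtype=float)
    if img.ndim != 2:
        raise ValueError("h_map must be 2-D")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("h_map values must lie in [0, 1]")
    if 2 * params.window_radius + 1 > min(img.shape):
        raise ValueError("window_radius larger than image")
    mean, sd = local_mean_sd(img, params.window_radius)
    t = phansalkar_threshold(mean, sd, params)
    return img > t if params.bright_nuclei else img < t


def split_touching(
    mask: np.ndarray, params: WatershedParams | None = None
) -> np.ndarray:
    """Split conjoined nuclei by watershed on the negated distance transform.

    Seeds are local maxima of the distance map separated by at least
    ``min_seed_separation`` pixels; connected plateau maxima collapse to one
    seed.  Returns an int label image (background 0).
    """
    if params is None:
        params = WatershedParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        dist,
        min_distance=params.min_seed_separation,
        labels=mask,
        exclude_border=False,
    )
    peaks = np.zeros(mask.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, n_markers = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n_markers == 0:  # degenerate: fall back to connected components
        labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        return labels.astype(np.int32)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


@dataclass(frozen=True)
class NucleusContour:
    """Closed outer boundary of one nucleus plus its filled-pixel area."""

    boundary: np.ndarray  # (n, 2) ordered (row, col) pixel coordinates
    area: int
    label: int


@dataclass(frozen=True)
class NucleiMorphometry:
    contours: list[NucleusContour]
    total_area: int
    count: int


# Moore neighborhood in clockwise order starting east.
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor border following of the outer boundary of one region.

    ``mask`` must contain a single 8-connected region.  Returns ordered
    (row, col) boundary coordinates; closed in the sense that consecutive
    points (and last-to-first) are Moore neighbors.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost pixel (row-major scan)

    def next_boundary_pixel(current: tuple[int, int], backtrack: int):
        for step in range(8):
            idx = (backtrack + 1 + step) % 8
            dy, dx = _MOORE[idx]
            ny, nx = current[0] + dy, current[1] + dx
            if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1] and mask[ny, nx]:
                return (ny, nx), (idx + 4) % 8
        return None, backtrack

    boundary = [start]
    # Entered from the west (row-major scan direction): backtrack points west.
    first_move = next_boundary_pixel(start, 4)
    if first_move[0] is None:  # isolated pixel
        return np.array(boundary, dtype=int)
    current, backtrack = first_move
    boundary.append(current)
    # Jacob's criterion: stop when the initial (start -> second) edge recurs.
    for _ in range(4 * mask.size):
        nxt, backtrack = next_boundary_pixel(current, backtrack)
        if current == start and nxt == first_move[0]:
            boundary.pop()  # drop the duplicated start pixel
            return np.array(boundary, dtype=int)
        boundary.append(nxt)
        current = nxt
    raise RuntimeError("contour tracing failed to terminate")


def trace_contours(labels: np.ndarray) -> list[NucleusContour]:
    """One outer contour per label by border following; holes are ignored.

    Area is the label's filled pixel count (not a polygonal boundary area).
    """
    labels = np.asarray(labels)
    out: list[NucleusContour] = []
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for lab in ids:
        mask = labels == lab
        boundary = _trace_boundary(mask)
        out.append(NucleusContour(boundary=boundary, area=int(mask.sum()), label=int(lab)))
    return out


def measure(
    patch: np.ndarray,
    threshold_params: PhansalkarParams | None = None,
    watershed_params: WatershedParams | None = None,
    deconvolution_matrix: np.ndarray | None = None,
) -> NucleiMorphometry:
    """Full pipeline: deconvolve, binarize, split, trace; returns (area, count).

    Labeled regions smaller than ``watershed_params.min_area`` are dropped as
    specks before contour tracing.  Deterministic for fixed inputs.
    """
    if watershed_params is None:
        watershed_params = WatershedParams()
    h = stains.normalized_hematoxylin(patch, deconvolution_matrix)
    if h.max() == 0:
        return NucleiMorphometry(contours=[], total_area=0, count=0)
    mask = binarize(h, threshold_params)
    labels = split_touching(mask, watershed_params)
    if watershed_params.min_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < watershed_params.min_area)
        labels[np.isin(labels, small)] = 0
    contours = trace_contours(labels)
    total_area = int(sum(c.area for c in contours))
    return NucleiMorphometry(contours=contours, total_area=total_area, count=len(contours))
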