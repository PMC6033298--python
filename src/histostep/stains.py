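"""Optical-density conversion and color deconvolution of H&E(-DAB) patches.

Intensities live in [0, 1] with unit incident intensity, so the optical
density of channel ``c`` is ``OD_c = -log10(I_c)``.  A fixed 3x3
deconvolution matrix maps the per-pixel OD vector to (hematoxylin, eosin,
DAB) concentrations.  The default matrix is the classic H&E-DAB unmixing
matrix; it can be overridden per call or via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Intensity floor applied before the log so saturated black pixels stay finite.
INTENSITY_EPS = 1e-6

#: Default H&E-DAB deconvolution matrix (rows map OD_RGB -> H, E, DAB).
DEFAULT_DECONVOLUTION_MATRIX = np.array(
    [
        [1.88, -0.07, -0.60],
        [-1.02, 1.13, -0.48],
        [-0.55, -0.13, 1.57],
    ]
)


class StainConfigError(ValueError):
    """Raised for unusable stain matrices/bases."""


def validate_patch(pixels: np.ndarray) -> np.ndarray:
    """Validate an RGB patch: H x W x 3 float array with values in [0, 1]."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 patch, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("patch contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("patch intensities must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class DeconvolutionMatrix:
    """3x3 matrix taking OD vectors in RGB space to stain concentrations."""

    entries: np.ndarray = field(
        default_factory=lambda: DEFAULT_DECONVOLUTION_MATRIX.copy()
    )

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (3, 3):
            raise StainConfigError(f"deconvolution matrix must be 3x3, got {entries.shape}")
        if not np.isfinite(entries).all():
            raise StainConfigError("deconvolution matrix contains non-finite entries")
        object.__setattr__(self, "entries", entries)


@dataclass(frozen=True)
class StainMaps:
    """Per-pixel concentration maps for the three unmixed stains."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    dab: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


def optical_density(patch: np.ndarray) -> np.ndarray:
    """Convert an RGB patch to optical density, ``OD_c = -log10(I_c / I_0)``.

    ``I_0`` is 1; intensities are floored at ``INTENSITY_EPS`` before the log
    so OD is capped at 6 for black pixels.

    Parameters
    ----------
    patch : (H, W, 3) array with values in [0, 1].

    Returns
    -------
    (H, W, 3) nonnegative array of optical densities.
    """
    arr = validate_patch(patch)
    return -np.log10(np.maximum(arr, INTENSITY_EPS))


def separate_stains(
    patch: np.ndarray, matrix: DeconvolutionMatrix | np.ndarray | None = None
) -> StainMaps:
    """Unmix an RGB patch into hematoxylin / eosin / DAB concentration maps.

    Per pixel, ``(H, E, DAB) = D @ (OD_R, OD_G, OD_B)``.  Raw maps are
    returned without clamping; nonnegativity is a downstream concern.
    """
    if matrix is None:
        matrix = DeconvolutionMatrix()
    elif not isinstance(matrix, DeconvolutionMatrix):
        matrix = DeconvolutionMatrix(np.asarray(matrix))
    od = optical_density(patch)
    conc = od @ matrix.entries.T
    return StainMaps(
        hematoxylin=conc[..., 0], eosin=conc[..., 1], dab=conc[..., 2]
    )


def normalized_hematoxylin(
    patch: np.ndarray, matrix: DeconvolutionMatrix | np.ndarray | None = None
) -> np.ndarray:
    """Hematoxylin map clipped to >= 0 and scaled to [0, 1] by its maximum.

    An all-nonpositive map comes back all-zero.  This is the map handed to
    the local thresholding stage, which presumes a normalized image.
    """
    h = np.maximum(separate_stains(patch, matrix).hematoxylin, 0.0)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h
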