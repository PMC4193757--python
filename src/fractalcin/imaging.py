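"""Tile I/O and nuclei segmentation for H&E histology tiles.

Haematoxylin stains nuclei blue-purple while eosin renders cytoplasm and
stroma pink.  A pixel is therefore called nuclear when the blue channel's
*relative share* of the RGB sum exceeds a threshold: pink backgrounds sit
near 33 % blue share, haematoxylin nuclei well above 40 %.  The default
threshold of 41 % separates the two for typical H&E palettes.

Segmentation output is a boolean mask (nuclei = True) which is then cleaned
by removing small isolated components ("blobs") that are staining debris
rather than nuclei.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import imageio.v3 as iio
import numpy as np
from skimage.morphology import remove_small_objects

__all__ = [
    "RgbTile",
    "NucleiMask",
    "read_tile",
    "write_mask",
    "read_mask",
    "segment_relative_rgb",
    "remove_blobs",
]

#: mapping from pixel-neighbourhood convention to scikit-image connectivity rank
_CONNECTIVITY_RANK = {4: 1, 8: 2}


class FormatError(ValueError):
    """Raised when an input image violates the 8-bit RGB contract."""


@dataclass
class RgbTile:
    """One 8-bit RGB region-of-interest tile (H x W x 3)."""

    pixels: np.ndarray
    id: str
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"tile {self.id!r}: expected HxWx3 RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"tile {self.id!r}: empty image")
        if px.min() < 0 or px.max() > 255:
            raise FormatError(f"tile {self.id!r}: intensities outside [0, 255]")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class NucleiMask:
    """Binary nuclei mask (True = nucleus foreground) with provenance."""

    pixels: np.ndarray
    id: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask {self.id!r}: expected 2-D array, got {px.ndim}-D")
        self.pixels = px.astype(bool, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def read_tile(path: str | os.PathLike, id: str | None = None) -> RgbTile:
    """Read an 8-bit RGB tile from a TIFF or PNG file.

    Intensities are preserved bit-exactly.  Greyscale or non-8-bit inputs
    are rejected with :class:`FormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise FormatError(f"{path}: single-channel greyscale image, expected RGB")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3 colour channels, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit channels, got dtype {arr.dtype}")
    tile_id = id if id is not None else os.path.splitext(os.path.basename(path))[0]
    return RgbTile(pixels=arr, id=tile_id, source_path=path)


def write_mask(mask: NucleiMask, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF (foreground = 255)."""
    iio.imwrite(os.fspath(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path: str | os.PathLike, id: str | None = None) -> NucleiMask:
    """Read a mask written by :func:`write_mask` (any non-zero pixel = foreground)."""
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3:  # tolerate RGB-saved masks
        arr = arr[..., 0]
    mask_id = id if id is not None else os.path.splitext(os.path.basename(path))[0]
    return NucleiMask(pixels=arr > 0, id=mask_id, provenance={"source": os.fspath(path)})


def segment_relative_rgb(tile: RgbTile, ratio: int = 41) -> NucleiMask:
    """Threshold on the blue channel's relative share of the RGB sum.

    A pixel is foreground iff ``100 * B / (R + G + B) >= ratio``.  The
    comparison is evaluated in integer arithmetic (``100*B >= ratio*(R+G+B)``)
    so the threshold is exact, with the tie going to foreground.  Pure black
    pixels (R = G = B = 0), where the share is undefined, are background:
    black is not nuclear stain.

    Parameters
    ----------
    ratio:
        Blue-share threshold in percent, ``0 < ratio <= 100``.  41 separates
        haematoxylin-blue nuclei (share > 0.5) from eosin-pink background
        (share near 1/3).
    """
    if not 0 < ratio <= 100:
        raise ValueError(f"ratio must be in (0, 100], got {ratio}")
    px = tile.pixels.astype(np.int64)
    rgb_sum = px.sum(axis=2)
    fg = (100 * px[:, :, 2] >= ratio * rgb_sum) & (rgb_sum > 0)
    return NucleiMask(
        pixels=fg,
        id=tile.id,
        provenance={"segmentation": "relative_rgb", "ratio": int(ratio)},
    )


def remove_blobs(mask: NucleiMask, min_area: int = 2, connectivity: int = 8) -> NucleiMask:
    """Delete foreground components smaller than ``min_area`` pixels.

    With the defaults (``min_area=2``, 8-connectivity) only isolated single
    pixels — components with no adjacent foreground pixel — are erased,
    which is the most literal cleanup of thresholding speckle.  The
    operation is idempotent.
    """
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    # components with area < min_area are removed, i.e. area <= min_area - 1
    cleaned = remove_small_objects(
        mask.pixels.copy(),
        max_size=min_area - 1,
        connectivity=_CONNECTIVITY_RANK[connectivity],
    )
    provenance = dict(mask.provenance)
    provenance.update({"min_blob_area": int(min_area), "connectivity": int(connectivity)})
    return NucleiMask(pixels=cleaned, id=mask.id, provenance=provenance)


def segment_tile(
    tile: RgbTile,
    ratio: int = 41,
    min_blob_area: int = 2,
    connectivity: int = 8,
) -> NucleiMask:
    """Full segmentation: relative-RGB threshold followed by blob removal."""
    return remove_blobs(
        segment_relative_rgb(tile, ratio=ratio),
        min_area=min_blob_area,
        connectivity=connectivity,
    )
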