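"""Image reading, writing, and grayscale conversion.

Micrographs are handled as 8-bit-per-channel rasters: an RGB image is an
H x W x 3 array of integers in [0, 255] and a grayscale image is the map
f : D -> [0, 255] over the pixel grid D that the thresholding and feature
operators consume.  Geometry is row-major with the origin at the top-left
corner and 0-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .errors import ImageIOError, ValidationError

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "GRAY_METHODS",
    "read_image",
    "to_grayscale",
    "write_image",
    "write_mask",
    "read_mask",
]

#: BT.601 luma weights for the ``luminance`` conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

GRAY_METHODS = ("luminance", "red", "green", "blue", "mean")


@dataclass(frozen=True)
class RgbImage:
    """8-bit RGB raster. ``pixels`` is H x W x 3 uint8."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"RGB pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have H, W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel raster; real-valued entries permitted after filtering."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"grayscale pixels must be HxW, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have H, W >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("grayscale image contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def geometry(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """H x W mask of {0, 1}; ``area`` counts the 1-pixels."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"mask must be HxW, got shape {px.shape}")
        object.__setattr__(self, "pixels", (px != 0).astype(np.uint8))

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def geometry(self) -> tuple[int, int]:
        return self.pixels.shape

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels & other.pixels)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels | other.pixels)

    def complement(self) -> "BinaryMask":
        return BinaryMask(1 - self.pixels)


def read_image(path) -> RgbImage:
    """Read a PNG/TIFF/JPEG file as a canonical 8-bit RGB image.

    16-bit inputs are rescaled by integer division (257), mapping
    [0, 65535] onto [0, 255] with both endpoints preserved; single-channel
    inputs are replicated to three channels; an alpha channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (UnidentifiedImageError, ValueError, OSError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)  # 65535 // 257 == 255
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer):
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        else:
            raise ImageIOError(f"unsupported pixel dtype {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ImageIOError(f"unsupported image layout {arr.shape} in {path}")
    return RgbImage(arr)


def write_image(img: RgbImage, path) -> None:
    """Write an RGB image losslessly (PNG or TIFF; JPEG is refused)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        raise ValidationError("refusing lossy JPEG output; use PNG or TIFF")
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), img.pixels)
    else:
        Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit PNG with 0/255 encoding."""
    Image.fromarray(mask.pixels * 255, mode="L").save(Path(path), format="PNG")


def read_mask(path) -> BinaryMask:
    """Read a 0/255-encoded PNG mask back to {0, 1}."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask(arr >= 128)


def to_grayscale(img: RgbImage, method: str = "luminance") -> GrayImage:
    """Convert RGB to grayscale.

    ``luminance`` uses BT.601 weights 0.299 R + 0.587 G + 0.114 B rounded
    half-up; ``red``/``green``/``blue`` select a single channel (the red
    channel gives the best contrast for blue-stained fungal structures,
    which absorb red light strongly); ``mean`` averages the channels.
    """
    if method not in GRAY_METHODS:
        raise ValidationError(
            f"unknown grayscale method {method!r}; choose one of {GRAY_METHODS}"
        )
    px = img.pixels.astype(np.float64)
    if method == "luminance":
        w = LUMA_WEIGHTS
        gray = w[0] * px[:, :, 0] + w[1] * px[:, :, 1] + w[2] * px[:, :, 2]
        gray = np.floor(gray + 0.5)  # round half-up
    elif method == "mean":
        gray = px.mean(axis=2)
    else:
        gray = px[:, :, ("red", "green", "blue").index(method)]
    return GrayImage(gray)
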