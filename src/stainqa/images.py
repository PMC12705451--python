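"""Image container and file I/O.

All images are stored as float64 grids in [0, 1], row-major, origin at the
top-left, 0-based indices.  Single-channel (autofluorescence-like) images have
shape ``(H, W)``; colour (stain-like) images have shape ``(H, W, 3)``.
Conversion to integer bit depths happens only at file boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


class Domain(str, enum.Enum):
    """Which imaging modality a field of view belongs to."""

    AF = "AF"          # label-free autofluorescence (1 channel)
    STAIN = "STAIN"    # histochemical-stain appearance, H&E-like (3 channels)


@dataclass
class ImageFOV:
    """A single field of view with a domain tag.

    Parameters
    ----------
    pixels
        Float array in [0, 1]; ``(H, W)`` for AF, ``(H, W, 3)`` for STAIN.
    domain
        Modality tag (:class:`Domain`).
    meta
        Free-form provenance (file path, model id, degradation label, ...).
    """

    pixels: np.ndarray
    domain: Domain
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.domain = Domain(self.domain)
        if self.domain is Domain.AF and self.pixels.ndim != 2:
            raise ValueError(f"AF image must be 2-D, got shape {self.pixels.shape}")
        if self.domain is Domain.STAIN and (
            self.pixels.ndim != 3 or self.pixels.shape[2] != 3
        ):
            raise ValueError(
                f"STAIN image must be (H, W, 3), got shape {self.pixels.shape}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def clipped(self) -> "ImageFOV":
        return ImageFOV(np.clip(self.pixels, 0.0, 1.0), self.domain, dict(self.meta))


def _depth_info(depth: int) -> tuple[float, np.dtype]:
    if depth == 8:
        return 255.0, np.dtype(np.uint8)
    if depth == 16:
        return 65535.0, np.dtype(np.uint16)
    raise ValueError(f"unsupported bit depth: {depth}")


def read_image(path: str | Path, domain: Domain | str | None = None) -> ImageFOV:
    """Read a PNG or TIFF file into an :class:`ImageFOV` normalized to [0, 1].

    The domain tag is taken from ``domain`` if given, otherwise inferred from
    the filename convention ``{id}_{domain}.{ext}``, otherwise from the channel
    count (1 channel -> AF, 3 channels -> STAIN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")
    pixels = arr.astype(np.float64) / scale

    if domain is None:
        stem = path.stem.rsplit("_", 1)
        if len(stem) == 2 and stem[1].upper() in Domain.__members__:
            domain = Domain[stem[1].upper()]
        else:
            domain = Domain.AF if pixels.ndim == 2 else Domain.STAIN
    return ImageFOV(pixels, Domain(domain), {"path": str(path)})


def write_image(path: str | Path, fov: ImageFOV, depth: int = 8) -> Path:
    """Write an :class:`ImageFOV` as an 8- or 16-bit PNG/TIFF file.

    Values are clipped to [0, 1] and rounded to the nearest representable
    level, so ``read_image(write_image(...))`` round-trips bit-identically for
    images already on the quantized grid.
    """
    path = Path(path)
    scale, dtype = _depth_info(depth)
    arr = np.clip(fov.pixels, 0.0, 1.0)
    quant = np.rint(arr * scale).astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    elif suffix == ".png":
        if depth == 16 and quant.ndim == 3:
            raise ValueError("16-bit colour PNG not supported; use TIFF")
        Image.fromarray(quant).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def as_chw(pixels: np.ndarray) -> np.ndarray:
    """View (H, W) or (H, W, C) pixels as channels-first (C, H, W)."""
    if pixels.ndim == 2:
        return pixels[None, :, :]
    return np.moveaxis(pixels, -1, 0)


def from_chw(arr: np.ndarray) -> np.ndarray:
    """Inverse of :func:`as_chw`; squeezes single channels back to (H, W)."""
    if arr.shape[0] == 1:
        return arr[0]
    return np.moveaxis(arr, 0, -1)
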