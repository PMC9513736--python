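"""En face image container and raster I/O.

The analysis operates on 2-D en face choriocapillaris (CC) rasters: an OCTA
angiogram, the matching structural slab projection, and binary lesion masks.
Physical scale is carried as a per-pixel pitch in micrometers (a 3 x 3 mm
scan at 500 x 500 px has a 6.0 um pitch), so every downstream area is
reported in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["EnFaceImage", "GeometryError", "read_image", "write_image", "read_mask", "write_mask"]


class GeometryError(ValueError):
    """Raised when raster grids, margins, or ring placement are inconsistent."""


VALID_MODALITIES = ("angiogram", "structural", "compensated")


@dataclass(frozen=True)
class EnFaceImage:
    """A 2-D en face raster with physical pixel pitch.

    Parameters
    ----------
    pixels
        Nonnegative intensities, shape (rows, cols). Stored as float64;
        values must lie within the declared bit depth.
    pixel_pitch_um
        Physical size of one pixel, in micrometers.
    bit_depth
        8 or 16; defines the intensity range [0, 2**bit_depth - 1].
    modality
        One of ``angiogram``, ``structural``, ``compensated``.
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    bit_depth: int = 8
    modality: str = "angiogram"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise GeometryError(f"en face image must be 2-D, got shape {px.shape}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}")
        if px.size and (px.min() < 0 or px.max() > self.intensity_max(self.bit_depth)):
            raise ValueError("intensities outside declared bit depth")
        object.__setattr__(self, "pixels", px)

    @staticmethod
    def intensity_max(bit_depth: int) -> int:
        return (1 << bit_depth) - 1

    @property
    def i_max(self) -> int:
        return self.intensity_max(self.bit_depth)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the scan in millimeters."""
        r, c = self.shape
        return (r * self.pixel_pitch_um / 1000.0, c * self.pixel_pitch_um / 1000.0)

    def with_pixels(self, pixels: np.ndarray, modality: str | None = None) -> "EnFaceImage":
        return replace(self, pixels=pixels, modality=modality or self.modality)

    def normalized(self) -> np.ndarray:
        """Intensities mapped to [0, 1] by the bit-depth maximum."""
        return self.pixels / float(self.i_max)

    def same_grid(self, other: "EnFaceImage") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_pitch_um, other.pixel_pitch_um
        )


def _quantize(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    hi = EnFaceImage.intensity_max(bit_depth)
    arr = np.clip(np.rint(pixels), 0, hi)
    return arr.astype(np.uint8 if bit_depth == 8 else np.uint16)


def write_image(path: str | Path, image: EnFaceImage) -> None:
    """Write an en face image as grayscale TIFF or PNG (by extension)."""
    path = Path(path)
    arr = _quantize(image.pixels, image.bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(
    path: str | Path,
    pixel_pitch_um: float,
    modality: str = "angiogram",
) -> EnFaceImage:
    """Read a grayscale TIFF/PNG as an :class:`EnFaceImage`.

    Bit depth is inferred from the stored dtype (uint8 -> 8, uint16 -> 16).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse any accidental RGB to luminance-ish first channel
        arr = arr[..., 0]
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return EnFaceImage(arr.astype(np.float64), pixel_pitch_um, bit_depth, modality)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit 0/255 TIFF or PNG."""
    path = Path(path)
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 (or 0/1) raster as a boolean mask."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
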