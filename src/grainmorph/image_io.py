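"""Image and metadata I/O for micrograph analysis.

Images are treated as scalar height fields: grayscale intensity is read,
normalized by bit depth to ``[0, 1]``, and tagged with a pixel scale in
micrometres per pixel supplied by the caller (SEM vendor TIFF tags are not
standardized, so the scale is never parsed from headers).

Binary maps use the convention white = solid phase (starch + protein),
matching the backscatter appearance of endosperm in SEM, with black = voids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "HeightField",
    "BinaryImage",
    "read_image",
    "write_image",
    "binarize",
]


@dataclass(frozen=True)
class HeightField:
    """2-D scalar field (intensity treated as height) with a pixel scale.

    Parameters
    ----------
    values : ndarray of float, shape (rows, cols)
        Height / intensity values. Must be finite.
    pixel_scale : float
        Physical size of one pixel in µm/px. Must be positive.
    """

    values: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive (µm/px)")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryImage:
    """Binary segmentation mask; white (True) is the solid phase.

    Parameters
    ----------
    mask : ndarray of bool, shape (rows, cols)
    pixel_scale : float
        µm/px, positive.
    """

    mask: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean array")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive (µm/px)")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path, pixel_scale: float) -> HeightField:
    """Read a grayscale TIFF/PNG as a height field normalized to [0, 1].

    Integer images are divided by the maximum value of their bit depth
    (255 for 8-bit, 65535 for 16-bit); float images are taken as-is.
    RGB input is converted to luminance with a warning.

    Parameters
    ----------
    path : str or Path
    pixel_scale : float
        µm/px; user-supplied, never parsed from vendor headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        warnings.warn(f"{path.name}: RGB input converted to luminance")
        arr = arr.astype(float) @ _LUMA
        if arr.max() > 1:
            arr = arr / 255.0
        return HeightField(arr, pixel_scale)
    if np.issubdtype(arr.dtype, np.integer):
        quantum = float(np.iinfo(arr.dtype).max)
        return HeightField(arr.astype(float) / quantum, pixel_scale)
    return HeightField(arr.astype(float), pixel_scale)


def write_image(path: str | Path, field: HeightField, bit_depth: int = 16) -> None:
    """Write a height field as an 8- or 16-bit grayscale image.

    Values are clipped to [0, 1] then quantized; a read after write differs
    from the original by at most one bit-depth quantum.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    quantum = 2**bit_depth - 1
    clipped = np.clip(field.values, 0.0, 1.0)
    quantized = np.round(clipped * quantum)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), quantized.astype(dtype))


def binarize(
    field: HeightField,
    method: str = "otsu",
    manual_threshold: float | None = None,
    bright_is_solid: bool = True,
) -> BinaryImage:
    """Threshold a height field into a solid/void binary map.

    Parameters
    ----------
    field : HeightField
    method : {"otsu", "manual"}
        "otsu" selects the threshold by Otsu's between-class variance
        criterion; "manual" requires ``manual_threshold``.
    manual_threshold : float, optional
        Explicit threshold; values strictly above it map to white.
    bright_is_solid : bool
        Polarity. True (default) maps high intensity to white (solid);
        False complements the mask.

    Raises
    ------
    ValueError
        For a constant field with the automatic method, or an unknown method.
    """
    values = field.values
    if manual_threshold is not None or method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        thresh = float(manual_threshold)
    elif method == "otsu":
        if np.ptp(values) == 0:
            raise ValueError("constant image: automatic thresholding is degenerate")
        thresh = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    mask = values > thresh
    if not bright_is_solid:
        mask = ~mask
    return BinaryImage(mask, field.pixel_scale)
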