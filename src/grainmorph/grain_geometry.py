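"""Kernel shape descriptors from measured dimensions or silhouettes.

For a kernel of length ``L``, width ``W`` and thickness ``T`` (mm) with a
projection of area ``A`` and perimeter ``P``:

* mean geometric diameter ``D_m = (L·W·T)^(1/3)``;
* thinness ratio ``R_s = P² / (4π·A)`` — 1 for a circle, growing with
  elongation (the isoperimetric deficit);
* circularity ``R_c = 2√(π·A) / P`` — 1 for a circle, shrinking with
  elongation.

``R_s·R_c² = 1`` identically, so the two descriptors carry the same
information on reciprocal scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton, regionprops

from .image_io import BinaryImage

__all__ = [
    "KernelMeasurements",
    "ShapeDescriptors",
    "mean_diameter",
    "thinness_ratio",
    "circularity",
    "shape_descriptors",
    "silhouette_measure",
]


@dataclass(frozen=True)
class KernelMeasurements:
    """Per-kernel geometry: axes (mm), projection areas (mm²), perimeters (mm).

    Projection ``a`` is the kernel lying sideways, projection ``b`` the
    kernel with the crease (furrow) down.
    """

    L: float
    W: float
    T: float
    A_a: float | None = None
    A_b: float | None = None
    P_a: float | None = None
    P_b: float | None = None
    KW_mg: float | None = None
    cultivar: str = ""

    def __post_init__(self) -> None:
        for name in ("L", "W", "T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("A_a", "A_b", "P_a", "P_b"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when given")
        if self.A_b is not None and self.P_b is not None:
            if self.P_b**2 < 4 * np.pi * self.A_b * (1 - 1e-9):
                raise ValueError(
                    "P_b and A_b violate the isoperimetric inequality"
                )


@dataclass(frozen=True)
class ShapeDescriptors:
    Dm: float  # mm
    Rs: float  # ≥ 1
    Rc: float  # (0, 1]


def mean_diameter(L: float, W: float, T: float) -> float:
    """Geometric mean diameter ``(L·W·T)^(1/3)`` in mm."""
    if L <= 0 or W <= 0 or T <= 0:
        raise ValueError("L, W, T must all be positive")
    return float(np.cbrt(L * W * T))


def thinness_ratio(P_b: float, A_b: float) -> float:
    """``P² / (4π·A)``; equals 1 for a circle, > 1 otherwise."""
    if P_b <= 0 or A_b <= 0:
        raise ValueError("perimeter and area must be positive")
    rs = P_b**2 / (4.0 * np.pi * A_b)
    if rs < 1.0 - 1e-9:
        raise ValueError(
            f"R_s = {rs:.4f} < 1 violates the isoperimetric inequality; "
            "perimeter and area are inconsistent"
        )
    return float(max(rs, 1.0))


def circularity(P_b: float, A_b: float) -> float:
    """``2√(π·A) / P``; equals 1 for a circle, < 1 otherwise."""
    if P_b <= 0 or A_b <= 0:
        raise ValueError("perimeter and area must be positive")
    return float(min(2.0 * np.sqrt(np.pi * A_b) / P_b, 1.0))


def shape_descriptors(km: KernelMeasurements) -> ShapeDescriptors:
    """All three descriptors from one kernel's measurements."""
    if km.P_b is None or km.A_b is None:
        raise ValueError("P_b and A_b are required for R_s and R_c")
    return ShapeDescriptors(
        Dm=mean_diameter(km.L, km.W, km.T),
        Rs=thinness_ratio(km.P_b, km.A_b),
        Rc=circularity(km.P_b, km.A_b),
    )


def silhouette_measure(
    binary: BinaryImage, pixel_scale_mm: float | None = None, min_pixels: int = 16
) -> tuple[float, float, float, float]:
    """Area, perimeter and axis lengths of a single kernel silhouette.

    Area is the pixel count times the squared scale. The perimeter uses the
    four-direction Crofton estimator, which corrects the ~11 % positive
    bias of naive pixel-edge counting and lands within 2 % of the analytic
    perimeter for smooth convex shapes at moderate resolution. ``L`` and
    ``W`` are the major and minor axis lengths of the ellipse matching the
    region's second moments.

    Parameters
    ----------
    binary : BinaryImage
        Must contain exactly one connected component of at least
        ``min_pixels`` pixels.
    pixel_scale_mm : float, optional
        Physical scale (mm/px); defaults to the image's own scale field.

    Returns
    -------
    (A, P, L, W) in mm², mm, mm, mm.
    """
    scale = pixel_scale_mm if pixel_scale_mm is not None else binary.pixel_scale
    labels = cc_label(binary.mask, connectivity=2)
    n_comp = int(labels.max())
    if n_comp != 1:
        raise ValueError(
            f"silhouette must be a single connected component, found {n_comp}"
        )
    region = regionprops(labels)[0]
    if region.area < min_pixels:
        raise ValueError(
            f"silhouette of {region.area} px is degenerate (< {min_pixels} px)"
        )
    area = float(region.area) * scale**2
    perim = float(perimeter_crofton(binary.mask, directions=4)) * scale
    length = float(region.axis_major_length) * scale
    width = float(region.axis_minor_length) * scale
    return area, perim, length, width
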