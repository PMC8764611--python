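"""Shared domain types for the ascites CT pipeline.

Images are axial CT slices in Hounsfield units (HU): water ~ 0 HU,
air ~ -1000 HU.  Masks are per-pixel binary ascites labels on the same
grid.  The abdomen display window (width 400 HU, level 60 HU) maps the
clinically relevant soft-tissue/fluid range onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: HU band considered "near water", i.e. compatible with simple fluid.
FLUID_HU_RANGE = (-10.0, 30.0)


@dataclass
class HUSlice:
    """One axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : ndarray, shape (n, n)
        Square grid of HU values.
    pixel_spacing_mm : tuple of float
        (row, column) spacing in millimetres.
    slice_thickness_mm : float
        Reconstruction slice thickness in millimetres.
    subject_id, slice_index
        Identifiers used for bookkeeping and subject-level splits.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.74, 0.74)
    slice_thickness_mm: float = 5.0
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(
                f"CT slice grid must be square 2-D, got shape {self.pixels.shape}"
            )
        if isinstance(self.pixel_spacing_mm, (int, float)):
            self.pixel_spacing_mm = (float(self.pixel_spacing_mm),) * 2
        if min(self.pixel_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")

    @property
    def grid_size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Linear HU display window: ``width`` HU centred at ``level`` HU."""

    width: float = 400.0
    level: float = 60.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


@dataclass(frozen=True)
class AugmentSpec:
    """Random paired image/mask augmentation: small rotation plus flips.

    The rotation angle is drawn uniformly from ``rotation_range_deg``
    (symmetric about zero); each enabled flip is applied independently
    with probability 1/2.  The same draw is applied to the image and its
    mask.
    """

    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    allow_horizontal_flip: bool = True
    allow_vertical_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not np.isclose(lo, -hi):
            raise ValueError(
                f"rotation range must be symmetric about 0, got ({lo}, {hi})"
            )
        if lo > hi:
            raise ValueError("rotation range must be ordered (lo, hi)")


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` contains only {0, 1} and return it as uint8."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary in {{0,1}}, found values {vals[:10]}")
    return mask.astype(np.uint8)


def validate_model_input(x: np.ndarray) -> np.ndarray:
    """Check the (H, W, 3) in-[0,1] contract of a model input tensor."""
    x = np.asarray(x)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"model input must be (H, W, 3), got {x.shape}")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("model input values must lie in [0, 1]")
    return x
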