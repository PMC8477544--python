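"""Shared containers and error types for the LIC segmentation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class LicSegError(ValueError):
    """Base class for all validation / domain errors raised by licseg."""


class ValidationError(LicSegError):
    """Invalid argument values or shapes."""


class InsufficientDataError(LicSegError):
    """Fewer samples than the operation requires."""


class DegenerateInputError(LicSegError):
    """Input carries no usable contrast (e.g. a constant image)."""


class MetricUndefinedError(LicSegError):
    """A segmentation metric is undefined for the given masks."""


class BodyNotFoundError(LicSegError):
    """No foreground object survived body-ROI selection."""


class MetadataError(LicSegError):
    """Required acquisition metadata (echo times, spacing) is missing."""


@dataclass
class BinaryMask:
    """A 2-D boolean region with its pixel spacing.

    Parameters
    ----------
    pixels : (H, W) bool array
        Region membership per pixel.
    pixel_spacing_mm : (row_mm, col_mm)
        Physical pixel size; used by distance-based metrics.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2-D")
        r, c = self.pixel_spacing_mm
        if not (r > 0 and c > 0):
            raise ValidationError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels & other.pixels, self.pixel_spacing_mm)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels | other.pixels, self.pixel_spacing_mm)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, self.pixel_spacing_mm)

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return bool(np.all(~self.pixels | other.pixels))


def as_bool_array(mask) -> np.ndarray:
    """Coerce a BinaryMask or array-like into a 2-D boolean array."""
    px = getattr(mask, "pixels", mask)
    arr = np.asarray(px, dtype=bool)
    if arr.ndim != 2:
        raise ValidationError("mask must be 2-D")
    return arr


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete disk structuring element {(dr, dc): dr**2 + dc**2 <= r**2}."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r
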