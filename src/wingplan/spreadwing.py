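"""Spread-wing image workflow: segmentation, area measurement, total area.

The traditional route to a bird's total wing area measures one prepared
spread wing from a scaled photograph: threshold the image to a binary mask,
fill enclosed holes, measure the area of the wing object, then reconstruct
the two-winged total from the single-wing area ``a``, the root chord ``c``
(wing width at the body junction), the wing extent ``e`` (wingtip to root
chord) and the wingspan ``WS``::

    total = 2*a + c * (WS - 2*e)

The second term is the "root box" covering the body between the two wings.

Segmentation conventions: the wing is the *dark* object on a light
background; automatic thresholding uses Otsu's criterion; connected
components use 4-connectivity and hole filling floods the background with
8-connectivity (the standard complementary pair, which prevents
checkerboard leakage between object and background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .estimators import GeometryViolationError, InvalidMeasurementError

__all__ = [
    "WingImage",
    "BinaryMask",
    "SpreadWingMeasurements",
    "DegenerateSegmentationWarning",
    "binarize",
    "fill_holes",
    "largest_component_area",
    "total_area_spread",
]

AUTO = "auto"

# object/background connectivity: 4-connected components, 8-connected background
_STRUCT_OBJECT = ndimage.generate_binary_structure(2, 1)
_STRUCT_BACKGROUND = ndimage.generate_binary_structure(2, 2)


class DegenerateSegmentationWarning(UserWarning):
    """Thresholding produced an all-true or all-false mask."""


@dataclass(frozen=True)
class WingImage:
    """Grayscale raster with a pixel scale (pixels per cm)."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidMeasurementError("image must be a non-empty 2-D raster")
        if not self.scale > 0:
            raise InvalidMeasurementError(f"scale must be positive, got {self.scale!r}")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster sharing the shape and scale of its source image."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise InvalidMeasurementError("mask must be a non-empty 2-D raster")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SpreadWingMeasurements:
    """Inputs of the spread-wing total-area reconstruction (cm, cm^2)."""

    single_wing_area: float
    root_chord: float
    wing_extent: float
    wingspan: float

    def __post_init__(self):
        if self.single_wing_area <= 0:
            raise InvalidMeasurementError("single_wing_area must be positive")
        if self.root_chord < 0:
            raise InvalidMeasurementError("root_chord must be non-negative")
        if self.wing_extent <= 0 or self.wingspan <= 0:
            raise InvalidMeasurementError("wing_extent and wingspan must be positive")
        if self.wing_extent > self.wingspan:
            raise InvalidMeasurementError(
                f"wing extent {self.wing_extent} exceeds wingspan {self.wingspan}"
            )


def binarize(image: WingImage, threshold=AUTO) -> BinaryMask:
    """Threshold a grayscale wing image into a binary mask.

    Pixels with intensity <= threshold (the dark-object convention) become
    True.  ``threshold='auto'`` selects the threshold with Otsu's
    between-class-variance criterion; a constant image cannot be thresholded
    automatically and yields an empty mask with a warning.
    """
    px = image.pixels
    if threshold == AUTO:
        if px.min() == px.max():
            warnings.warn(
                "image has a single intensity level; automatic thresholding "
                "produced an empty mask",
                DegenerateSegmentationWarning,
                stacklevel=2,
            )
            return BinaryMask(np.zeros_like(px, dtype=bool), image.scale)
        thr = threshold_otsu(px)
    else:
        thr = float(threshold)
    mask = px <= thr
    if mask.all() or not mask.any():
        warnings.warn(
            f"threshold {thr} produced a degenerate "
            f"({'all-wing' if mask.all() else 'empty'}) mask",
            DegenerateSegmentationWarning,
            stacklevel=2,
        )
    return BinaryMask(mask, image.scale)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill enclosed holes: background regions not connected to the border.

    The background is flooded with 8-connectivity from the raster border;
    any background region the flood cannot reach is an enclosed hole and
    becomes wing.  Border-connected background (including open notches) is
    left unchanged, so the true-pixel count never decreases.
    """
    # the structure drives the background flood: 8-connected background
    filled = ndimage.binary_fill_holes(mask.pixels, structure=_STRUCT_BACKGROUND)
    return BinaryMask(filled, mask.scale)


def largest_component_area(mask: BinaryMask) -> float:
    """Area (cm^2) of the largest 4-connected component of the mask.

    Mirrors measuring the single wing object in a thresholded photo while
    ignoring detached specks: pixel count of the largest component divided
    by scale^2.
    """
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT_OBJECT)
    if n == 0:
        raise InvalidMeasurementError("mask contains no object (no true pixels)")
    counts = np.bincount(labels.ravel())[1:]  # drop background label 0
    return float(counts.max()) / (mask.scale ** 2)


def total_area_spread(m: SpreadWingMeasurements, *, clamp: bool = False) -> float:
    """Two-winged total area from single-wing measurements, cm^2.

    ``2*a + c*(WS - 2*e)``: twice the measured single-wing area plus the
    root box between the wings.  ``WS < 2*e`` makes the root box negative
    and raises unless ``clamp`` forces it to zero — the same policy as the
    folded-wing medial box.
    """
    root_box = m.root_chord * (m.wingspan - 2.0 * m.wing_extent)
    if root_box < 0:
        if not clamp:
            raise GeometryViolationError(
                f"wingspan {m.wingspan} < 2 * wing extent {m.wing_extent}: "
                "negative root box (use clamp to force 0)"
            )
        root_box = 0.0
    return 2.0 * m.single_wing_area + root_box
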