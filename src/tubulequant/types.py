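"""Shared domain containers and error types.

The pipeline's working objects are thin dataclasses around numpy arrays so
that physical calibration (micrometres per pixel) travels with the pixels.
Label masks use a fixed three-class vocabulary: background (0), tubule (1),
spheroid (2); 255 marks pixels not yet assigned by annotation propagation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# fixed class codes shared by masks, annotations and the PNG palette
BACKGROUND = 0
TUBULE = 1
SPHEROID = 2
UNLABELLED = 255

CLASS_NAMES = {BACKGROUND: "background", TUBULE: "tubule", SPHEROID: "spheroid"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

# indexed-PNG palette for label masks: background black, tubule grey,
# spheroid white. Any other palette is rejected on read.
MASK_PALETTE = {BACKGROUND: (0, 0, 0), TUBULE: (128, 128, 128), SPHEROID: (255, 255, 255)}


class InvalidSpecError(ValueError):
    """A synthetic-scene or dose-response specification violates its invariants."""


class CannotFillError(ValueError):
    """Boundary fill has no boundary values to propagate from."""


class MissingAnnotationError(ValueError):
    """Annotation propagation was asked to run with no annotations."""


class InsufficientDataError(ValueError):
    """Too few distinct concentrations for a four-parameter fit."""


class ConditioningError(ValueError):
    """The polynomial design matrix is numerically degenerate."""


class FormatError(ValueError):
    """An input file is missing, corrupt, or in an unsupported format."""


@dataclass
class GrayImage:
    """Calibrated 2-D grayscale intensity raster.

    ``pixels`` is a float array with intensities nominally in [0, 1]
    (illumination-corrected images may slightly exceed the range);
    ``pixel_size`` is the edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask aligned with its source image (True = cell)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Per-pixel class map over {background, tubule, spheroid, unlabelled}."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    annotations: Optional["object"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.pixels.shape}")
        valid = {BACKGROUND, TUBULE, SPHEROID, UNLABELLED}
        present = set(np.unique(self.pixels).tolist())
        if not present <= valid:
            raise ValueError(f"mask contains invalid class codes: {sorted(present - valid)}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
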