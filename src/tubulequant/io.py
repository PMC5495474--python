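"""File formats: grayscale TIFF/PNG images, indexed-PNG label masks,
JSON annotations, CSV dose tables.

Images round-trip losslessly at 16-bit depth; intensities are normalised to
[0, 1] on read with the source bit depth recorded.  Label masks are written
as single-channel indexed PNG with a fixed three-entry palette (background
black, tubule grey, spheroid white); any other palette is rejected so classes
can never be silently remapped.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .segmentation import AnnotationSet
from .types import (
    BACKGROUND,
    MASK_PALETTE,
    SPHEROID,
    TUBULE,
    FormatError,
    GrayImage,
    LabelMask,
)

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def read_image(path: str | os.PathLike, pixel_size: float = 1.0) -> GrayImage:
    """Read a grayscale TIFF/PNG as a [0, 1] float image.

    8-bit data is scaled by 1/255, 16-bit by 1/65535; float data must already
    be within [0, 1].  Colour images are rejected — the pipeline is defined
    on single-channel bright-field frames.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode == "P":
                    raise FormatError(
                        f"{path} is an indexed (palette) file; use read_mask"
                    )
                arr = np.asarray(im)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise FormatError(f"{path} is not grayscale (shape {arr.shape}); RGB is rejected")
    if arr.ndim != 2:
        raise FormatError(f"{path} has unsupported dimensionality {arr.ndim}")
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(np.float64)
        if pixels.min() < 0 or pixels.max() > 1:
            raise FormatError(f"float image {path} is not in [0, 1]")
    else:
        raise FormatError(f"unsupported dtype {arr.dtype} in {path}")
    return GrayImage(pixels, pixel_size=pixel_size)


def write_image(path: str | os.PathLike, img: GrayImage) -> None:
    """Write a [0, 1] image as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    data = np.clip(img.pixels, 0.0, 1.0)
    arr16 = np.round(data * 65535.0).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    elif suffix == ".png":
        Image.fromarray(arr16).save(path)
    else:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")


def _expected_palette() -> list[int]:
    flat = [0] * 768
    for idx, rgb in MASK_PALETTE.items():
        flat[3 * idx : 3 * idx + 3] = list(rgb)
    return flat


def write_mask(path: str | os.PathLike, mask: LabelMask) -> None:
    """Write a label mask as indexed PNG with the fixed 3-entry palette."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise FormatError(f"label masks are written as indexed PNG, not {path.suffix!r}")
    im = Image.fromarray(mask.pixels, mode="P")
    im.putpalette(_expected_palette())
    im.save(path)


def read_mask(path: str | os.PathLike, pixel_size: float = 1.0) -> LabelMask:
    """Read an indexed-PNG label mask, verifying the class palette."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mask file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode != "P":
                raise FormatError(f"{path} is not an indexed (palette) PNG")
            palette = im.getpalette() or []
            arr = np.asarray(im, dtype=np.uint8)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read mask {path}: {exc}") from exc
    expected = _expected_palette()
    used = sorted({int(v) for v in np.unique(arr) if v in MASK_PALETTE})
    for idx in used:
        if palette[3 * idx : 3 * idx + 3] != expected[3 * idx : 3 * idx + 3]:
            raise FormatError(
                f"{path} does not use the fixed class palette; refusing to remap"
            )
    return LabelMask(arr, pixel_size=pixel_size)


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read point/scribble annotations from a JSON file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such annotation file: {path}")
    try:
        return AnnotationSet.from_json(path.read_text())
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not parse annotations {path}: {exc}") from exc


def write_annotations(path: str | os.PathLike, ann: AnnotationSet) -> None:
    Path(path).write_text(ann.to_json())


def read_dose_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dose–response CSV into the tidy fitting format.

    Accepts either an ``inhibition_pct`` column or the viability pair
    ``viability`` + ``viability_untreated`` (converted to percent inhibition
    on read).  ``condition`` and ``replicate`` columns pass through.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such dose table: {path}")
    df = pd.read_csv(path)
    if "concentration_M" not in df.columns:
        raise FormatError(f"{path} lacks a concentration_M column")
    if "inhibition_pct" not in df.columns:
        if {"viability", "viability_untreated"} <= set(df.columns):
            from .doseresponse import inhibition

            df["inhibition_pct"] = [
                inhibition(t, u)
                for t, u in zip(df["viability"], df["viability_untreated"])
            ]
        else:
            raise FormatError(
                f"{path} needs inhibition_pct or viability + viability_untreated columns"
            )
    return df


def write_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    """Write a CSV with floats at 6 significant digits (byte-stable runs)."""
    df.to_csv(path, index=False, float_format="%.6g")
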