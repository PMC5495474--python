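"""Background/illumination correction for bright-field images.

Off-centre lighting leaves a smooth dark-to-bright gradient across the frame.
The correction chain: downsample the raw image, mask cellular (textured)
regions with a local-entropy filter, close small holes in the mask with a
disc, replace each cell region with values propagated inward from its
boundary to obtain a cell-free background estimate, least-squares fit that
background to a degree-4 bivariate polynomial, and subtract the fitted
surface from the image (re-adding its mean so the display range is kept).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .types import BinaryMask, CannotFillError, ConditioningError, GrayImage

N_ENTROPY_BINS = 256  # 8-bit intensity quantisation for the entropy histogram


# --------------------------------------------------------------------------- #
# downsampling
# --------------------------------------------------------------------------- #


def downsample(img: GrayImage, factor: float) -> GrayImage:
    """Shrink an image by a linear factor in (0, 1], anti-aliased.

    Output dimensions are ``round(dim * factor)`` and the physical pixel size
    grows by ``1 / factor`` so calibrated areas are preserved.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"downsample factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return GrayImage(img.pixels.copy(), img.pixel_size)
    h, w = img.shape
    out_shape = (int(round(h * factor)), int(round(w * factor)))
    out = resize(
        img.pixels, out_shape, order=1, mode="reflect", anti_aliasing=True,
        preserve_range=True,
    )
    return GrayImage(out, img.pixel_size / factor)


# --------------------------------------------------------------------------- #
# entropy masking
# --------------------------------------------------------------------------- #


def local_entropy(img: GrayImage, window: int = 9) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the windowed intensity histogram.

    Intensities are quantised to 256 bins; the window is reflected at the
    image border.  Values lie in [0, log2(256)] = [0, 8].
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    h, w = img.shape
    if window > h or window > w:
        raise ValueError(f"window {window} exceeds image dimensions {img.shape}")
    q = np.clip((img.pixels * N_ENTROPY_BINS).astype(np.int64), 0, N_ENTROPY_BINS - 1)
    n = window * window
    ent = np.zeros((h, w), dtype=np.float64)
    for v in np.unique(q):
        ind = (q == v).astype(np.float64)
        counts = np.rint(ndimage.uniform_filter(ind, size=window, mode="reflect") * n)
        p = counts / n
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    return ent


def threshold_entropy(entropy_map: np.ndarray, threshold: Union[float, str] = "auto") -> BinaryMask:
    """Binary cell mask: True where local entropy exceeds the threshold.

    ``"auto"`` uses Otsu's bimodal threshold on the entropy map (textured
    cells vs smooth background); a numeric value reproduces the manual
    thresholding workflow.  A constant entropy map yields an empty mask.
    """
    entropy_map = np.asarray(entropy_map, dtype=np.float64)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if np.ptp(entropy_map) == 0:
            return BinaryMask(np.zeros(entropy_map.shape, dtype=bool))
        thr = float(threshold_otsu(entropy_map))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError("entropy threshold must be non-negative")
    return BinaryMask(entropy_map > thr)


# --------------------------------------------------------------------------- #
# morphological closing
# --------------------------------------------------------------------------- #


def disc_footprint(radius: int) -> np.ndarray:
    """Rasterised disc: offsets whose centre distance is <= radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= r**2


def close_mask(mask: BinaryMask, radius: int = 8) -> BinaryMask:
    """Morphological closing by a disc: fills holes narrower than the disc.

    Computed as closing on the infinite plane (the mask embedded in an empty
    background): the input is padded by two radii before dilation/erosion and
    cropped afterwards, which makes discrete closing exactly idempotent.
    """
    footprint = disc_footprint(radius)
    r = int(radius)
    pad = 2 * r
    padded = np.pad(mask.pixels, pad, mode="constant", constant_values=False)
    dil = ndimage.binary_dilation(padded, structure=footprint)
    ero = ndimage.binary_erosion(dil, structure=footprint, border_value=0)
    return BinaryMask(ero[pad:-pad, pad:-pad])


# --------------------------------------------------------------------------- #
# background extraction (boundary fill)
# --------------------------------------------------------------------------- #


def extract_background(img: GrayImage, mask: BinaryMask) -> GrayImage:
    """Replace each masked cell region with values propagated from its boundary.

    Masked pixels are filled with the discrete harmonic interpolant of the
    surrounding unmasked values (the fixed point of repeatedly averaging each
    filled pixel with its 4-neighbours), solved directly as a sparse Laplace
    system.  By the discrete maximum principle every filled value lies within
    the range of its region's boundary values.  Background pixels are
    untouched.
    """
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    m = mask.pixels
    if not m.any():
        return GrayImage(img.pixels.copy(), img.pixel_size)
    if m.all():
        raise CannotFillError("mask covers the entire image; no boundary to fill from")

    h, w = img.shape
    out = img.pixels.copy()
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(m)
    n = len(ys)
    idx[ys, xs] = np.arange(n)

    rows, cols, data = [], [], []
    b = np.zeros(n, dtype=np.float64)
    diag = np.zeros(n, dtype=np.float64)
    bnd_count = np.zeros(n, dtype=np.float64)
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        diag += inside  # in-frame neighbours define the averaging degree
        nb_idx = np.where(inside, idx[ny % h, nx % w], -1)
        masked_nb = inside & (nb_idx >= 0)
        rows.extend(np.arange(n)[masked_nb])
        cols.extend(nb_idx[masked_nb])
        data.extend(np.full(int(masked_nb.sum()), -1.0))
        free_nb = inside & (nb_idx < 0)
        np.add.at(b, np.arange(n)[free_nb], out[ny[free_nb], nx[free_nb]])
        bnd_count += free_nb

    # a 4-connected masked region with no unmasked in-frame neighbour anywhere
    # has no Dirichlet data: refuse rather than return an arbitrary fill
    lbl, n_regions = ndimage.label(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    region_bnd = np.zeros(n_regions + 1)
    np.add.at(region_bnd, lbl[ys, xs], bnd_count)
    if np.any(region_bnd[1:] == 0):
        raise CannotFillError("a masked region has no boundary pixels to fill from")

    a_mat = sparse.coo_matrix(
        (np.concatenate([diag, np.asarray(data)]),
         (np.concatenate([np.arange(n), np.asarray(rows, dtype=np.int64)]),
          np.concatenate([np.arange(n), np.asarray(cols, dtype=np.int64)]))),
        shape=(n, n),
    ).tocsr()
    out[ys, xs] = spsolve(a_mat, b)
    return GrayImage(out, img.pixel_size)


# --------------------------------------------------------------------------- #
# polynomial illumination model
# --------------------------------------------------------------------------- #


def _poly_exponents(degree: int) -> list[tuple[int, int]]:
    return [(i, j) for d in range(degree + 1) for i in range(d + 1) for j in [d - i]]


def _design_matrix(shape: tuple[int, int], exponents) -> np.ndarray:
    h, w = shape
    x = np.linspace(-1.0, 1.0, w)
    y = np.linspace(-1.0, 1.0, h)
    gx, gy = np.meshgrid(x, y)
    cols = [(gx**i * gy**j).ravel() for i, j in exponents]
    return np.column_stack(cols)


@dataclass
class IlluminationModel:
    """Least-squares bivariate polynomial background over [-1, 1]-normalised
    coordinates (x along columns, y along rows)."""

    coeffs: np.ndarray
    exponents: list[tuple[int, int]]
    degree: int
    residual_rms: float

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the fitted surface on a pixel grid of the given shape."""
        a = _design_matrix(shape, self.exponents)
        return (a @ self.coeffs).reshape(shape)

    def coeff_dict(self) -> dict[tuple[int, int], float]:
        return {e: float(c) for e, c in zip(self.exponents, self.coeffs)}


def fit_illumination(bg: GrayImage, degree: int = 4) -> IlluminationModel:
    """Fit the extracted background to a total-degree-``degree`` polynomial.

    The full bivariate monomial basis x^i y^j with i + j <= degree is used
    (15 terms at degree 4).  Degenerate geometry (an image too small or thin
    to determine the surface) raises a conditioning error.
    """
    exponents = _poly_exponents(degree)
    h, w = bg.shape
    if h * w <= len(exponents):
        raise ConditioningError(
            f"image with {h * w} pixels cannot determine {len(exponents)} coefficients"
        )
    a = _design_matrix(bg.shape, exponents)
    coeffs, _, rank, sv = np.linalg.lstsq(a, bg.pixels.ravel(), rcond=None)
    if rank < len(exponents) or sv[0] <= 0 or sv[-1] / sv[0] < 1e-12:
        raise ConditioningError("polynomial design matrix is numerically degenerate")
    resid = bg.pixels.ravel() - a @ coeffs
    return IlluminationModel(
        coeffs=coeffs,
        exponents=exponents,
        degree=degree,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def correct_illumination(img: GrayImage, model: IlluminationModel) -> GrayImage:
    """Subtract the fitted background surface, re-adding its mean.

    Subtracting the surface removes the smooth gradient; adding back the
    surface mean keeps the result in a displayable range and preserves the
    image mean exactly.
    """
    surface = model.evaluate(img.shape)
    out = img.pixels - surface + surface.mean()
    return GrayImage(out, img.pixel_size)


# --------------------------------------------------------------------------- #
# composed chain
# --------------------------------------------------------------------------- #


@dataclass
class PreprocessParams:
    """Tunables of the correction chain, defaulting to the working protocol:
    25% downsampling, 9x9 entropy window, radius-8 disc closing, degree-4
    background polynomial."""

    downsample_factor: float = 0.25
    entropy_window: int = 9
    entropy_threshold: Union[float, str] = "auto"
    closing_radius: int = 8
    poly_degree: int = 4


@dataclass
class PreprocessResult:
    """Corrected image plus every intermediate artefact for inspection."""

    corrected: GrayImage
    downsampled: GrayImage
    entropy_map: np.ndarray
    cell_mask: BinaryMask
    background: GrayImage
    model: IlluminationModel


def preprocess_image(img: GrayImage, params: PreprocessParams | None = None) -> PreprocessResult:
    """Run the full correction chain on one image.

    downsample -> local entropy -> threshold -> disc closing -> boundary-fill
    background extraction -> polynomial fit -> subtraction.  Deterministic for
    fixed input and parameters.
    """
    p = params or PreprocessParams()
    small = downsample(img, p.downsample_factor)
    ent = local_entropy(small, p.entropy_window)
    mask = threshold_entropy(ent, p.entropy_threshold)
    closed = close_mask(mask, p.closing_radius) if mask.pixels.any() else mask
    bg = extract_background(small, closed)
    model = fit_illumination(bg, p.poly_degree)
    corrected = correct_illumination(small, model)
    return PreprocessResult(
        corrected=corrected,
        downsampled=small,
        entropy_map=ent,
        cell_mask=closed,
        background=bg,
        model=model,
    )
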