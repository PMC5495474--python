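"""Contour-strength hierarchy and sparse-annotation propagation.

The corrected image is turned into a boundary-strength map (smoothed gradient
magnitude), over-segmented into fine watershed regions, and organised into a
merge tree: adjacent regions are united in order of increasing shared-boundary
strength, so cutting the tree at any strength yields a partition and the
partitions at increasing cuts are nested.  A handful of human point/scribble
annotations (one per object plus a few background points) is then propagated:
each annotated base region takes its class, and every other region inherits
the class of the labelled region it first joins in the merge tree — i.e. the
label reachable across the weakest contours.

Coordinates are 0-based (x = column, y = row), origin at the top-left, pixel
centres at integer coordinates.  Watershed regions use 4-connectivity.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import sobel
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .types import (
    BACKGROUND,
    CLASS_CODES,
    CLASS_NAMES,
    SPHEROID,
    TUBULE,
    UNLABELLED,
    GrayImage,
    LabelMask,
    MissingAnnotationError,
)

# tie-break priority when annotation classes conflict in one region/cluster
_CLASS_PRIORITY = {SPHEROID: 0, TUBULE: 1, BACKGROUND: 2}


# --------------------------------------------------------------------------- #
# annotations
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Annotation:
    """One point label: pixel coordinates and a class code."""

    x: float
    y: float
    cls: int


@dataclass
class Polyline:
    """A scribble: a polyline of vertices sharing one class."""

    points: list[tuple[float, float]]
    cls: int


@dataclass
class AnnotationSet:
    """Sparse human labels: points and optional polyline scribbles."""

    points: list[Annotation] = field(default_factory=list)
    polylines: list[Polyline] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points) + len(self.polylines)

    def union(self, other: "AnnotationSet") -> "AnnotationSet":
        return AnnotationSet(
            points=self.points + other.points,
            polylines=self.polylines + other.polylines,
        )

    def rasterised_points(self, shape: tuple[int, int]) -> list[tuple[int, int, int]]:
        """All annotation pixels as (row, col, class), polylines rasterised."""
        h, w = shape
        out: list[tuple[int, int, int]] = []

        def _add(x: float, y: float, cls: int) -> None:
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"annotation ({x}, {y}) outside image {shape}")
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown annotation class {cls}")
            out.append((r, c, cls))

        for p in self.points:
            _add(p.x, p.y, p.cls)
        for pl in self.polylines:
            if len(pl.points) == 1:
                _add(pl.points[0][0], pl.points[0][1], pl.cls)
                continue
            for (x0, y0), (x1, y1) in zip(pl.points[:-1], pl.points[1:]):
                rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
                for r, c in zip(rr, cc):
                    _add(float(c), float(r), pl.cls)
        return out

    @classmethod
    def from_json(cls, text: str) -> "AnnotationSet":
        data = json.loads(text)
        if isinstance(data, list):  # bare list of point objects
            data = {"points": data}
        points = [
            Annotation(x=float(p["x"]), y=float(p["y"]), cls=_parse_class(p["class"]))
            for p in data.get("points", [])
        ]
        polylines = [
            Polyline(
                points=[(float(x), float(y)) for x, y in pl["points"]],
                cls=_parse_class(pl["class"]),
            )
            for pl in data.get("polylines", [])
        ]
        return cls(points=points, polylines=polylines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "points": [
                    {"x": p.x, "y": p.y, "class": CLASS_NAMES[p.cls]} for p in self.points
                ],
                "polylines": [
                    {"points": [[x, y] for x, y in pl.points], "class": CLASS_NAMES[pl.cls]}
                    for pl in self.polylines
                ],
            },
            indent=1,
        )


def _parse_class(value) -> int:
    if isinstance(value, str):
        if value not in CLASS_CODES:
            raise ValueError(f"unknown annotation class {value!r}")
        return CLASS_CODES[value]
    iv = int(value)
    if iv not in CLASS_NAMES:
        raise ValueError(f"unknown annotation class {value!r}")
    return iv


# --------------------------------------------------------------------------- #
# boundary strength
# --------------------------------------------------------------------------- #


@dataclass
class BoundaryStrengthMap:
    """Non-negative contour-strength raster, normalised to [0, 1]."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("strength map must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("strength values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def detect_contours(img: GrayImage, sigma: float = 2.0) -> BoundaryStrengthMap:
    """Smoothed gradient-magnitude boundary strength, scaled to [0, 1].

    Gaussian pre-smoothing (default sigma 2 px) suppresses cellular texture
    before the Sobel gradient; the map is invariant to intensity inversion.
    """
    smoothed = ndimage.gaussian_filter(img.pixels, sigma) if sigma > 0 else img.pixels
    grad = sobel(smoothed)
    peak = grad.max()
    if peak > 0:
        grad = grad / peak
    return BoundaryStrengthMap(grad, img.pixel_size)


# --------------------------------------------------------------------------- #
# region hierarchy
# --------------------------------------------------------------------------- #


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if rb < ra:  # keep the smaller id as representative, deterministic
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True


@dataclass
class RegionHierarchy:
    """Fine watershed partition plus a merge tree indexed by contour strength.

    ``base_labels`` holds region ids 1..n_base; ``merges`` lists
    (region_a, region_b, strength) with non-decreasing strength — uniting the
    pairs with strength <= t gives the partition at cut level t, and cuts at
    increasing t are nested by construction.
    """

    base_labels: np.ndarray
    merges: list[tuple[int, int, float]]
    n_base: int
    pixel_size: float = 1.0

    def cut(self, strength: float) -> np.ndarray:
        """Partition at a cut level: region ids relabelled to representatives."""
        uf = _UnionFind(self.n_base + 1)
        for a, b, s in self.merges:
            if s <= strength:
                uf.union(a, b)
        lut = np.arange(self.n_base + 1)
        for i in range(1, self.n_base + 1):
            lut[i] = uf.find(i)
        return lut[self.base_labels]

    @property
    def max_strength(self) -> float:
        return max((s for _, _, s in self.merges), default=0.0)


def build_hierarchy(strength: BoundaryStrengthMap) -> RegionHierarchy:
    """Watershed base partition merged bottom-up by shared-boundary strength.

    The strength map is flooded from its local minima (4-connectivity); each
    pair of adjacent regions gets a boundary strength — the minimum over their
    shared boundary of the stronger pixel of each touching pair — and regions
    are united in increasing order of that strength (single-linkage over the
    region adjacency graph), which yields non-decreasing merge strengths.
    """
    s = strength.pixels
    markers, n_markers = ndimage.label(local_minima(s, connectivity=1))
    if n_markers == 0:  # constant map: every pixel is a minimum plateau
        base = np.ones(s.shape, dtype=np.int32)
    else:
        base = watershed(s, markers=markers, connectivity=1)
    n_base = int(base.max())

    # boundary strength per adjacent region pair, over 4-adjacent pixel pairs
    keys_parts, w_parts = [], []
    for axis in (0, 1):
        a = base[:-1, :] if axis == 0 else base[:, :-1]
        b = base[1:, :] if axis == 0 else base[:, 1:]
        sa = s[:-1, :] if axis == 0 else s[:, :-1]
        sb = s[1:, :] if axis == 0 else s[:, 1:]
        diff = a != b
        if not diff.any():
            continue
        ra, rb = a[diff].astype(np.int64), b[diff].astype(np.int64)
        lo, hi = np.minimum(ra, rb), np.maximum(ra, rb)
        keys_parts.append(lo * (n_base + 1) + hi)
        w_parts.append(np.maximum(sa[diff], sb[diff]))

    edges: list[tuple[tuple[int, int], float]] = []
    if keys_parts:
        keys = np.concatenate(keys_parts)
        ws = np.concatenate(w_parts)
        uniq, inv = np.unique(keys, return_inverse=True)
        wmin = np.full(len(uniq), np.inf)
        np.minimum.at(wmin, inv, ws)
        lo = (uniq // (n_base + 1)).astype(int)
        hi = (uniq % (n_base + 1)).astype(int)
        order = np.lexsort((hi, lo, wmin))
        edges = [((int(lo[k]), int(hi[k])), float(wmin[k])) for k in order]
    uf = _UnionFind(n_base + 1)
    merges: list[tuple[int, int, float]] = []
    for (a, b), w in edges:
        if uf.union(a, b):
            merges.append((a, b, w))
    return RegionHierarchy(
        base_labels=base, merges=merges, n_base=n_base, pixel_size=strength.pixel_size
    )


# --------------------------------------------------------------------------- #
# annotation propagation
# --------------------------------------------------------------------------- #


def _dominant_class(class_counts: dict[int, int]) -> int:
    """Majority class; ties broken by spheroid > tubule > background."""
    return min(
        class_counts,
        key=lambda c: (-class_counts[c], _CLASS_PRIORITY[c]),
    )


def propagate_annotations(h: RegionHierarchy, ann: AnnotationSet) -> LabelMask:
    """Spread sparse labels through the merge tree into a full class mask.

    Base regions containing annotation pixels take their majority class.
    Every unannotated region inherits a class at the first (lowest-strength)
    merge that joins it to an annotated cluster — the label separated from it
    by the weakest contours.  The result has no unlabelled pixels.
    """
    if len(ann) == 0:
        raise MissingAnnotationError("at least one annotation is required")
    pts = ann.rasterised_points(h.base_labels.shape)
    if not pts:
        raise MissingAnnotationError("annotation set rasterised to no pixels")

    # per-region annotation class counts (counting annotation pixels)
    region_counts: dict[int, dict[int, int]] = {}
    for r, c, cls in pts:
        rid = int(h.base_labels[r, c])
        region_counts.setdefault(rid, {}).setdefault(cls, 0)
        region_counts[rid][cls] += 1

    assigned: dict[int, int] = {
        rid: _dominant_class(counts) for rid, counts in region_counts.items()
    }

    # replay merges; an unlabelled cluster joining a labelled one inherits the
    # assigned class of the specific labelled region at the triggering
    # boundary (the labelled region reached across the weakest contour)
    uf = _UnionFind(h.n_base + 1)
    labelled: dict[int, bool] = {}
    members: dict[int, list[int]] = {}
    for rid in range(1, h.n_base + 1):
        labelled[rid] = rid in assigned
        members[rid] = [] if rid in assigned else [rid]

    for a, b, _s in h.merges:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        la, lb = labelled[ra], labelled[rb]
        pending = members[ra] + members[rb]
        if la or lb:
            if pending:
                donor_region = a if la else b
                cls = assigned[donor_region]
                for rid in pending:
                    assigned[rid] = cls
            pending = []
        uf.union(ra, rb)
        root = uf.find(ra)
        other = rb if root == ra else ra
        labelled[root] = la or lb
        members[root] = pending
        labelled.pop(other, None)
        members.pop(other, None)

    lut = np.full(h.n_base + 1, UNLABELLED, dtype=np.uint8)
    for rid, cls in assigned.items():
        lut[rid] = cls
    mask = lut[h.base_labels]
    if np.any(mask == UNLABELLED):  # only possible on a disconnected grid
        raise MissingAnnotationError("annotations did not reach every region")
    return LabelMask(mask, pixel_size=h.pixel_size, annotations=ann)


def refine_labels(
    mask: LabelMask, h: RegionHierarchy, extra: AnnotationSet
) -> LabelMask:
    """Re-propagate with the union of the mask's annotations and new ones.

    Regions already pinned by an annotation keep their class unless directly
    re-annotated; idempotent for a fixed annotation union.
    """
    prior = mask.annotations if isinstance(mask.annotations, AnnotationSet) else AnnotationSet()
    if len(extra) == 0:
        return LabelMask(mask.pixels.copy(), mask.pixel_size, annotations=prior)
    return propagate_annotations(h, prior.union(extra))
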