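"""Ground-truth-labelled synthetic co-culture scenes and dose–response tables.

Emulates the bright-field appearance of an endothelial/cancer-cell co-culture
in a gel sandwich: compact cancer-cell spheroids (filled ellipses), a branched
endothelial tubule network (strokes along the edges of a relative-neighbourhood
graph), a smooth dark-to-bright illumination gradient (low-degree bivariate
polynomial) and additive Gaussian sensor noise.  Every scene carries its exact
ground truth — label mask, per-spheroid areas, centreline length and the
junction count of the generating graph — so each downstream analysis stage can
be validated without any deposited image data.

Rasterisation is exact point-in-shape at pixel centres: a pixel belongs to a
tubule iff its centre lies within half a stroke width of some network edge,
and to a spheroid iff the ellipse form evaluates to <= 1.  Spheroids take
precedence over tubules in the label mask (the two cell types cluster
together in real co-cultures and the compact structure occludes the thin one).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    BACKGROUND,
    SPHEROID,
    TUBULE,
    GrayImage,
    InvalidSpecError,
    LabelMask,
)

# --------------------------------------------------------------------------- #
# specifications
# --------------------------------------------------------------------------- #


@dataclass
class SceneSpec:
    """Parameters of one synthetic co-culture field of view.

    Lengths are in micrometres; intensities in [0, 1].  ``illum_coeffs`` maps
    monomial exponents ``(i, j)`` (total degree <= 4) to coefficients of the
    additive illumination field evaluated over coordinates normalised to
    [-1, 1] in x (columns) and y (rows).  ``cell_texture_sd`` is the standard
    deviation of the intensity texture inside cells — the cue the entropy
    filter keys on — while ``noise_sd`` is sensor noise over the whole frame.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size: float = 1.0
    n_spheroids: int = 5
    spheroid_radius_range: tuple[float, float] = (20.0, 60.0)
    n_tubule_nodes: int = 12
    tubule_width: float = 8.0
    foreground_level: float = 0.35
    background_level: float = 0.65
    cell_texture_sd: float = 0.05
    illum_coeffs: dict[tuple[int, int], float] = field(
        default_factory=lambda: {
            (0, 0): 0.0,
            (1, 0): 0.06,
            (0, 1): 0.04,
            (1, 1): 0.02,
            (2, 0): 0.02,
            (0, 2): -0.015,
            (2, 1): 0.01,
            (0, 3): 0.008,
            (2, 2): -0.006,
            (4, 0): 0.005,
        }
    )
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise InvalidSpecError("frame must be at least 64x64 pixels")
        if not self.pixel_size > 0:
            raise InvalidSpecError("pixel_size must be positive")
        if self.noise_sd < 0 or self.cell_texture_sd < 0:
            raise InvalidSpecError("noise levels must be non-negative")
        r_lo, r_hi = self.spheroid_radius_range
        if not (0 < r_lo <= r_hi):
            raise InvalidSpecError("spheroid radii must be positive and ordered")
        if self.n_spheroids < 0 or self.n_tubule_nodes < 0:
            raise InvalidSpecError("object counts must be non-negative")
        if not self.tubule_width > 0:
            raise InvalidSpecError("tubule_width must be positive")
        r_hi_px = r_hi / self.pixel_size
        if self.n_spheroids > 0 and r_hi_px > min(self.width_px, self.height_px) / 2:
            raise InvalidSpecError(
                f"spheroid radius {r_hi} um ({r_hi_px:.0f} px) cannot fit in a "
                f"{self.width_px}x{self.height_px} frame"
            )
        for (i, j) in self.illum_coeffs:
            if i < 0 or j < 0 or i + j > 4:
                raise InvalidSpecError("illumination exponents must satisfy 0 <= i+j <= 4")


@dataclass
class DoseResponseSpec:
    """Parameters of a simulated log-dose inhibition experiment.

    The noiseless response follows the four-parameter logistic
    ``floor + (ceiling - floor) / (1 + (ic50 / c) ** hill_slope)`` with
    concentrations in molar and responses in percent inhibition.
    """

    ic50: float = 2.1e-7
    hill_slope: float = 1.0
    floor: float = 0.0
    ceiling: float = 100.0
    concentrations: tuple[float, ...] = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.ic50 > 0:
            raise InvalidSpecError("ic50 must be positive")
        if not self.floor < self.ceiling:
            raise InvalidSpecError("floor must be below ceiling")
        if len(self.concentrations) == 0 or any(c <= 0 for c in self.concentrations):
            raise InvalidSpecError("concentrations must be strictly positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise InvalidSpecError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """Exact reference quantities for one rendered scene (areas in um^2)."""

    label_mask: LabelMask
    per_spheroid_areas: list[float]
    true_total_tubule_area: float
    true_junction_count: int
    true_skeleton_length: float
    illum_field: GrayImage
    spheroid_centres_px: list[tuple[float, float]]  # (x, y)
    spheroid_axes_px: list[tuple[float, float]]  # (semi-major, semi-minor)
    spheroid_angles: list[float]  # radians
    tubule_nodes_px: list[tuple[float, float]]
    tubule_edges: list[tuple[int, int]]
    seed: int = 0


# --------------------------------------------------------------------------- #
# geometry sampling
# --------------------------------------------------------------------------- #


@dataclass
class _Geometry:
    # spheroids: centre (x, y) px, semi-axes (a, b) px at unit scale, angle rad
    sph_centres: np.ndarray
    sph_axes: np.ndarray
    sph_angles: np.ndarray
    # tubule graph: node positions (x, y) px, edge index pairs
    nodes: np.ndarray
    edges: list[tuple[int, int]]


def _relative_neighbourhood_graph(points: np.ndarray) -> list[tuple[int, int]]:
    """Edges (i, j) such that no third point is closer to both endpoints."""
    n = len(points)
    if n < 2:
        return []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = d[i, j]
            blocked = False
            for k in range(n):
                if k != i and k != j and max(d[i, k], d[j, k]) < dij:
                    blocked = True
                    break
            if not blocked:
                edges.append((i, j))
    return edges


def _sample_geometry(spec: SceneSpec, max_sph_scale: float, max_tub_scale: float) -> _Geometry:
    """Place objects once, with separations sized for the largest timepoint.

    Spheroids are rejection-sampled to be pairwise disjoint (so per-spheroid
    areas sum exactly to the class area) and fully inside the frame.  Tubule
    nodes keep a minimum mutual separation of four stroke widths so that
    distinct graph junctions stay resolvable after rasterisation.
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0xA11CE])
    ps = spec.pixel_size

    # --- tubule nodes -------------------------------------------------------
    w_px = spec.tubule_width / ps * max_tub_scale
    node_margin = w_px / 2 + 2
    min_sep = max(4.0 * w_px, 20.0)
    nodes: list[np.ndarray] = []
    for _ in range(spec.n_tubule_nodes):
        for attempt in range(2000):
            p = rng.uniform(
                [node_margin, node_margin],
                [spec.width_px - node_margin, spec.height_px - node_margin],
            )
            if all(np.linalg.norm(p - q) >= min_sep for q in nodes):
                nodes.append(p)
                break
        else:
            raise InvalidSpecError(
                f"could not place {spec.n_tubule_nodes} tubule nodes with "
                f"separation {min_sep:.0f} px in the frame"
            )
    nodes_arr = np.array(nodes) if nodes else np.zeros((0, 2))
    edges = _relative_neighbourhood_graph(nodes_arr)

    # --- spheroids ----------------------------------------------------------
    r_lo, r_hi = spec.spheroid_radius_range
    centres, axes, angles = [], [], []
    for _ in range(spec.n_spheroids):
        for attempt in range(2000):
            r = rng.uniform(r_lo, r_hi) / ps * max_sph_scale
            ratio = rng.uniform(0.75, 1.0)
            ang = rng.uniform(0.0, np.pi)
            margin = r + 2
            if margin >= spec.width_px - margin or margin >= spec.height_px - margin:
                continue
            c = rng.uniform(
                [margin, margin], [spec.width_px - margin, spec.height_px - margin]
            )
            ok = all(
                np.linalg.norm(c - c2) > r + a2 + 2 for c2, (a2, _) in zip(centres, axes)
            )
            if ok:
                centres.append(c)
                axes.append((r, r * ratio))
                angles.append(ang)
                break
        else:
            raise InvalidSpecError(
                f"could not place {spec.n_spheroids} disjoint spheroids in the frame"
            )
    return _Geometry(
        sph_centres=np.array(centres) if centres else np.zeros((0, 2)),
        sph_axes=np.array(axes) if axes else np.zeros((0, 2)),
        sph_angles=np.array(angles) if angles else np.zeros(0),
        nodes=nodes_arr,
        edges=edges,
    )


# --------------------------------------------------------------------------- #
# rasterisation
# --------------------------------------------------------------------------- #


def _raster_tubules(geom: _Geometry, shape: tuple[int, int], half_width: float) -> np.ndarray:
    """Pixel centre within ``half_width`` of any network edge segment."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pad = int(np.ceil(half_width)) + 1
    for i, j in geom.edges:
        p, q = geom.nodes[i], geom.nodes[j]
        x0 = max(0, int(np.floor(min(p[0], q[0]) - pad)))
        x1 = min(w - 1, int(np.ceil(max(p[0], q[0]) + pad)))
        y0 = max(0, int(np.floor(min(p[1], q[1]) - pad)))
        y1 = min(h - 1, int(np.ceil(max(p[1], q[1]) + pad)))
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1, dtype=float)
        ys = np.arange(y0, y1 + 1, dtype=float)
        gx, gy = np.meshgrid(xs, ys)
        v = q - p
        vv = float(v @ v)
        if vv == 0.0:
            dist = np.hypot(gx - p[0], gy - p[1])
        else:
            t = ((gx - p[0]) * v[0] + (gy - p[1]) * v[1]) / vv
            t = np.clip(t, 0.0, 1.0)
            dist = np.hypot(gx - (p[0] + t * v[0]), gy - (p[1] + t * v[1]))
        mask[y0 : y1 + 1, x0 : x1 + 1] |= dist <= half_width
    return mask


def _raster_spheroid(
    centre: np.ndarray, ab: np.ndarray, angle: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of one rotated filled ellipse, evaluated at pixel centres."""
    h, w = shape
    a, b = float(ab[0]), float(ab[1])
    pad = int(np.ceil(max(a, b))) + 1
    x0 = max(0, int(np.floor(centre[0] - pad)))
    x1 = min(w - 1, int(np.ceil(centre[0] + pad)))
    y0 = max(0, int(np.floor(centre[1] - pad)))
    y1 = min(h - 1, int(np.ceil(centre[1] + pad)))
    mask = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs = np.arange(x0, x1 + 1, dtype=float) - centre[0]
    ys = np.arange(y0, y1 + 1, dtype=float) - centre[1]
    gx, gy = np.meshgrid(xs, ys)
    ca, sa = np.cos(angle), np.sin(angle)
    u = gx * ca + gy * sa
    v = -gx * sa + gy * ca
    mask[y0 : y1 + 1, x0 : x1 + 1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def evaluate_illumination(
    coeffs: dict[tuple[int, int], float], shape: tuple[int, int]
) -> np.ndarray:
    """Evaluate the bivariate illumination polynomial over a pixel grid.

    Coordinates are normalised to [-1, 1]: x along columns, y along rows.
    """
    h, w = shape
    x = np.linspace(-1.0, 1.0, w)
    y = np.linspace(-1.0, 1.0, h)
    gx, gy = np.meshgrid(x, y)
    out = np.zeros(shape, dtype=np.float64)
    for (i, j), c in coeffs.items():
        out += c * gx**i * gy**j
    return out


# --------------------------------------------------------------------------- #
# scene rendering
# --------------------------------------------------------------------------- #


def _render_scene(
    spec: SceneSpec, geom: _Geometry, sph_scale: float, tub_scale: float
) -> tuple[GrayImage, GroundTruth]:
    shape = (spec.height_px, spec.width_px)
    ps = spec.pixel_size

    half_width = spec.tubule_width / ps * tub_scale / 2.0
    tubule = _raster_tubules(geom, shape, half_width) if geom.edges else np.zeros(shape, bool)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[tubule] = TUBULE
    per_spheroid_px: list[int] = []
    sph_any = np.zeros(shape, dtype=bool)
    for c, ab, ang in zip(geom.sph_centres, geom.sph_axes, geom.sph_angles):
        m = _raster_spheroid(c, ab * sph_scale, float(ang), shape)
        per_spheroid_px.append(int(m.sum()))
        sph_any |= m
    labels[sph_any] = SPHEROID

    # ground-truth network quantities come from the generating graph
    deg = np.zeros(len(geom.nodes), dtype=int)
    for i, j in geom.edges:
        deg[i] += 1
        deg[j] += 1
    junctions = int(np.sum(deg >= 3))
    edge_len_px = sum(
        float(np.linalg.norm(geom.nodes[i] - geom.nodes[j])) for i, j in geom.edges
    )

    illum = evaluate_illumination(spec.illum_coeffs, shape)

    # texture and sensor noise use streams independent of the geometry stream
    # so that the label mask and all scene statistics are invariant to them
    rng_tex = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x7E47])
    rng_noise = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0x501E])
    img = np.full(shape, spec.background_level, dtype=np.float64)
    cells = labels != BACKGROUND
    img[cells] = spec.foreground_level
    if spec.cell_texture_sd > 0:
        texture = rng_tex.normal(0.0, spec.cell_texture_sd, shape)
        img[cells] += texture[cells]
    img += illum
    if spec.noise_sd > 0:
        img += rng_noise.normal(0.0, spec.noise_sd, shape)
    np.clip(img, 0.0, 1.0, out=img)

    gt = GroundTruth(
        label_mask=LabelMask(labels, pixel_size=ps),
        per_spheroid_areas=[n * ps**2 for n in per_spheroid_px],
        true_total_tubule_area=float(np.sum(labels == TUBULE)) * ps**2,
        true_junction_count=junctions,
        true_skeleton_length=edge_len_px * ps,
        illum_field=GrayImage(illum, pixel_size=ps),
        spheroid_centres_px=[(float(c[0]), float(c[1])) for c in geom.sph_centres],
        spheroid_axes_px=[
            (float(ab[0] * sph_scale), float(ab[1] * sph_scale)) for ab in geom.sph_axes
        ],
        spheroid_angles=[float(a) for a in geom.sph_angles],
        tubule_nodes_px=[(float(p[0]), float(p[1])) for p in geom.nodes],
        tubule_edges=list(geom.edges),
        seed=spec.seed,
    )
    return GrayImage(img, pixel_size=ps), gt


def generate_scene(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one synthetic co-culture image with its exact ground truth.

    Identical specs (including seed) produce bit-identical output.
    """
    spec.validate()
    geom = _sample_geometry(spec, max_sph_scale=1.0, max_tub_scale=1.0)
    return _render_scene(spec, geom, sph_scale=1.0, tub_scale=1.0)


def generate_timecourse(
    spec: SceneSpec,
    n_days: int,
    spheroid_growth_rate: float = 0.0,
    tubule_change_rate: float = 0.0,
) -> list[tuple[GrayImage, GroundTruth]]:
    """Day-indexed series in which true spheroid area grows by the given
    fraction per day (tubule area likewise via stroke width).

    The scene geometry (object placement, network topology) is sampled once
    so the series depicts the same field of view growing over time; day ``d``
    (1-based) scales true spheroid area by ``(1 + rate) ** (d - 1)``.
    """
    spec.validate()
    if n_days < 1:
        raise InvalidSpecError("n_days must be >= 1")
    if spheroid_growth_rate <= -1 or tubule_change_rate <= -1:
        raise InvalidSpecError("growth rates must be > -1")
    sph_final = (1.0 + spheroid_growth_rate) ** ((n_days - 1) / 2.0)  # area -> radius
    tub_final = (1.0 + tubule_change_rate) ** (n_days - 1)
    geom = _sample_geometry(
        spec, max_sph_scale=max(1.0, sph_final), max_tub_scale=max(1.0, tub_final)
    )
    series = []
    for day in range(1, n_days + 1):
        s_scale = (1.0 + spheroid_growth_rate) ** ((day - 1) / 2.0)
        t_scale = (1.0 + tubule_change_rate) ** (day - 1)
        series.append(_render_scene(spec, geom, sph_scale=s_scale, tub_scale=t_scale))
    return series


# --------------------------------------------------------------------------- #
# dose-response generator
# --------------------------------------------------------------------------- #


def generate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Tabulate (concentration, replicate, inhibition %) on a 4PL curve.

    Emulates a plate-based viability assay read in ``n_replicates`` wells per
    concentration (triplicate by default, the usual plate layout).  With
    ``noise_sd == 0`` every replicate carries the exact curve value;
    otherwise i.i.d. Gaussian noise in percent is added, reproducibly per
    seed.
    """
    spec.validate()
    c1 = np.asarray(spec.concentrations, dtype=float)
    c = np.repeat(c1, spec.n_replicates)
    rep = np.tile(np.arange(1, spec.n_replicates + 1), len(c1))
    inhib = spec.floor + (spec.ceiling - spec.floor) / (1.0 + (spec.ic50 / c) ** spec.hill_slope)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
        inhib = inhib + rng.normal(0.0, spec.noise_sd, size=c.shape)
    return pd.DataFrame({"concentration_M": c, "replicate": rep, "inhibition_pct": inhib})


# --------------------------------------------------------------------------- #
# annotation seeding from ground truth
# --------------------------------------------------------------------------- #


def annotations_from_ground_truth(
    gt: GroundTruth, n_background: int = 3, scribbles: bool = False, scribble_step: float = 6.0
):
    """Derive the annotations a user would draw on this scene.

    The quick pass (``scribbles=False``): one point per spheroid (its
    centre), one point per connected tubule-network component (a node of
    that component), and ``n_background`` points placed at the deepest
    background locations (maxima of the distance transform from cells).
    The refined pass (``scribbles=True``) instead traces each tubule with
    points every ``scribble_step`` px along its visible centreline — what an
    annotator does after seeing thin structures under-labelled — clipped to
    pixels where the tubule is actually visible (not occluded by a
    spheroid).
    """
    from .segmentation import Annotation, AnnotationSet  # local import, no cycle

    points: list[Annotation] = []
    for x, y in gt.spheroid_centres_px:
        points.append(Annotation(x=x, y=y, cls=SPHEROID))

    mask_px = gt.label_mask.pixels
    h, w = mask_px.shape
    if scribbles and gt.tubule_edges:
        for i, j in gt.tubule_edges:
            p = np.array(gt.tubule_nodes_px[i])
            q = np.array(gt.tubule_nodes_px[j])
            n = max(2, int(np.linalg.norm(q - p) / scribble_step))
            for t in np.linspace(0.0, 1.0, n):
                x, y = p + t * (q - p)
                r, c = int(round(y)), int(round(x))
                if 0 <= r < h and 0 <= c < w and mask_px[r, c] == TUBULE:
                    points.append(Annotation(x=float(c), y=float(r), cls=TUBULE))
    elif gt.tubule_edges:
        # one representative node per tubule component
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(gt.tubule_nodes_px)))
        g.add_edges_from(gt.tubule_edges)
        for comp in nx.connected_components(g):
            # prefer a node that actually has an incident edge (isolated nodes
            # rasterise to nothing)
            comp_nodes = [n for n in comp if g.degree[n] > 0]
            if not comp_nodes:
                continue
            n0 = min(comp_nodes)
            x, y = gt.tubule_nodes_px[n0]
            points.append(Annotation(x=x, y=y, cls=TUBULE))

    # background points: cover the largest background components first (an
    # enclosed pocket between tubules needs its own point), then spread any
    # remaining points across the largest component
    bg = gt.label_mask.pixels == BACKGROUND
    comp_lbl, n_comp = ndimage.label(bg)
    sizes = ndimage.sum_labels(np.ones_like(comp_lbl), comp_lbl, np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1] + 1
    dist = ndimage.distance_transform_edt(bg)
    h, w = bg.shape
    placed = 0
    for k in order[:n_background]:
        d = np.where(comp_lbl == k, dist, -1.0)
        r, c = divmod(int(np.argmax(d)), w)
        points.append(Annotation(x=float(c), y=float(r), cls=BACKGROUND))
        placed += 1
    if placed < n_background and n_comp > 0:
        d = np.where(comp_lbl == int(order[0]), dist, -1.0)
        rr, cc = np.ogrid[:h, :w]
        for _ in range(n_background - placed):
            r, c = divmod(int(np.argmax(d)), w)
            points.append(Annotation(x=float(c), y=float(r), cls=BACKGROUND))
            d[(rr - r) ** 2 + (cc - c) ** 2 <= (min(h, w) / 4) ** 2] = -1.0
    return AnnotationSet(points=points)
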