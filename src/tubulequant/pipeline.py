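"""End-to-end orchestration: correct -> segment -> measure -> compare.

A run is described by a :class:`RunConfig` (YAML on disk), processes every
image in an input directory (or a batch of seeded synthetic scenes in
simulation mode), writes one morphometric record per image as CSV, and emits
a :class:`RunManifest` — config snapshot, package version, per-stage timings
and input checksums — sufficient to replay the run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morphometrics import MorphometricRecord, compare_groups, measure
from .preprocess import PreprocessParams, preprocess_image
from .segmentation import AnnotationSet, build_hierarchy, detect_contours, propagate_annotations
from .synthetic import SceneSpec, generate_scene
from .types import GrayImage, LabelMask
from . import io as tio

logger = logging.getLogger("tubulequant")


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    The preprocessing defaults follow the working protocol: 25% downsampling,
    9x9 entropy window, radius-8 disc closing, degree-4 background
    polynomial.  ``simulate`` switches from reading images/annotations on
    disk to generating ``n_scenes`` seeded synthetic scenes whose
    ground-truth masks are measured directly.
    """

    input_dir: str = ""
    annotation_dir: str = ""
    output_dir: str = "out"
    pixel_size: float = 1.0
    downsample_factor: float = 0.25
    entropy_window: int = 9
    entropy_threshold: float | str = "auto"
    closing_radius: int = 8
    poly_degree: int = 4
    smoothing_sigma: float = 2.0
    min_spheroid_area: float = 0.0
    constrain_0_100: bool = False
    seed: int = 0
    simulate: bool = False
    n_scenes: int = 5
    scene: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.downsample_factor <= 1:
            raise ValueError("downsample_factor must be in (0, 1]")
        if self.entropy_window < 3 or self.entropy_window % 2 == 0:
            raise ValueError("entropy_window must be an odd integer >= 3")
        if self.closing_radius < 1:
            raise ValueError("closing_radius must be >= 1")
        if self.poly_degree < 0:
            raise ValueError("poly_degree must be non-negative")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not isinstance(self.entropy_threshold, str):
            if float(self.entropy_threshold) < 0:
                raise ValueError("entropy_threshold must be non-negative or 'auto'")
        if self.simulate and self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1 in simulation mode")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            downsample_factor=self.downsample_factor,
            entropy_window=self.entropy_window,
            entropy_threshold=self.entropy_threshold,
            closing_radius=self.closing_radius,
            poly_degree=self.poly_degree,
        )


@dataclass
class RunManifest:
    """Replayable record of one run."""

    config: dict
    version: str
    timings_s: dict
    input_checksums: dict
    outputs: list

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def segment_image(
    img: GrayImage, ann: AnnotationSet, sigma: float = 2.0
) -> LabelMask:
    """Corrected image -> contour hierarchy -> propagated label mask."""
    strength = detect_contours(img, sigma=sigma)
    hierarchy = build_hierarchy(strength)
    return propagate_annotations(hierarchy, ann)


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Process a batch of images into a morphometric table plus manifest.

    Disk mode reads every TIFF/PNG from ``input_dir`` with a same-stem JSON
    annotation file in ``annotation_dir``; a missing or broken annotation is
    recorded as a per-image error and the run continues.  Simulation mode
    instead generates seeded synthetic scenes and measures their ground-truth
    masks.  The records CSV and a manifest are written to ``output_dir``.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    records: list[MorphometricRecord] = []
    errors: list[dict] = []

    t0 = time.perf_counter()
    if cfg.simulate:
        base = cfg.scene or {}
        for k in range(cfg.n_scenes):
            spec = SceneSpec(**{**base, "seed": cfg.seed + k, "pixel_size": cfg.pixel_size})
            _img, gt = generate_scene(spec)
            rec = measure(
                gt.label_mask,
                image_id=f"scene_{spec.seed:04d}",
                min_spheroid_area=cfg.min_spheroid_area,
            )
            records.append(rec)
        timings["simulate_and_measure"] = time.perf_counter() - t0
    else:
        in_dir = Path(cfg.input_dir)
        images = sorted(
            p for p in in_dir.glob("*") if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not images:
            logger.warning("no input images found in %s", in_dir)
        for img_path in images:
            try:
                t_img = time.perf_counter()
                checksums[img_path.name] = _sha256(img_path)
                img = tio.read_image(img_path, pixel_size=cfg.pixel_size)
                pre = preprocess_image(img, cfg.preprocess_params())
                ann_path = Path(cfg.annotation_dir) / (img_path.stem + ".json")
                ann = tio.read_annotations(ann_path)
                mask = segment_image(pre.corrected, ann, sigma=cfg.smoothing_sigma)
                rec = measure(
                    mask, image_id=img_path.stem, min_spheroid_area=cfg.min_spheroid_area
                )
                records.append(rec)
                timings[img_path.name] = time.perf_counter() - t_img
            except Exception as exc:  # per-image failure: record and continue
                logger.error("failed on %s: %s", img_path.name, exc)
                errors.append({"image": img_path.name, "error": str(exc)})

    table = pd.DataFrame([r.to_row() for r in records])
    csv_path = out_dir / "morphometrics.csv"
    tio.write_table(csv_path, table)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        version=__version__,
        timings_s={k: round(v, 4) for k, v in timings.items()},
        input_checksums=checksums,
        outputs=[str(csv_path)] + ([{"errors": errors}] if errors else []),
    )
    manifest.write(out_dir / "manifest.json")
    return table


def summarize_timecourse(
    records: pd.DataFrame,
    group_keys: Sequence[str] = ("day", "condition"),
    metric: str = "total_tubule_area_um2",
    compare_between: Optional[tuple[str, str]] = None,
) -> pd.DataFrame:
    """Per-group mean ± SD table with day-wise two-condition comparisons.

    Groups ``records`` by ``group_keys`` and summarises ``metric``.  When
    ``compare_between`` names two conditions, a Student's t-test compares
    them within each day; groups with fewer than two replicates are skipped
    with a warning and a NaN p-value.
    """
    group_keys = list(group_keys)
    summary = (
        records.groupby(group_keys, dropna=False)[metric]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    summary["sd"] = summary["sd"].fillna(0.0)
    if compare_between is None:
        return summary

    cond_a, cond_b = compare_between
    p_values, t_stats, sig = [], [], []
    for _, row in summary.iterrows():
        day = row["day"]
        sub = records[records["day"] == day]
        a = sub.loc[sub["condition"] == cond_a, metric].to_numpy()
        b = sub.loc[sub["condition"] == cond_b, metric].to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning("day %s: fewer than 2 replicates, comparison skipped", day)
            p_values.append(np.nan)
            t_stats.append(np.nan)
            sig.append(False)
        else:
            cmpres = compare_groups(a, b)
            p_values.append(cmpres.p_value)
            t_stats.append(cmpres.t_statistic)
            sig.append(cmpres.significant)
    summary["t_statistic"] = t_stats
    summary["p_value"] = p_values
    summary["significant"] = sig
    return summary
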