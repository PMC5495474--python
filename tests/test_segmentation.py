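"""Contour hierarchy and annotation propagation contracts."""
import json

import numpy as np
import pytest

from tubulequant import (
    BACKGROUND,
    SPHEROID,
    TUBULE,
    Annotation,
    AnnotationSet,
    GrayImage,
    Polyline,
    build_hierarchy,
    detect_contours,
    propagate_annotations,
    refine_labels,
)
from tubulequant.segmentation import BoundaryStrengthMap
from tubulequant.types import MissingAnnotationError


class TestDetectContours:
    def test_constant_image_has_zero_strength(self):
        s = detect_contours(GrayImage(np.full((32, 32), 0.5)))
        assert np.all(s.pixels == 0.0)

    def test_step_edge_peaks_at_edge_column(self):
        img = np.zeros((40, 40))
        img[:, 20:] = 1.0
        s = detect_contours(GrayImage(img), sigma=1.0)
        col = int(np.argmax(s.pixels[20]))
        assert abs(col - 20) <= 1

    def test_invariant_under_intensity_inversion(self, rng):
        img = rng.random((32, 32))
        s1 = detect_contours(GrayImage(img))
        s2 = detect_contours(GrayImage(1.0 - img))
        assert np.allclose(s1.pixels, s2.pixels, atol=1e-12)


class TestBuildHierarchy:
    def test_flat_map_is_single_region(self):
        h = build_hierarchy(BoundaryStrengthMap(np.zeros((24, 24))))
        assert h.n_base == 1
        assert len(np.unique(h.cut(0.0))) == 1

    def test_closed_contour_splits_in_two_and_merges_at_its_strength(self):
        s = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        ring = np.abs(np.hypot(yy - 20, xx - 20) - 10) < 1.2
        s[ring] = 0.8
        h = build_hierarchy(BoundaryStrengthMap(s))
        assert h.n_base == 2
        assert len(h.merges) == 1
        assert h.merges[0][2] == pytest.approx(0.8, abs=0.2)
        # flood-fill oracle: the two base regions are the inside and outside
        inside = np.hypot(yy - 20, xx - 20) < 9
        outside = np.hypot(yy - 20, xx - 20) > 11
        lbl = h.base_labels
        assert len(np.unique(lbl[inside])) == 1
        assert len(np.unique(lbl[outside])) == 1
        assert lbl[inside][0] != lbl[outside][0]

    def test_merge_strengths_non_decreasing(self, rng):
        from scipy import ndimage

        s = ndimage.gaussian_filter(rng.random((48, 48)), 2)
        s = (s - s.min()) / np.ptp(s)
        h = build_hierarchy(BoundaryStrengthMap(s))
        strengths = [m[2] for m in h.merges]
        assert all(a <= b for a, b in zip(strengths, strengths[1:]))
        assert len(np.unique(h.cut(h.max_strength))) == 1


def _two_region_hierarchy():
    s = np.zeros((20, 20))
    s[:, 10] = 1.0
    return build_hierarchy(BoundaryStrengthMap(s))


class TestPropagation:
    def test_every_region_annotated_equals_direct_painting(self):
        h = _two_region_hierarchy()
        left = Annotation(x=2.0, y=10.0, cls=TUBULE)
        right = Annotation(x=18.0, y=10.0, cls=SPHEROID)
        mask = propagate_annotations(h, AnnotationSet(points=[left, right]))
        assert mask.pixels[10, 2] == TUBULE
        assert mask.pixels[10, 18] == SPHEROID
        assert set(np.unique(mask.pixels)) == {TUBULE, SPHEROID}

    def test_single_background_point_labels_everything(self, rng):
        from scipy import ndimage

        s = ndimage.gaussian_filter(rng.random((32, 32)), 2)
        h = build_hierarchy(BoundaryStrengthMap(s - s.min()))
        mask = propagate_annotations(
            h, AnnotationSet(points=[Annotation(x=5.0, y=5.0, cls=BACKGROUND)])
        )
        assert np.all(mask.pixels == BACKGROUND)

    def test_no_unlabelled_pixels_remain(self, rng):
        from scipy import ndimage

        s = ndimage.gaussian_filter(rng.random((48, 48)), 1.5)
        h = build_hierarchy(BoundaryStrengthMap(s - s.min()))
        mask = propagate_annotations(
            h,
            AnnotationSet(points=[
                Annotation(x=5.0, y=5.0, cls=BACKGROUND),
                Annotation(x=40.0, y=40.0, cls=SPHEROID),
            ]),
        )
        assert 255 not in np.unique(mask.pixels)

    def test_empty_annotation_set_raises(self):
        with pytest.raises(MissingAnnotationError):
            propagate_annotations(_two_region_hierarchy(), AnnotationSet())

    def test_deterministic(self, rng):
        from scipy import ndimage

        s = ndimage.gaussian_filter(rng.random((48, 48)), 1.5)
        h = build_hierarchy(BoundaryStrengthMap(s - s.min()))
        ann = AnnotationSet(points=[
            Annotation(x=5.0, y=5.0, cls=BACKGROUND),
            Annotation(x=40.0, y=40.0, cls=TUBULE),
        ])
        m1 = propagate_annotations(h, ann)
        m2 = propagate_annotations(h, ann)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_annotated_region_keeps_class_when_other_class_added_nearby(self):
        h = _two_region_hierarchy()
        ann = AnnotationSet(points=[
            Annotation(x=2.0, y=10.0, cls=TUBULE),
            Annotation(x=18.0, y=10.0, cls=SPHEROID),
        ])
        mask = propagate_annotations(h, ann)
        # an extra spheroid point in the right region must not flip the left
        extra = AnnotationSet(points=[Annotation(x=15.0, y=5.0, cls=SPHEROID)])
        refined = refine_labels(mask, h, extra)
        assert refined.pixels[10, 2] == TUBULE


class TestScribbleRefinement:
    def test_tubule_scribbles_recover_both_classes(self):
        # the refined annotation pass traces thin tubules, lifting their
        # recall without sacrificing the spheroids
        from tubulequant import (
            PreprocessParams,
            SceneSpec,
            annotations_from_ground_truth,
            generate_scene,
            preprocess_image,
            segment_image,
        )

        for seed in (0, 3):
            spec = SceneSpec(width_px=256, height_px=256, n_spheroids=3,
                             n_tubule_nodes=8, seed=seed)
            img, gt = generate_scene(spec)
            res = preprocess_image(img, PreprocessParams(downsample_factor=1.0))
            ann = annotations_from_ground_truth(gt, scribbles=True)
            mask = segment_image(res.corrected, ann)
            assert (mask.pixels == gt.label_mask.pixels).mean() >= 0.95
            tub = gt.label_mask.pixels == TUBULE
            sph = gt.label_mask.pixels == SPHEROID
            assert (mask.pixels[tub] == TUBULE).mean() >= 0.9
            assert (mask.pixels[sph] == SPHEROID).mean() >= 0.9


class TestRefinement:
    def test_empty_extra_is_identity(self):
        h = _two_region_hierarchy()
        ann = AnnotationSet(points=[Annotation(x=2.0, y=10.0, cls=BACKGROUND)])
        mask = propagate_annotations(h, ann)
        refined = refine_labels(mask, h, AnnotationSet())
        assert np.array_equal(refined.pixels, mask.pixels)

    def test_reannotation_flips_exactly_that_region(self):
        h = _two_region_hierarchy()
        ann = AnnotationSet(points=[Annotation(x=2.0, y=10.0, cls=BACKGROUND)])
        mask = propagate_annotations(h, ann)
        assert np.all(mask.pixels == BACKGROUND)
        extra = AnnotationSet(points=[Annotation(x=18.0, y=10.0, cls=SPHEROID)])
        refined = refine_labels(mask, h, extra)
        right = h.base_labels == h.base_labels[10, 18]
        assert np.all(refined.pixels[right] == SPHEROID)
        assert np.all(refined.pixels[~right] == BACKGROUND)

    def test_idempotent_for_fixed_union(self):
        h = _two_region_hierarchy()
        ann = AnnotationSet(points=[Annotation(x=2.0, y=10.0, cls=BACKGROUND)])
        extra = AnnotationSet(points=[Annotation(x=18.0, y=10.0, cls=TUBULE)])
        m1 = refine_labels(propagate_annotations(h, ann), h, extra)
        m2 = refine_labels(m1, h, AnnotationSet())
        assert np.array_equal(m1.pixels, m2.pixels)


class TestAnnotationSet:
    def test_json_round_trip(self):
        ann = AnnotationSet(
            points=[Annotation(x=1.0, y=2.0, cls=SPHEROID)],
            polylines=[Polyline(points=[(0.0, 0.0), (5.0, 5.0)], cls=TUBULE)],
        )
        back = AnnotationSet.from_json(ann.to_json())
        assert back.points == ann.points
        assert back.polylines[0].cls == TUBULE

    def test_bare_point_list_accepted(self):
        back = AnnotationSet.from_json(json.dumps([{"x": 1, "y": 2, "class": "tubule"}]))
        assert back.points[0].cls == TUBULE

    def test_polyline_rasterises_along_the_segment(self):
        ann = AnnotationSet(polylines=[Polyline(points=[(0.0, 0.0), (4.0, 0.0)], cls=TUBULE)])
        pts = ann.rasterised_points((10, 10))
        assert len(pts) == 5
        assert all(cls == TUBULE for _r, _c, cls in pts)

    def test_out_of_frame_coordinates_rejected(self):
        ann = AnnotationSet(points=[Annotation(x=100.0, y=2.0, cls=TUBULE)])
        with pytest.raises(ValueError):
            ann.rasterised_points((10, 10))

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet.from_json(json.dumps([{"x": 1, "y": 2, "class": "nucleus"}]))
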