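import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from cgom.segmentation import (
    Annotation,
    ExternalSegmenterAdapter,
    InstanceMask,
    LabelDataset,
    OracleSegmenter,
    SegmentationError,
    dataset_summary,
    erode_masks,
    point_in_mask,
    rasterize_polygon,
    read_label_dataset,
    write_coco_dataset,
)


def square_mask(side=10, size=(20, 20), offset=(0, 0)):
    m = np.zeros(size, dtype=bool)
    m[offset[1]: offset[1] + side, offset[0]: offset[0] + side] = True
    return m


class TestRasterization:
    def test_axis_aligned_square_fills_exactly(self):
        poly = [(0, 0), (10, 0), (10, 10), (0, 10)]
        mask = rasterize_polygon(poly, 64, 64)
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_agrees_with_shapely_point_in_polygon(self):
        """Center-sampling rasterization vs. an independent geometric oracle."""
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(3, 7)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(5, 25, n)
            verts = [
                (32 + ri * np.cos(a), 32 + ri * np.sin(a))
                for ri, a in zip(r, angles)
            ]
            mask = rasterize_polygon(verts, 64, 64)
            poly = Polygon(verts)
            brute = np.zeros((64, 64), dtype=bool)
            for i in range(64):
                for j in range(64):
                    brute[i, j] = poly.contains(Point(j + 0.5, i + 0.5))
            assert (mask == brute).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(SegmentationError):
            rasterize_polygon([(0, 0), (1, 1)], 10, 10)


class TestPointInMask:
    def test_inside_outside_and_bounds(self):
        m = square_mask(10)
        assert point_in_mask(m, 5, 5)
        assert not point_in_mask(m, 15, 5)
        assert not point_in_mask(m, -1, 5)
        assert not point_in_mask(m, 5, 25)

    def test_boundary_pixels_contained_half_open(self):
        """Every pixel of the mask, including its border row/column, hits;
        the first coordinates past them miss."""
        m = square_mask(10)
        for c in range(10):
            assert point_in_mask(m, c, 0)
            assert point_in_mask(m, 0, c)
            assert point_in_mask(m, c + 0.999, 9.999)
        assert not point_in_mask(m, 10.0, 5.0)
        assert not point_in_mask(m, 5.0, 10.0)


class TestErosion:
    def test_radius_zero_is_identity(self):
        masks = [InstanceMask("a", square_mask(10))]
        out = erode_masks(masks, 0)
        assert (out[0].mask == masks[0].mask).all()

    def test_square_shrinks_by_radius_ring(self):
        """Brute-force check: a 10x10 square eroded with a 3x3 element is the
        8x8 square of pixels whose full neighbourhood lies inside."""
        m = square_mask(10, offset=(2, 2))
        (out,) = erode_masks([InstanceMask("a", m)], 1)
        brute = np.zeros_like(m)
        for i in range(1, m.shape[0] - 1):
            for j in range(1, m.shape[1] - 1):
                brute[i, j] = m[i - 1: i + 2, j - 1: j + 2].all()
        assert (out.mask == brute).all()
        assert out.area_px == 64

    @given(radii=st.tuples(st.integers(0, 4), st.integers(0, 4)))
    @settings(deadline=None)
    def test_erosion_monotone_in_radius(self, radii):
        a, b = min(radii), max(radii)
        rng = np.random.default_rng(3)
        m = rng.random((24, 24)) > 0.4
        (ea,) = erode_masks([InstanceMask("x", m)], a)
        (eb,) = erode_masks([InstanceMask("x", m)], b)
        assert not (eb.mask & ~ea.mask).any()  # eroded(b) ⊆ eroded(a)
        assert not (ea.mask & ~m).any()  # never adds pixels

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            erode_masks([], -1)


def _study_like_dataset():
    """72 annotated images with 264 syringe and 32 bottle representations."""
    annotations = []
    per_image_syringe = [4] * 48 + [3] * 24  # 192 + 72 = 264
    for frame, n_syr in enumerate(per_image_syringe):
        for k in range(n_syr):
            annotations.append(
                Annotation(frame, "syringe",
                           polygon=((5 * k, 0), (5 * k + 4, 0), (5 * k + 4, 4), (5 * k, 4)))
            )
    for frame in range(32):
        annotations.append(
            Annotation(frame, "bottle", polygon=((30, 30), (40, 30), (40, 40), (30, 40)))
        )
    return LabelDataset(
        width=64, height=48, label_set=("syringe", "bottle"),
        frame_indices=tuple(range(72)), annotations=annotations,
    )


class TestLabelDataset:
    def test_summary_counts_images_and_representations(self):
        n_images, counts = dataset_summary(_study_like_dataset())
        assert n_images == 72
        assert counts == {"syringe": 264, "bottle": 32}

    def test_summary_of_empty_dataset(self):
        ds = LabelDataset(10, 10, ("a",), (0, 1), [])
        assert dataset_summary(ds) == (2, {})

    def test_concat_counts_are_additive(self):
        a = _study_like_dataset()
        b = LabelDataset(
            64, 48, ("bottle",), (100, 101),
            [Annotation(100, "bottle", polygon=((0, 0), (4, 0), (4, 4)))],
        )
        n, counts = dataset_summary(a.concat(b))
        assert n == 74
        assert counts == {"syringe": 264, "bottle": 33}

    def test_unknown_frame_reference_rejected(self):
        with pytest.raises(SegmentationError, match="unknown frame"):
            LabelDataset(
                10, 10, ("a",), (0,),
                [Annotation(5, "a", polygon=((0, 0), (2, 0), (2, 2)))],
            )

    def test_label_outside_declared_set_rejected(self):
        with pytest.raises(SegmentationError, match="label set"):
            LabelDataset(
                10, 10, ("a",), (0,),
                [Annotation(0, "b", polygon=((0, 0), (2, 0), (2, 2)))],
            )


class TestOracleSegmenter:
    def test_returns_rasterized_ground_truth(self):
        ds = _study_like_dataset()
        seg = OracleSegmenter(ds)
        masks = seg(0)
        assert len(masks) == 5  # 4 syringes + 1 bottle on frame 0
        assert all(m.confidence == 1.0 for m in masks)
        expected = ds.masks_for_frame(0)
        for got, want in zip(masks, expected):
            assert (got.mask == want.mask).all()

    def test_unannotated_frame_is_empty(self):
        ds = LabelDataset(10, 10, ("a",), (0, 1), [])
        assert OracleSegmenter(ds)(1) == []

    def test_unknown_frame_warns_and_returns_nothing(self):
        ds = LabelDataset(10, 10, ("a",), (0,), [])
        with pytest.warns(UserWarning, match="absent"):
            assert OracleSegmenter(ds)(999) == []


class TestExternalSegmenterAdapter:
    def test_threshold_filters_low_confidence(self):
        m = square_mask(4)
        backend = lambda i: [("a", m, 0.9), ("a", m, 0.3), ("b", m, 0.5)]
        masks = ExternalSegmenterAdapter(backend, confidence_threshold=0.5)(0)
        assert [(x.class_label, x.confidence) for x in masks] == [("a", 0.9), ("b", 0.5)]

    def test_multiple_instances_of_one_class_retained(self):
        m = square_mask(4)
        backend = lambda i: [("a", m, 0.9), ("a", m, 0.8)]
        assert len(ExternalSegmenterAdapter(backend)(0)) == 2

    def test_backend_failure_names_the_frame(self):
        def backend(i):
            raise RuntimeError("boom")

        with pytest.raises(SegmentationError, match="frame 7"):
            ExternalSegmenterAdapter(backend)(7)


class TestDatasetIO:
    def test_coco_round_trip(self, tmp_path):
        ds = _study_like_dataset()
        path = tmp_path / "labels.json"
        write_coco_dataset(ds, path)
        back = read_label_dataset(path)
        assert dataset_summary(back) == dataset_summary(ds)
        assert (back.width, back.height) == (ds.width, ds.height)
        for frame in (0, 50, 71):
            for got, want in zip(back.masks_for_frame(frame), ds.masks_for_frame(frame)):
                assert got.class_label == want.class_label
                assert (got.mask == want.mask).all()

    def test_coco_unknown_image_reference_rejected(self, tmp_path):
        doc = {
            "images": [{"id": 1, "file_name": "frame_000000.png", "width": 10, "height": 10}],
            "annotations": [{"id": 1, "image_id": 99, "category_id": 1,
                             "segmentation": [[0, 0, 4, 0, 4, 4]]}],
            "categories": [{"id": 1, "name": "a"}],
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(SegmentationError, match="unknown"):
            read_label_dataset(p)

    def test_coco_short_polygon_rejected(self, tmp_path):
        doc = {
            "images": [{"id": 1, "file_name": "frame_000000.png", "width": 10, "height": 10}],
            "annotations": [{"id": 1, "image_id": 1, "category_id": 1,
                             "segmentation": [[0, 0, 4, 0]]}],
            "categories": [{"id": 1, "name": "a"}],
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(SegmentationError, match="fewer than 3"):
            read_label_dataset(p)

    def test_png_mask_directory(self, tmp_path):
        arr = np.zeros((12, 16), dtype=np.uint8)
        arr[2:6, 3:9] = 1
        arr[8:11, 10:14] = 2
        Image.fromarray(arr).save(tmp_path / "frame_000004.png")
        (tmp_path / "labels.json").write_text(json.dumps({"1": "syringe", "2": "bottle"}))
        ds = read_label_dataset(tmp_path)
        assert ds.frame_indices == (4,)
        masks = {m.class_label: m for m in ds.masks_for_frame(4)}
        assert masks["syringe"].area_px == 24
        assert masks["bottle"].area_px == 12
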