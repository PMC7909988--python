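"""Instance masks, label datasets and the segmenter contract.

An instance mask is one detected or hand-labelled object: a class label
(the AOI name), a binary pixel grid covering the object's close contour,
and a confidence. Label datasets hold ground-truth annotations — either
COCO-style polygons or indexed PNG masks — and back the *oracle*
segmenter, which plays the role of a perfectly trained network in tests
and simulations. Real detection backends (e.g. a Mask R-CNN) plug in
through :class:`ExternalSegmenterAdapter`; no network ships here.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Callable, Protocol

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

__all__ = [
    "InstanceMask",
    "Annotation",
    "LabelDataset",
    "Segmenter",
    "OracleSegmenter",
    "ExternalSegmenterAdapter",
    "SegmentationError",
    "read_label_dataset",
    "write_coco_dataset",
    "dataset_summary",
    "point_in_mask",
    "rasterize_polygon",
    "erode_masks",
]


class SegmentationError(ValueError):
    """A label dataset or segmenter backend violates its contract."""


@dataclass(frozen=True)
class InstanceMask:
    """One object instance: AOI class label, binary mask, confidence."""

    class_label: str
    mask: np.ndarray  # bool, (height, width)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D pixel grid")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area_px(self) -> int:
        """Number of set pixels."""
        return int(self.mask.sum())


@dataclass(frozen=True)
class Annotation:
    """One ground-truth object on one frame.

    Exactly one of ``polygon`` (list of (x, y) vertices in pixel
    coordinates) or ``mask`` (binary grid at frame resolution) is set.
    """

    frame_index: int
    class_label: str
    polygon: tuple[tuple[float, float], ...] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("annotation needs exactly one of polygon or mask")
        if self.polygon is not None and len(self.polygon) < 3:
            raise SegmentationError(
                f"frame {self.frame_index}: polygon with "
                f"{len(self.polygon)} < 3 vertices"
            )


def rasterize_polygon(
    polygon, width: int, height: int
) -> np.ndarray:
    """Rasterize a polygon to a binary mask at the given resolution.

    A pixel (i, j) is inside iff its center (j + 0.5, i + 0.5) lies
    inside the polygon — the unambiguous center-sampling rule, testable
    against brute-force point-in-polygon.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise SegmentationError("polygon must be >=3 (x, y) vertices")
    # restrict the center test to the polygon's bounding box
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())) + 1, width)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())) + 1, height)
    mask = np.zeros((height, width), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    xs, ys = np.meshgrid(
        np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5
    )
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    inside = MplPath(poly).contains_points(centers)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


@dataclass
class LabelDataset:
    """Ground-truth instance annotations over a set of frames.

    Frames with no annotations are valid (nothing of interest in view).
    ``frame_indices`` lists every frame the dataset covers, annotated or
    not; a frame absent from it is *unknown* to the dataset, which the
    oracle segmenter reports as "nothing detected" with a warning.
    """

    width: int
    height: int
    label_set: tuple[str, ...]
    frame_indices: tuple[int, ...] = ()
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.frame_indices)
        for ann in self.annotations:
            if ann.frame_index not in known:
                raise SegmentationError(
                    f"annotation references unknown frame {ann.frame_index}"
                )
            if ann.class_label not in self.label_set:
                raise SegmentationError(
                    f"annotation label '{ann.class_label}' not in the "
                    f"declared label set {self.label_set}"
                )

    def _annotations_by_frame(self) -> dict[int, list[Annotation]]:
        # built lazily; large scenes query a few hundred middle frames only
        cache = self.__dict__.get("_frame_map")
        if cache is None:
            cache = {}
            for ann in self.annotations:
                cache.setdefault(ann.frame_index, []).append(ann)
            self.__dict__["_frame_map"] = cache
        return cache

    def masks_for_frame(self, frame_index: int) -> list[InstanceMask]:
        """Rasterize this frame's annotations to instance masks (confidence 1)."""
        out = []
        for ann in self._annotations_by_frame().get(frame_index, []):
            if ann.mask is not None:
                m = np.asarray(ann.mask, dtype=bool)
                if m.shape != (self.height, self.width):
                    raise SegmentationError(
                        f"frame {frame_index}: mask shape {m.shape} does not "
                        f"match frame {(self.height, self.width)}"
                    )
            else:
                m = rasterize_polygon(ann.polygon, self.width, self.height)
            out.append(InstanceMask(ann.class_label, m, 1.0))
        return out

    def concat(self, other: "LabelDataset") -> "LabelDataset":
        """Concatenate two datasets over disjoint frame ranges."""
        if (self.width, self.height) != (other.width, other.height):
            raise SegmentationError("cannot concatenate datasets of different resolution")
        if set(self.frame_indices) & set(other.frame_indices):
            raise SegmentationError("datasets overlap in frame indices")
        return LabelDataset(
            width=self.width,
            height=self.height,
            label_set=tuple(dict.fromkeys(self.label_set + other.label_set)),
            frame_indices=self.frame_indices + other.frame_indices,
            annotations=self.annotations + other.annotations,
        )


def dataset_summary(dataset: LabelDataset) -> tuple[int, dict[str, int]]:
    """Image count and per-class annotation counts.

    Both the number of annotated images and the total number of object
    representations per class matter for segmentation quality, so both
    are reported.
    """
    counts: dict[str, int] = {}
    for ann in dataset.annotations:
        counts[ann.class_label] = counts.get(ann.class_label, 0) + 1
    return len(dataset.frame_indices), counts


class Segmenter(Protocol):
    """Anything that produces instance masks for a frame index.

    Must be deterministic for a fixed frame and backend state and return
    an empty list when nothing is detected.
    """

    def __call__(self, frame_index: int) -> list[InstanceMask]: ...


class OracleSegmenter:
    """Ground-truth segmenter: returns each frame's labelled masks exactly.

    Stands in for a perfectly trained detection network; every mask has
    confidence 1.0. Frames the dataset does not cover yield an empty
    list ("nothing detected") with a warning.
    """

    def __init__(self, dataset: LabelDataset):
        self.dataset = dataset
        self._known = frozenset(dataset.frame_indices)

    def __call__(self, frame_index: int) -> list[InstanceMask]:
        if frame_index not in self._known:
            warnings.warn(
                f"frame {frame_index} absent from the label dataset; "
                "treating as nothing detected",
                stacklevel=2,
            )
            return []
        return self.dataset.masks_for_frame(frame_index)


class ExternalSegmenterAdapter:
    """Adapt a user-supplied detection callable to the segmenter contract.

    The callable receives the frame index and must return an iterable of
    ``(class_label, mask, confidence)`` triples; detections below the
    confidence threshold are dropped. Class-level merging of multiple
    instances happens later, in mapping.
    """

    def __init__(
        self,
        backend: Callable[[int], list[tuple[str, np.ndarray, float]]],
        confidence_threshold: float = 0.5,
    ):
        self.backend = backend
        self.confidence_threshold = confidence_threshold

    def __call__(self, frame_index: int) -> list[InstanceMask]:
        try:
            raw = self.backend(frame_index)
        except Exception as exc:
            raise SegmentationError(
                f"segmenter backend failed on frame {frame_index}: {exc}"
            ) from exc
        return [
            InstanceMask(label, mask, conf)
            for label, mask, conf in raw
            if conf >= self.confidence_threshold
        ]


def point_in_mask(mask: np.ndarray, x: float, y: float) -> bool:
    """Pixel-containment test on the half-open grid [0, W) × [0, H).

    The gaze coordinate (x, y) maps to pixel (floor x, floor y); the
    test is true iff that pixel lies inside the grid and is set.
    Out-of-bounds coordinates simply return False.
    """
    mask = np.asarray(mask, dtype=bool)
    j = int(np.floor(x))
    i = int(np.floor(y))
    if not (0 <= j < mask.shape[1] and 0 <= i < mask.shape[0]):
        return False
    return bool(mask[i, j])


def erode_masks(masks: list[InstanceMask], radius_px: int) -> list[InstanceMask]:
    """Morphologically erode each mask with a (2r+1)² square element.

    Simulates the typical segmentation failure mode where predicted
    masks under-fill the object contour. Radius 0 is the identity;
    erosion never adds pixels.
    """
    if radius_px < 0 or int(radius_px) != radius_px:
        raise ValueError("erosion radius must be a non-negative integer")
    radius_px = int(radius_px)
    if radius_px == 0:
        return list(masks)
    selem = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    return [
        InstanceMask(
            m.class_label,
            ndimage.binary_erosion(m.mask, structure=selem),
            m.confidence,
        )
        for m in masks
    ]


# ---------------------------------------------------------------------------
# Dataset I/O: COCO-style polygon JSON and indexed-PNG mask directories
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)\D*$")


def _frame_index_from_name(name: str, fallback: int) -> int:
    m = _FRAME_RE.search(FsPath(name).stem)
    return int(m.group(1)) if m else fallback


def read_label_dataset(path, format: str | None = None) -> LabelDataset:
    """Read a label dataset from disk.

    Two formats are supported:

    ``"coco"``
        A single JSON file with ``images``, ``annotations`` (polygon
        ``segmentation`` as a flat ``[x1, y1, x2, y2, ...]`` list) and
        ``categories``. The frame index of an image is taken from an
        explicit ``frame_index`` key when present, else from trailing
        digits in ``file_name``, else from its list position.
    ``"png"``
        A directory of indexed PNG masks (pixel value = instance index,
        0 = background) named ``frame_<index>.png``, next to a
        ``labels.json`` map ``{"<png value>": "<class label>"}`` and a
        ``meta.json`` with ``width``/``height``.

    The format is inferred from the path when not given.
    """
    path = FsPath(path)
    if format is None:
        format = "coco" if path.suffix == ".json" else "png"
    if format == "coco":
        return _read_coco(path)
    if format == "png":
        return _read_png_dir(path)
    raise ValueError(f"unknown label-dataset format '{format}'")


def _read_coco(path: FsPath) -> LabelDataset:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    categories = {c["id"]: c["name"] for c in doc.get("categories", [])}
    images = doc.get("images", [])
    if not images:
        raise SegmentationError(f"{path}: no images in dataset")
    width = images[0].get("width")
    height = images[0].get("height")
    if width is None or height is None:
        raise SegmentationError(f"{path}: images must declare width and height")
    frame_of_image: dict[int, int] = {}
    for pos, img in enumerate(images):
        frame = img.get("frame_index")
        if frame is None:
            frame = _frame_index_from_name(img.get("file_name", ""), pos)
        frame_of_image[img["id"]] = int(frame)
    annotations = []
    for ann in doc.get("annotations", []):
        image_id = ann["image_id"]
        if image_id not in frame_of_image:
            raise SegmentationError(
                f"{path}: annotation {ann.get('id')} references unknown "
                f"image {image_id}"
            )
        label = categories.get(ann["category_id"])
        if label is None:
            raise SegmentationError(
                f"{path}: annotation {ann.get('id')} references unknown "
                f"category {ann['category_id']}"
            )
        seg = ann["segmentation"]
        ring = seg[0] if seg and isinstance(seg[0], (list, tuple)) else seg
        if len(ring) < 6:
            raise SegmentationError(
                f"{path}: annotation {ann.get('id')}: polygon with fewer "
                "than 3 vertices"
            )
        polygon = tuple(
            (float(ring[i]), float(ring[i + 1])) for i in range(0, len(ring), 2)
        )
        annotations.append(
            Annotation(frame_of_image[image_id], label, polygon=polygon)
        )
    return LabelDataset(
        width=int(width),
        height=int(height),
        label_set=tuple(categories.values()),
        frame_indices=tuple(frame_of_image.values()),
        annotations=annotations,
    )


def _read_png_dir(path: FsPath) -> LabelDataset:
    from PIL import Image

    labels_file = path / "labels.json"
    meta_file = path / "meta.json"
    if not labels_file.exists():
        raise SegmentationError(f"{path}: missing labels.json label-index map")
    with open(labels_file, encoding="utf-8") as fh:
        index_map = {int(k): v for k, v in json.load(fh).items()}
    if meta_file.exists():
        with open(meta_file, encoding="utf-8") as fh:
            meta = json.load(fh)
        width, height = int(meta["width"]), int(meta["height"])
    else:
        width = height = None
    frames = []
    annotations = []
    for pos, png in enumerate(sorted(path.glob("*.png"))):
        frame = _frame_index_from_name(png.name, pos)
        arr = np.asarray(Image.open(png))
        if width is None:
            height, width = arr.shape[:2]
        frames.append(frame)
        for value in np.unique(arr):
            if value == 0:
                continue
            if int(value) not in index_map:
                raise SegmentationError(
                    f"{png}: pixel value {value} not in labels.json"
                )
            annotations.append(
                Annotation(frame, index_map[int(value)], mask=(arr == value))
            )
    if width is None:
        raise SegmentationError(f"{path}: no PNG masks and no meta.json")
    return LabelDataset(
        width=width,
        height=height,
        label_set=tuple(dict.fromkeys(index_map.values())),
        frame_indices=tuple(frames),
        annotations=annotations,
    )


def write_coco_dataset(dataset: LabelDataset, path) -> None:
    """Write a polygon dataset as COCO-style JSON.

    Mask-backed annotations cannot be written (no polygon tracing here);
    they raise.
    """
    categories = [
        {"id": i + 1, "name": name} for i, name in enumerate(dataset.label_set)
    ]
    cat_id = {c["name"]: c["id"] for c in categories}
    images = [
        {
            "id": i + 1,
            "file_name": f"frame_{frame:06d}.png",
            "frame_index": frame,
            "width": dataset.width,
            "height": dataset.height,
        }
        for i, frame in enumerate(dataset.frame_indices)
    ]
    image_id = {img["frame_index"]: img["id"] for img in images}
    annotations = []
    for i, ann in enumerate(dataset.annotations):
        if ann.polygon is None:
            raise SegmentationError(
                "cannot export mask-backed annotations to COCO polygons"
            )
        flat = [coord for vertex in ann.polygon for coord in vertex]
        annotations.append(
            {
                "id": i + 1,
                "image_id": image_id[ann.frame_index],
                "category_id": cat_id[ann.class_label],
                "segmentation": [flat],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"images": images, "annotations": annotations, "categories": categories},
            fh,
        )
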