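"""Synthetic recordings: scenes with known masks plus simulated gaze.

No public recordings exist for this kind of handling-task study, so the
whole pipeline is exercised on synthetic material: frames containing
simple geometric objects whose ground-truth masks are known exactly
(rendering and annotation share one geometry routine), and fixation
streams whose intended targets are recorded, giving a ground-truth
mapping against which the automatic one can be scored.

The default scene is a miniature of the study's setup: a 320x240 px
scene at 24 frames/s containing five elongated "syringe" rectangles and
one round "bottle", so class imbalance (many syringe representations,
few bottle ones) can be emulated. Gaze noise defaults to the tracker
accuracy of 0.5 degrees of visual angle, converted to pixels via a
60-degree horizontal field of view over the frame width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cgom.io_gaze import (
    BACKGROUND_LABEL,
    FixationEvent,
    MappedFixation,
    RecordingMeta,
    write_mapped_fixations,
)
from cgom.mapping import frame_span, middle_frame
from cgom.segmentation import (
    Annotation,
    LabelDataset,
    erode_masks,
    write_coco_dataset,
)

__all__ = [
    "ObjectSpec",
    "SceneSpec",
    "GazeSimConfig",
    "SceneError",
    "degrees_to_pixels",
    "default_scene_spec",
    "render_scene",
    "SyntheticFrameSource",
    "simulate_gaze",
    "degrade",
    "export_recording",
]

#: horizontal field of view assumed for degree↔pixel conversion
FOV_DEG = 60.0


class SceneError(ValueError):
    """A scene specification is geometrically invalid."""


def degrees_to_pixels(degrees: float, frame_width: int, fov_deg: float = FOV_DEG) -> float:
    """Convert visual angle to pixels for a scene camera.

    Assumes the frame width spans ``fov_deg`` degrees horizontally
    (small-angle linear approximation, adequate near the image centre).
    """
    return degrees * frame_width / fov_deg


@dataclass(frozen=True)
class ObjectSpec:
    """One object instance in the scene.

    ``shape`` is ``"rectangle"`` (params x, y, w, h), ``"circle"``
    (params cx, cy, r) or ``"polygon"`` (params vertices). ``velocity``
    is an optional (dx, dy) drift in pixels per frame.
    """

    class_label: str
    shape: str
    params: dict
    velocity: tuple[float, float] = (0.0, 0.0)

    def polygon_at(self, frame: int) -> tuple[tuple[float, float], ...]:
        """Outline polygon at the given frame, motion applied."""
        dx = self.velocity[0] * frame
        dy = self.velocity[1] * frame
        if self.shape == "rectangle":
            x, y = self.params["x"] + dx, self.params["y"] + dy
            w, h = self.params["w"], self.params["h"]
            return ((x, y), (x + w, y), (x + w, y + h), (x, y + h))
        if self.shape == "circle":
            cx, cy = self.params["cx"] + dx, self.params["cy"] + dy
            r = self.params["r"]
            theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
            return tuple(
                (cx + r * np.cos(t), cy + r * np.sin(t)) for t in theta
            )
        if self.shape == "polygon":
            return tuple((x + dx, y + dy) for x, y in self.params["vertices"])
        raise SceneError(f"unknown shape '{self.shape}'")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and timing of a synthetic recording."""

    width: int = 320
    height: int = 240
    fps: float = 24.0
    n_frames: int = 240
    objects: tuple[ObjectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))
        if self.width <= 0 or self.height <= 0 or self.fps <= 0:
            raise SceneError("width, height and fps must be positive")
        if self.n_frames <= 0:
            raise SceneError("n_frames must be positive")
        for obj in self.objects:
            for frame in (0, self.n_frames - 1):
                poly = np.asarray(obj.polygon_at(frame))
                if (
                    poly[:, 0].min() < 0
                    or poly[:, 1].min() < 0
                    or poly[:, 0].max() > self.width
                    or poly[:, 1].max() > self.height
                ):
                    raise SceneError(
                        f"object '{obj.class_label}' leaves the frame at "
                        f"frame {frame}"
                    )

    @property
    def meta(self) -> RecordingMeta:
        return RecordingMeta(self.width, self.height, self.fps)

    @property
    def duration_ms(self) -> float:
        return self.n_frames * 1000.0 / self.fps

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(o.class_label for o in self.objects))


def default_scene_spec(n_frames: int = 240, seed: int = 0) -> SceneSpec:
    """The study-in-miniature scene: five syringes, one bottle, static."""
    syringes = [
        ObjectSpec("syringe", "rectangle", {"x": x, "y": y, "w": 60, "h": 14})
        for x, y in [(20, 20), (180, 30), (40, 100), (200, 120), (90, 200)]
    ]
    bottle = ObjectSpec("bottle", "circle", {"cx": 280, "cy": 200, "r": 22})
    return SceneSpec(
        width=320,
        height=240,
        fps=24.0,
        n_frames=n_frames,
        objects=tuple(syringes) + (bottle,),
        seed=seed,
    )


def render_scene(spec: SceneSpec) -> tuple["SyntheticFrameSource", LabelDataset]:
    """Build the frame source and the exactly matching label dataset.

    The dataset annotates every object's outline polygon on every frame;
    masks rasterize from those same polygons on demand, and the frame
    source paints its pixels from the same rasterization, so the labels
    are pixel-exact by construction.
    """
    annotations = [
        Annotation(frame, obj.class_label, polygon=obj.polygon_at(frame))
        for frame in range(spec.n_frames)
        for obj in spec.objects
    ]
    dataset = LabelDataset(
        width=spec.width,
        height=spec.height,
        label_set=spec.label_set,
        frame_indices=tuple(range(spec.n_frames)),
        annotations=annotations,
    )
    return SyntheticFrameSource(spec, dataset), dataset


class SyntheticFrameSource:
    """Renders scene frames on demand as 8-bit grayscale arrays.

    Each object class paints a distinct gray level over a black
    background; rendering is deterministic, so identical specs yield
    bit-identical frames.
    """

    def __init__(self, spec: SceneSpec, dataset: LabelDataset):
        self._spec = spec
        self._dataset = dataset
        self.n_frames = spec.n_frames
        self.fps = spec.fps
        self.width = spec.width
        self.height = spec.height
        labels = spec.label_set
        step = 200 // max(len(labels), 1)
        self._intensity = {
            label: 55 + step * (i + 1) for i, label in enumerate(labels)
        }

    def get_frame(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_frames:
            raise IndexError(f"frame {index} outside [0, {self.n_frames})")
        frame = np.zeros((self.height, self.width), dtype=np.uint8)
        for mask in self._dataset.masks_for_frame(index):
            frame[mask.mask] = self._intensity[mask.class_label]
        return frame


@dataclass(frozen=True)
class GazeSimConfig:
    """Parameters of the simulated fixation stream.

    ``target_mix`` gives the probability that a fixation is aimed at
    each object class or at the background (``"BG"``); the default
    mirrors the study's fixation distribution (roughly 46% syringe, 2%
    bottle, the rest background). Durations are Gaussian
    (mean 445 ms, SD 300 ms, truncated below at ``min_duration_ms``),
    matching the scale of the study's fixation durations. Gaze noise is
    isotropic Gaussian in pixels; the default equals the tracker
    accuracy of 0.5 degrees on the default 320-px-wide scene.
    """

    n_fixations: int = 100
    target_mix: dict = field(
        default_factory=lambda: {"syringe": 0.46, "bottle": 0.02, BACKGROUND_LABEL: 0.52}
    )
    duration_mean_ms: float = 445.0
    duration_sd_ms: float = 300.0
    min_duration_ms: float = 50.0
    noise_sd_px: float = degrees_to_pixels(0.5, 320)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fixations < 0:
            raise ValueError("n_fixations must be >= 0")
        total = sum(self.target_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target_mix probabilities sum to {total}, not 1")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")


def _sample_mask_pixel(rng: np.random.Generator, mask: np.ndarray) -> tuple[float, float]:
    ii, jj = np.nonzero(mask)
    k = rng.integers(len(ii))
    # centre of the chosen pixel, so zero noise stays inside it
    return float(jj[k]) + 0.5, float(ii[k]) + 0.5


def simulate_gaze(
    spec: SceneSpec,
    dataset: LabelDataset,
    config: GazeSimConfig,
) -> tuple[list[FixationEvent], list[MappedFixation]]:
    """Simulate a fixation stream over a rendered scene.

    Fixations tile the recording back to back. For each fixation a
    target (object class or background) is drawn from ``target_mix``;
    the gaze point is a uniformly drawn pixel of one of that class's
    instance masks on the fixation's *middle* frame (or of the
    background region), then perturbed with isotropic Gaussian noise.
    The returned ground truth records the intended target, which is
    what a human annotator watching the full fixation would report.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.target_mix)
    probs = np.array([config.target_mix[c] for c in classes])

    events: list[FixationEvent] = []
    truth: list[MappedFixation] = []
    t = 0.0
    for fid in range(1, config.n_fixations + 1):
        duration = max(
            float(rng.normal(config.duration_mean_ms, config.duration_sd_ms)),
            config.min_duration_ms,
        )
        if t + duration > spec.duration_ms:
            raise SceneError(
                f"recording too short: fixation {fid} would end at "
                f"{t + duration:.0f} ms but the scene lasts "
                f"{spec.duration_ms:.0f} ms"
            )
        start, end = t, t + duration
        t = end
        probe = FixationEvent(fid, start, duration, end, 0.0, 0.0)
        mid = middle_frame(*frame_span(probe, spec.fps))

        masks = dataset.masks_for_frame(mid)
        union = np.zeros((spec.height, spec.width), dtype=bool)
        for m in masks:
            union |= m.mask

        target = None
        for _ in range(20):
            candidate = classes[rng.choice(len(classes), p=probs)]
            if candidate == BACKGROUND_LABEL:
                if not union.all():
                    target = candidate
                    break
            else:
                if any(m.class_label == candidate and m.area_px for m in masks):
                    target = candidate
                    break
            warnings.warn(
                f"fixation {fid}: no '{candidate}' pixels on frame {mid}; "
                "resampling target",
                stacklevel=2,
            )
        if target is None:
            raise SceneError(f"fixation {fid}: no drawable target on frame {mid}")

        if target == BACKGROUND_LABEL:
            x, y = _sample_mask_pixel(rng, ~union)
        else:
            instances = [m for m in masks if m.class_label == target and m.area_px]
            chosen = instances[rng.integers(len(instances))]
            x, y = _sample_mask_pixel(rng, chosen.mask)
        if config.noise_sd_px > 0:
            x += float(rng.normal(0.0, config.noise_sd_px))
            y += float(rng.normal(0.0, config.noise_sd_px))

        events.append(FixationEvent(fid, start, duration, end, x, y))
        truth.append(
            MappedFixation(
                fixation_id=fid,
                start_ms=start,
                duration_ms=duration,
                end_ms=end,
                gaze_x=x,
                gaze_y=y,
                frame_index=mid,
                aoi_label=target,
                in_bounds=(0 <= x < spec.width) and (0 <= y < spec.height),
            )
        )
    return events, truth


class _DegradedDataset(LabelDataset):
    """Label dataset with simulated segmentation imperfection.

    Wraps a base dataset: annotations are dropped independently with a
    fixed probability (missed detections) and surviving masks are
    morphologically eroded (under-filled contours), both lazily so large
    scenes never materialize every mask.
    """

    def __init__(self, base: LabelDataset, erosion_radius: int, kept: list[Annotation]):
        super().__init__(
            width=base.width,
            height=base.height,
            label_set=base.label_set,
            frame_indices=base.frame_indices,
            annotations=kept,
        )
        self._erosion_radius = erosion_radius

    def masks_for_frame(self, frame_index: int):
        masks = super().masks_for_frame(frame_index)
        return erode_masks(masks, self._erosion_radius)


def degrade(
    dataset: LabelDataset,
    erosion_radius: int = 0,
    detection_dropout_prob: float = 0.0,
    seed: int = 0,
) -> LabelDataset:
    """Simulate imperfect segmentation on a ground-truth dataset.

    ``erosion_radius`` shrinks every mask by a square morphological
    erosion — the typical failure mode where predicted masks fill too
    little of the object rather than too much. ``detection_dropout_prob``
    removes each annotation independently (a missed detection). Radius 0
    with dropout 0 returns an equivalent dataset.
    """
    if erosion_radius < 0:
        raise ValueError("erosion_radius must be >= 0")
    if not 0.0 <= detection_dropout_prob <= 1.0:
        raise ValueError("detection_dropout_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = [
        ann
        for ann in dataset.annotations
        if detection_dropout_prob == 0.0 or rng.random() >= detection_dropout_prob
    ]
    return _DegradedDataset(dataset, int(erosion_radius), kept)


def export_recording(
    outdir,
    spec: SceneSpec,
    config: GazeSimConfig,
    write_frames: bool = True,
) -> dict:
    """Write a full synthetic recording to disk.

    Emits the same formats the real pipeline consumes: a frame
    directory of PNGs, a COCO-style label JSON, a fixation CSV and a
    ground-truth mapped CSV. Returns a manifest of the written paths.
    """
    from pathlib import Path

    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    source, dataset = render_scene(spec)
    events, truth = simulate_gaze(spec, dataset, config)

    manifest = {"seed": config.seed, "n_fixations": len(events)}
    labels_path = outdir / "labels.json"
    write_coco_dataset(dataset, labels_path)
    manifest["labels"] = str(labels_path)

    fix_path = outdir / "fixations.csv"
    pd.DataFrame(
        {
            "start_ms": [e.start_ms for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "end_ms": [e.end_ms for e in events],
            "gaze_x": [e.gaze_x for e in events],
            "gaze_y": [e.gaze_y for e in events],
        }
    ).to_csv(fix_path, index=False)
    manifest["fixations"] = str(fix_path)

    truth_path = outdir / "ground_truth.csv"
    if truth:
        write_mapped_fixations(truth, truth_path)
        manifest["ground_truth"] = str(truth_path)

    if write_frames:
        frames_dir = outdir / "frames"
        frames_dir.mkdir(exist_ok=True)
        for i in range(spec.n_frames):
            Image.fromarray(source.get_frame(i)).save(
                frames_dir / f"frame_{i:06d}.png"
            )
        manifest["frames"] = str(frames_dir)
    return manifest
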