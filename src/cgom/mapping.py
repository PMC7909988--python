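"""The gaze-object mapping core.

Each fixation spans a run of whole scene-video frames. Following the
fixation-by-fixation convention of manual semantic gaze mapping — where
the analyst is shown only the middle frame of each fixation — the
mapping uses a single frame per fixation: the ceil(n/2)-th of its
n-frame span. On that frame the fixation's gaze coordinate is tested
against every instance mask the segmenter produced; a hit assigns the
fixation to that mask's class (the AOI), a miss assigns it to the
background label ``"BG"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Protocol, Sequence

import numpy as np

from cgom.io_gaze import BACKGROUND_LABEL, FixationEvent, MappedFixation, RecordingMeta
from cgom.segmentation import InstanceMask, Segmenter

__all__ = [
    "MappingConfig",
    "MappingError",
    "FrameSource",
    "ArrayFrameSource",
    "DirectoryFrameSource",
    "VideoFrameSource",
    "frame_span",
    "middle_frame",
    "assign_fixation",
    "map_recording",
]

logger = logging.getLogger(__name__)

#: fixation end times are treated as exclusive with this guard (ms): a
#: fixation ending exactly on a frame boundary does not claim the next frame,
#: and boundary jitter from timestamps exported at 0.1 ms precision (e.g.
#: 291.7 ms for a seven-frame fixation at 24 fps, exactly 291.66.. ms) does
#: not spuriously extend the span by one frame
_BOUNDARY_EPS_MS = 0.1


class MappingError(RuntimeError):
    """Mapping could not be performed (missing frame, backend failure)."""


@dataclass(frozen=True)
class MappingConfig:
    """Parameters of the gaze→AOI assignment.

    Attributes
    ----------
    aoi_labels : tuple of str
        The AOI class names; all instances of one class merge into a
        single AOI (a syringe is a syringe, whichever one it is).
    background_label : str
        Label for fixations matching no AOI mask (default ``"BG"``).
    confidence_threshold : float
        Minimum detection confidence; applied by adapter backends.
    tolerance_px : int
        Chebyshev radius around the gaze pixel also tested against each
        mask. 0 (default) is the exact point-in-mask rule; a nonzero
        value absorbs tracker inaccuracy (~0.5° of visual angle).
    tie_break : str
        Policy for a gaze pixel inside several masks; only
        ``"confidence_area_label"`` is defined: highest confidence, then
        smallest pixel area, then lexicographically smallest label.
    out_of_bounds_policy : str
        ``"background"`` labels off-frame gaze as background;
        ``"exclude"`` additionally marks it for exclusion from metrics.
        Either way ``in_bounds`` is False on the mapped fixation.
    """

    aoi_labels: tuple[str, ...] = ()
    background_label: str = BACKGROUND_LABEL
    confidence_threshold: float = 0.5
    tolerance_px: int = 0
    tie_break: str = "confidence_area_label"
    out_of_bounds_policy: str = "background"

    def __post_init__(self) -> None:
        object.__setattr__(self, "aoi_labels", tuple(self.aoi_labels))
        if self.background_label in self.aoi_labels:
            raise ValueError("background label must not be an AOI label")
        if self.tolerance_px < 0:
            raise ValueError("tolerance_px must be >= 0")
        if self.tie_break != "confidence_area_label":
            raise ValueError(f"unknown tie_break policy '{self.tie_break}'")
        if self.out_of_bounds_policy not in ("background", "exclude"):
            raise ValueError("out_of_bounds_policy must be 'background' or 'exclude'")


def frame_span(event: FixationEvent, fps: float) -> tuple[int, int]:
    """Frames occupied by a fixation, as an inclusive (first, last) pair.

    Frame k covers the half-open interval [k/fps, (k+1)/fps); the
    fixation's end time is exclusive, so ending exactly on a frame
    boundary does not claim the next frame. End times within 0.1 ms of
    a boundary snap below it, absorbing the rounding of exports that
    print timestamps to 0.1 ms. A fixation shorter than one frame spans
    just the frame containing its start.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    first = int(np.floor(event.start_ms * fps / 1000.0))
    last = int(np.floor((event.end_ms - _BOUNDARY_EPS_MS) * fps / 1000.0))
    return first, max(first, last)


def middle_frame(first: int, last: int) -> int:
    """The ceil(n/2)-th frame of an n-frame span (1-based ordinal).

    A seven-frame fixation maps on its fourth frame; for even spans the
    earlier of the two central frames is used (3rd of 6).
    """
    if first > last:
        raise ValueError("first frame must not exceed last frame")
    return first + (last - first) // 2


def _tie_break_key(mask: InstanceMask):
    return (-mask.confidence, mask.area_px, mask.class_label)


def _hit(mask: np.ndarray, x: float, y: float, tolerance_px: int) -> bool:
    h, w = mask.shape
    j, i = int(np.floor(x)), int(np.floor(y))
    j0, j1 = max(j - tolerance_px, 0), min(j + tolerance_px + 1, w)
    i0, i1 = max(i - tolerance_px, 0), min(i + tolerance_px + 1, h)
    if j1 <= j0 or i1 <= i0:
        return False
    return bool(mask[i0:i1, j0:j1].any())


def assign_fixation(
    event: FixationEvent,
    masks: Sequence[InstanceMask],
    config: MappingConfig,
    meta: RecordingMeta,
) -> tuple[str, bool]:
    """Assign one fixation to an AOI label or the background.

    ``masks`` are the segmenter's output for the fixation's middle
    frame, already confidence-filtered. Returns ``(label, in_bounds)``.
    The gaze pixel (and, with ``tolerance_px`` > 0, its Chebyshev
    neighbourhood) is tested against every mask; among hits the
    tie-break order picks one label. Off-frame gaze goes to background.
    """
    in_bounds = (0 <= event.gaze_x < meta.width) and (0 <= event.gaze_y < meta.height)
    if not in_bounds:
        return config.background_label, False
    hits = [
        m
        for m in masks
        if (not config.aoi_labels or m.class_label in config.aoi_labels)
        and _hit(m.mask, event.gaze_x, event.gaze_y, config.tolerance_px)
    ]
    if not hits:
        return config.background_label, True
    return min(hits, key=_tie_break_key).class_label, True


class FrameSource(Protocol):
    """A scene video: frame count, geometry and per-index pixel access."""

    n_frames: int
    fps: float
    width: int
    height: int

    def get_frame(self, index: int) -> np.ndarray: ...


@dataclass
class ArrayFrameSource:
    """In-memory frame source over a (n, H, W[, C]) array."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.n_frames = int(self.frames.shape[0])
        self.height = int(self.frames.shape[1])
        self.width = int(self.frames.shape[2])

    def get_frame(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_frames:
            raise MappingError(f"frame {index} outside [0, {self.n_frames})")
        return self.frames[index]


class DirectoryFrameSource:
    """Frame source over a directory of zero-padded numbered images."""

    def __init__(self, path, fps: float):
        from PIL import Image

        self._path = FsPath(path)
        self._files = sorted(self._path.glob("*.png"))
        if not self._files:
            raise MappingError(f"{path}: no PNG frames found")
        self.fps = fps
        self.n_frames = len(self._files)
        first = np.asarray(Image.open(self._files[0]))
        self.height, self.width = first.shape[:2]

    def get_frame(self, index: int) -> np.ndarray:
        from PIL import Image

        if not 0 <= index < self.n_frames:
            raise MappingError(f"frame {index} outside [0, {self.n_frames})")
        return np.asarray(Image.open(self._files[index]))


class VideoFrameSource:
    """Frame source over a video container, decoded on demand via imageio.

    Requires an imageio plugin able to decode the container; raises a
    :class:`MappingError` naming the file when none is available.
    """

    def __init__(self, path, fps: float | None = None):
        import imageio.v3 as iio

        self._path = str(path)
        try:
            meta = iio.immeta(self._path)
            props = iio.improps(self._path, index=...)
        except Exception as exc:
            raise MappingError(f"cannot decode video '{path}': {exc}") from exc
        self.fps = float(fps or meta.get("fps", 0.0))
        self.n_frames = int(props.n_images)
        self.height, self.width = props.shape[-3], props.shape[-2]

    def get_frame(self, index: int) -> np.ndarray:
        import imageio.v3 as iio

        if not 0 <= index < self.n_frames:
            raise MappingError(f"frame {index} outside [0, {self.n_frames})")
        return iio.imread(self._path, index=index)


def map_recording(
    fixations: Sequence[FixationEvent],
    segmenter: Segmenter,
    frame_source: FrameSource | None,
    config: MappingConfig,
    meta: RecordingMeta,
) -> list[MappedFixation]:
    """Map every fixation of a recording to an AOI label.

    The loop visits each fixation's middle frame, queries the segmenter
    there, and assigns the fixation by the point-in-mask rule. Output
    order matches input order; the result is deterministic given a
    deterministic segmenter. ``frame_source`` may be None when the
    segmenter works from frame indices alone (e.g. the oracle).
    """
    mapped: list[MappedFixation] = []
    for event in fixations:
        first, last = frame_span(event, meta.fps)
        mid = middle_frame(first, last)
        if frame_source is not None and not (0 <= mid < frame_source.n_frames):
            raise MappingError(
                f"fixation {event.fixation_id}: middle frame {mid} not "
                f"available (source has {frame_source.n_frames} frames)"
            )
        masks = segmenter(mid)
        logger.debug(
            "fixation %d: frame %d, %d detections",
            event.fixation_id, mid, len(masks),
        )
        label, in_bounds = assign_fixation(event, masks, config, meta)
        mapped.append(
            MappedFixation(
                fixation_id=event.fixation_id,
                start_ms=event.start_ms,
                duration_ms=event.duration_ms,
                end_ms=event.end_ms,
                gaze_x=event.gaze_x,
                gaze_y=event.gaze_y,
                frame_index=mid,
                aoi_label=label,
                in_bounds=in_bounds,
            )
        )
    return mapped
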