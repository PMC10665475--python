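"""Respiration traces from video: green-channel averaging over fixed ROIs.

The camera looks at the driver's torso; a high-contrast chessboard band on
the seat belt moves with every in- and exhalation, so the mean green
intensity of a fixed rectangle over the belt (and one over the chest)
oscillates at the breathing frequency:

    color_avg = (1 / (w*h)) * sum over the w*h ROI pixels of their green value

Frames are RGB numpy arrays of shape (height, width, 3); a frame sequence
carries its frame rate so the derived trace is a proper channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .types import ChannelTrace, RespFusionError

log = logging.getLogger(__name__)

#: Default ROIs for the static in-cabin camera geometry (1280x720 frames),
#: pixel coordinates 0-based, x rightward, y downward.
ROI_BELT = None   # assigned below, after ROISpec is defined
ROI_CHEST = None


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: top-left corner (x, y), width w, height h."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise RespFusionError(f"ROI must have w >= 1 and h >= 1, got {self.w}x{self.h}")
        if self.x < 0 or self.y < 0:
            raise RespFusionError("ROI corner must be non-negative")

    def shifted(self, dx: int, dy: int) -> "ROISpec":
        return replace(self, x=self.x + dx, y=self.y + dy)


ROI_BELT = ROISpec(x=701, y=550, w=10, h=190)
ROI_CHEST = ROISpec(x=401, y=550, w=400, h=190)


@dataclass(frozen=True)
class FrameSequence:
    """Ordered RGB frames of fixed resolution with a frame rate in fps."""

    frames: np.ndarray  # (n_frames, height, width, 3)
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise RespFusionError(
                f"frames must have shape (n, height, width, 3), got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise RespFusionError("empty frame sequence")
        if not (self.fps > 0):
            raise RespFusionError(f"fps must be > 0, got {self.fps}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def resolution(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return int(self.frames.shape[2]), int(self.frames.shape[1])


def _check_roi_in_frame(frame: np.ndarray, roi: ROISpec) -> None:
    fh, fw = frame.shape[:2]
    if roi.x + roi.w > fw or roi.y + roi.h > fh:
        max_x, max_y = fw - roi.w, fh - roi.h
        raise RespFusionError(
            f"ROI (x={roi.x}, y={roi.y}, w={roi.w}, h={roi.h}) exceeds the "
            f"{fw}x{fh} frame; the corner must satisfy x <= {max_x}, y <= {max_y}"
        )


def roi_mean_green(frame: np.ndarray, roi: ROISpec) -> float:
    """Arithmetic mean of the green channel over the w*h ROI pixels."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise RespFusionError(f"frame must be (height, width, 3), got {frame.shape}")
    _check_roi_in_frame(frame, roi)
    patch = frame[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w, 1]
    return float(patch.astype(float).mean())


def frames_to_trace(seq: FrameSequence, roi: ROISpec, name: str = "video") -> ChannelTrace:
    """One green-mean sample per frame; the trace samples at the frame rate."""
    values = [roi_mean_green(f, roi) for f in seq.frames]
    return ChannelTrace(name, np.asarray(values), seq.fps)


def verify_roi(
    seq: FrameSequence,
    roi: ROISpec,
    search_radius: int = 10,
    min_contrast: float = 1.0,
) -> ROISpec:
    """Verify/adjust the nominal ROI position against the first frame.

    Searches integer shifts (dx, dy) within ``search_radius`` for the
    position maximizing local contrast (variance of the mean-RGB intensity
    inside the shifted ROI) — the chessboard band on the belt is the most
    contrast-rich structure near the nominal position.  If the best contrast
    stays below ``min_contrast`` (e.g. a featureless frame), a warning is
    logged and the original ROI returned.
    """
    frame = seq.frames[0].astype(float)
    intensity = frame.mean(axis=-1)
    fh, fw = intensity.shape

    shifts = sorted(
        (
            (dx, dy)
            for dy in range(-search_radius, search_radius + 1)
            for dx in range(-search_radius, search_radius + 1)
        ),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], abs(s[1]), abs(s[0]), s[1], s[0]),
    )
    best = (-1.0, 0, 0)
    for dx, dy in shifts:
        x, y = roi.x + dx, roi.y + dy
        if x < 0 or y < 0 or x + roi.w > fw or y + roi.h > fh:
            continue
        patch = intensity[y : y + roi.h, x : x + roi.w]
        contrast = float(patch.var())
        # strictly-greater keeps the smallest displacement on ties
        if contrast > best[0]:
            best = (contrast, dx, dy)
    contrast, dx, dy = best
    if contrast < min_contrast:
        log.warning(
            "verify_roi: best contrast %.3g below threshold %.3g; keeping nominal ROI",
            contrast, min_contrast,
        )
        return roi
    if (dx, dy) != (0, 0):
        log.info("verify_roi: adjusted ROI by (dx=%d, dy=%d)", dx, dy)
    return roi.shifted(dx, dy)


def load_frames(path: str | Path, fps: float = 10.0) -> FrameSequence:
    """Load a directory of PNG frames (sorted by filename) as a sequence."""
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(path.glob("*.png"))
    if not files:
        raise RespFusionError(f"{path}: no PNG frames found")
    frames = np.stack([np.asarray(iio.imread(f))[..., :3] for f in files])
    return FrameSequence(frames, fps)
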