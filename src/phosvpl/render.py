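"""Veridical encoding: gaze-contingent phosphene rendering.

Each phosphene plays a double role.  As a *filter* it measures the mean
luminance of the source frame under its footprint at its gaze-translated
screen position; as a *display* it is drawn as a 2D Gaussian at that
luminance.  The whole field is translated rigidly with the point of regard
on every monitor refresh, which approximately stabilizes the phosphenes in
retinal coordinates.

Rendering here is offline: frames and a gaze log go in, rendered frames
come out.  The frame scheduler reproduces the refresh bookkeeping of a
fixed-rate monitor showing a lower-rate video: with a refresh/video ratio
``r``, each video frame is repeated ``floor(r)`` times with an occasional
``ceil(r)``-repeat to resynchronize (at 144 Hz over 23.96 fps, ``r`` =
6.01: six repeats with a seventh roughly every four seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from phosvpl.field import Phosphene, PhospheneField, ScreenGeometry

__all__ = [
    "PhospheneFrame",
    "FrameScheduleEntry",
    "sample_luminance",
    "render_frame",
    "render_sequence",
    "schedule_frames",
    "to_luminance",
    "read_gaze_csv",
    "write_gaze_csv",
]

#: Gaussian footprints are truncated at this many sigma for speed.
TRUNCATE_SIGMA = 3.0

# Rec. 601 luma weights, used when collapsing RGB input to luminance.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PhospheneFrame:
    """A rendered frame: pixel grid in [0, 1] plus provenance."""

    pixels: np.ndarray
    source_frame: int
    gaze_px: tuple[float, float]
    gaze_held: bool = False  # True when the gaze sample was invalid and the
    # last valid sample was substituted


@dataclass(frozen=True)
class FrameScheduleEntry:
    """One video frame and how many monitor refreshes it occupies."""

    frame_index: int
    repetitions: int


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Convert an image array to a luminance grid in [0, 1].

    RGB(A) input is collapsed with Rec. 601 luma weights; integer input is
    scaled by its dtype range; the result is clipped to [0, 1].
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if np.issubdtype(img.dtype, np.integer):
        img = img / np.iinfo(image.dtype).max
    return np.clip(img.astype(float), 0.0, 1.0)


def _footprint_window(
    shape: tuple[int, int], cx: float, cy: float, radius: float
) -> tuple[slice, slice] | None:
    """Pixel window of a truncated footprint; None if off-image."""
    h, w = shape
    x0 = int(np.floor(cx - radius))
    x1 = int(np.ceil(cx + radius)) + 1
    y0 = int(np.floor(cy - radius))
    y1 = int(np.ceil(cy + radius)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    return slice(y0, y1), slice(x0, x1)


def sample_luminance(
    image: np.ndarray,
    phosphene: Phosphene,
    gaze_px: tuple[float, float],
    screen: ScreenGeometry,
    *,
    footprint: str = "gaussian",
) -> float:
    """Mean image luminance under one phosphene's footprint.

    The phosphene is translated to its screen position relative to
    ``gaze_px``.  With ``footprint="gaussian"`` (default) the mean is
    Gaussian-weighted with the phosphene's own sigma, truncated at 3 sigma
    — the filter matches the display kernel.  ``footprint="disc"`` uses an
    unweighted mean over a disc of radius 2 sigma.  A footprint that misses
    the image entirely samples 0.
    """
    lum = np.asarray(image, dtype=float)
    cx, cy = screen.deg_to_px(phosphene.x, phosphene.y, gaze_px)
    cx, cy = float(cx), float(cy)
    sigma_px = phosphene.sigma / screen.deg_per_px

    if footprint == "gaussian":
        radius = TRUNCATE_SIGMA * sigma_px
    elif footprint == "disc":
        radius = 2.0 * sigma_px
    else:
        raise ValueError(f"unknown footprint {footprint!r}")

    win = _footprint_window(lum.shape, cx, cy, radius)
    if win is None:
        return 0.0
    ys, xs = win
    yy, xx = np.mgrid[ys, xs]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    if footprint == "gaussian":
        w = np.exp(-d2 / (2.0 * sigma_px**2))
        w[d2 > radius**2] = 0.0
    else:
        w = (d2 <= radius**2).astype(float)
    total = w.sum()
    if total == 0.0:
        return 0.0
    return float((w * lum[ys, xs]).sum() / total)


def render_frame(
    image: np.ndarray,
    field: PhospheneField,
    gaze_px: tuple[float, float],
    screen: ScreenGeometry,
    *,
    source_frame: int = 0,
    gaze_held: bool = False,
    footprint: str = "gaussian",
) -> PhospheneFrame:
    """Render one phosphene-view frame.

    Every phosphene samples the image at its gaze-translated position and
    is drawn as a unit-peak 2D Gaussian scaled by the sampled luminance.
    Overlapping Gaussians add and the sum is clipped to [0, 1].  Shifting
    the gaze shifts the whole pattern rigidly (up to screen-edge
    truncation).
    """
    lum = np.asarray(image, dtype=float)
    out = np.zeros((screen.height_px, screen.width_px))
    x, y, sigma = field.as_arrays()
    pxs, pys = screen.deg_to_px(x, y, gaze_px)
    for p, cx, cy in zip(field.phosphenes, pxs, pys):
        level = sample_luminance(lum, p, gaze_px, screen, footprint=footprint)
        if level == 0.0:
            continue
        sigma_px = p.sigma / screen.deg_per_px
        radius = TRUNCATE_SIGMA * sigma_px
        win = _footprint_window(out.shape, float(cx), float(cy), radius)
        if win is None:
            continue
        ys, xs = win
        yy, xx = np.mgrid[ys, xs]
        d2 = (xx - float(cx)) ** 2 + (yy - float(cy)) ** 2
        g = np.exp(-d2 / (2.0 * sigma_px**2))
        g[d2 > radius**2] = 0.0
        out[ys, xs] += level * g
    np.clip(out, 0.0, 1.0, out=out)
    return PhospheneFrame(out, source_frame, tuple(gaze_px), gaze_held)


def render_sequence(
    images: list[np.ndarray],
    field: PhospheneField,
    gaze: pd.DataFrame,
    screen: ScreenGeometry,
    *,
    footprint: str = "gaussian",
) -> list[PhospheneFrame]:
    """Render a frame sequence against a gaze trace.

    ``gaze`` needs columns ``t_ms, x_px, y_px, valid`` with one row per
    frame-display time (the caller aligns timestamps; the most recent gaze
    sample is what a gaze-contingent loop would use).  Invalid samples hold
    the last valid gaze, flagged on the output frame; leading invalid
    samples hold the screen center.
    """
    frames: list[PhospheneFrame] = []
    last = (screen.width_px / 2.0, screen.height_px / 2.0)
    rows = gaze.itertuples(index=False)
    for i, (img, row) in enumerate(zip(images, rows)):
        valid = bool(row.valid)
        if valid:
            last = (float(row.x_px), float(row.y_px))
        frames.append(
            render_frame(
                img, field, last, screen,
                source_frame=i, gaze_held=not valid, footprint=footprint,
            )
        )
    return frames


def schedule_frames(
    video_fps: float, monitor_hz: float, duration: int
) -> list[FrameScheduleEntry]:
    """Accumulator schedule mapping video frames onto monitor refreshes.

    Each of ``duration`` video frames is held for ``floor(r)`` or
    ``ceil(r)`` refreshes, where ``r = monitor_hz / video_fps``; the
    fractional part accumulates and inserts the longer hold just often
    enough that total refreshes track ``duration * r`` within one refresh.
    """
    if video_fps <= 0:
        raise ValueError("video_fps must be positive")
    if video_fps > monitor_hz:
        raise ValueError(
            f"video rate {video_fps} Hz exceeds monitor refresh {monitor_hz} Hz"
        )
    r = monitor_hz / video_fps
    schedule = []
    emitted = 0
    acc = 0.0
    for i in range(duration):
        acc += r
        reps = int(np.floor(acc + 1e-9)) - emitted
        emitted += reps
        schedule.append(FrameScheduleEntry(i, reps))
    return schedule


def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    """Read a gaze trace CSV with columns ``t_ms, x_px, y_px, valid``."""
    df = pd.read_csv(path)
    required = {"t_ms", "x_px", "y_px", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gaze trace missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_gaze_csv(trace: pd.DataFrame, path: str | Path) -> None:
    trace.to_csv(path, index=False, columns=["t_ms", "x_px", "y_px", "valid"])
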