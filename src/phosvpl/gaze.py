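"""Scan-path metrics on gaze traces.

The scan path is the cumulative distance traveled by the point of regard,
normalized to screen widths so traces from different monitors compare
directly.  Raw samples are summed without saccade detection or smoothing
(an optional median filter is available); invalid samples (blinks, track
losses) are dropped and bridges longer than a threshold contribute no
distance, so a blink cannot inject a spurious jump into the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from scipy.stats import pearsonr

from phosvpl.field import ScreenGeometry

__all__ = [
    "GazeTrace",
    "ScanPathSummary",
    "path_length",
    "demeaned_correlation",
]

#: bridges across gaps longer than this contribute no path length
DEFAULT_MAX_GAP_MS = 100.0


@dataclass
class GazeTrace:
    """Timestamped gaze samples on a known screen."""

    samples: pd.DataFrame  # columns t_ms, x_px, y_px, valid
    screen: ScreenGeometry

    def __post_init__(self) -> None:
        required = {"t_ms", "x_px", "y_px", "valid"}
        if not required <= set(self.samples.columns):
            raise ValueError(f"gaze trace needs columns {sorted(required)}")
        t = self.samples["t_ms"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        v = self.samples["valid"].to_numpy(dtype=bool)
        xy = self.samples.loc[v, ["x_px", "y_px"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("valid samples must have finite coordinates")


@dataclass
class ScanPathSummary:
    path_length: float  # screen widths
    n_valid: int
    n_gaps: int


def path_length(
    trace: GazeTrace,
    *,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    median_filter: int = 0,
) -> ScanPathSummary:
    """Total scan path length of a trace, in screen widths.

    Sums Euclidean distances between consecutive valid samples and divides
    by the screen width in pixels.  A pair of valid samples separated by
    more than ``max_gap_ms`` (or by dropped invalid samples spanning such
    a gap) is a *gap*: it adds no distance and increments ``n_gaps``.
    ``median_filter`` (odd kernel size, 0 = off) optionally smooths the
    coordinates before summation.
    """
    df = trace.samples
    valid = df["valid"].to_numpy(dtype=bool)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid gaze samples")
    t = df.loc[valid, "t_ms"].to_numpy(dtype=float)
    x = df.loc[valid, "x_px"].to_numpy(dtype=float)
    y = df.loc[valid, "y_px"].to_numpy(dtype=float)
    if median_filter:
        if median_filter % 2 == 0:
            raise ValueError("median_filter kernel must be odd")
        x = medfilt(x, median_filter)
        y = medfilt(y, median_filter)
    dt = np.diff(t)
    seg = np.hypot(np.diff(x), np.diff(y))
    bridged = dt <= max_gap_ms
    length = float(seg[bridged].sum()) / trace.screen.width_px
    return ScanPathSummary(length, int(valid.sum()), int((~bridged).sum()))


def demeaned_correlation(
    pairs: pd.DataFrame,
    *,
    x: str = "reading_length",
    y: str = "video_length",
    subject: str = "subject",
) -> dict:
    """Per-subject-mean-corrected correlation between two scan-path series.

    ``pairs`` holds one row per paired observation (e.g. a reading test
    and the following video session) with a subject column.  Each
    subject's mean is subtracted from their values in both series, then
    the Pearson correlation is computed on the pooled residual pairs with
    ``df = n_pairs - 2``.  Removing subject offsets isolates the
    session-to-session covariation (e.g. shared motivation) from stable
    between-subject differences.
    """
    required = {x, y, subject}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observations")
    rx = pairs[x] - pairs.groupby(subject)[x].transform("mean")
    ry = pairs[y] - pairs.groupby(subject)[y].transform("mean")
    rx = rx.to_numpy(dtype=float)
    ry = ry.to_numpy(dtype=float)
    if np.allclose(rx, rx[0]) or np.allclose(ry, ry[0]):
        return {"r": np.nan, "df": len(pairs) - 2, "p": np.nan, "defined": False}
    r, p = pearsonr(rx, ry)
    return {"r": float(r), "df": len(pairs) - 2, "p": float(p), "defined": True}
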