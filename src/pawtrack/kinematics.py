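"""Kinematic series and summaries: distance, speed, acceleration, orientation.

Derivatives are first-order backward differences with no smoothing by
default; pose-estimation jitter inflates instantaneous speed, so an optional
centred moving-average smoother (odd window) is available but off by default.

Angles use the image convention (y grows downward), matching the pixel
coordinates of the tracking data: a tip directly "below" its reference on
screen has angle +π/2.  Use :func:`to_math_angle` for the conventional
y-up reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_tracking import TimeWindow, TrackingTable, select_time_window

__all__ = [
    "MotionSummary",
    "OrientationSeries",
    "motion_metrics",
    "orientation",
    "trajectory_points",
    "to_math_angle",
]


@dataclass
class MotionSummary:
    """Per-animal motion metrics over a (possibly windowed) recording.

    ``speed_series`` and ``acceleration_series`` have one entry per frame;
    frame 0 of both is 0 by convention (no preceding frame).  Units follow
    the table: px or cm for distance, per second for rates.
    """

    total_distance: float
    mean_speed: float
    max_speed: float
    speed_series: np.ndarray
    acceleration_series: np.ndarray
    units: str
    window: Optional[TimeWindow] = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame export: frame, time ignored here, speed, acceleration."""
        return pd.DataFrame(
            {
                "speed": self.speed_series,
                "acceleration": self.acceleration_series,
            }
        ).rename_axis("frame")


@dataclass
class OrientationSeries:
    """Per-frame atan2 angle (radians, image convention) from ref to tip."""

    angles: np.ndarray  # in (-pi, pi]; NaN where ref and tip coincide
    ref: str
    tip: str

    def __len__(self) -> int:
        return len(self.angles)


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return series
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(series, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def motion_metrics(
    t: TrackingTable,
    bodypart: str,
    w: Optional[TimeWindow] = None,
    smooth_window: Optional[int] = None,
) -> MotionSummary:
    """Traveled distance, speed and acceleration for one body part.

    Per-frame displacement ``d_i`` is the Euclidean step between consecutive
    frames; ``total_distance = Σ d_i``, ``speed_i = d_i · fps`` and
    ``acceleration_i = (speed_i − speed_{i−1}) · fps``, with frame 0 of both
    series set to 0.  Mean and max speed are taken over frames 1..n−1 (frame
    0 has no defined speed).

    Parameters
    ----------
    w
        Optional time window applied before computing metrics.
    smooth_window
        Odd length of a centred moving average applied to the speed series
        before summarising; default ``None`` (raw backward differences).
    """
    if w is not None:
        t = select_time_window(t, w)
    xy = t.xy(bodypart)
    if np.isnan(xy).any():
        raise ValueError(
            f"body part {bodypart!r} has missing coordinates in the window; "
            "run apply_likelihood_cutoff first"
        )
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total = float(steps.sum())
    speed = np.concatenate([[0.0], steps * t.fps])
    if smooth_window is not None:
        speed = _smooth(speed, smooth_window)
    accel = np.concatenate([[0.0], np.diff(speed) * t.fps])
    accel[0] = 0.0
    moving = speed[1:] if len(speed) > 1 else speed
    return MotionSummary(
        total_distance=total,
        mean_speed=float(moving.mean()),
        max_speed=float(moving.max()),
        speed_series=speed,
        acceleration_series=accel,
        units=t.units,
        window=w,
    )


def orientation(t: TrackingTable, ref: str, tip: str) -> OrientationSeries:
    """Element-wise arc tangent from a reference part to a tip part.

    ``angle_i = atan2(y_tip − y_ref, x_tip − x_ref)`` in image coordinates,
    mapped into (−π, π].  Head orientation is the common use (ref = neck,
    tip = snout); body orientation works the same way from the tail base.
    Frames where the two points coincide yield NaN, not 0 — a zero-length
    vector has no direction.
    """
    if ref == tip:
        raise ValueError("ref and tip must be different body parts")
    d = t.xy(tip) - t.xy(ref)
    angles = np.arctan2(d[:, 1], d[:, 0])
    angles[angles == -np.pi] = np.pi
    coincident = (d == 0).all(axis=1)
    angles[coincident] = np.nan
    return OrientationSeries(angles=angles, ref=ref, tip=tip)


def to_math_angle(angles: np.ndarray) -> np.ndarray:
    """Convert image-convention angles (y down) to mathematical (y up)."""
    out = -np.asarray(angles, float)
    out[out == -np.pi] = np.pi
    return out


def trajectory_points(t: TrackingTable, bodypart: str) -> pd.DataFrame:
    """The (x, y, time_s) triples behind a time-coloured trajectory plot.

    ``time_s = frame / fps`` restarts at 0 for windowed tables; the original
    offset is available as ``t.frame_offset`` (also stored in
    ``DataFrame.attrs['frame_offset']``).
    """
    xy = t.xy(bodypart)
    out = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "time_s": np.arange(t.n_frames) / t.fps,
        }
    ).rename_axis("frame")
    out.attrs["frame_offset"] = t.frame_offset
    out.attrs["bodypart"] = bodypart
    return out


def summary_row(name: str, m: MotionSummary) -> dict:
    """One CSV-ready row (animal name + scalar metrics)."""
    return {
        "name": name,
        "total_distance": m.total_distance,
        "mean_speed": m.mean_speed,
        "max_speed": m.max_speed,
        "units": m.units,
        "window_start_s": m.window.start_s if m.window else 0.0,
        "window_end_s": m.window.end_s if m.window else np.nan,
    }
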