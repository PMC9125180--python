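"""Synthetic fixtures with known ground truth for every analysis stage.

Three generators:

* :func:`make_trajectory` — parametric single-body-part trajectories
  (constant velocity, circle, bounded random walk) with closed-form
  distance/speed truth, for the kinematics and occupancy paths;
* :func:`make_behavior_frames` — frames drawn from per-cluster body-part
  geometry templates placed by seeded rigid transforms, so only pairwise
  distances (never absolute positions) carry cluster identity — which is
  exactly the invariance the behavior classifier relies on;
* :func:`make_event_signal` — Gaussian noise plus a sinusoid whose
  amplitude is boosted inside given event windows, for the epoch-extraction
  path.

All generators are pure functions of (spec, seed): the same inputs always
yield the same fixture, and the ground truth is emitted alongside so no
test needs to hard-code a generated value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io_tracking import TrackingTable, write_tracking
from .neural import SignalRecord

__all__ = [
    "TrajectorySpec",
    "TrajectoryTruth",
    "BehaviorSceneSpec",
    "BehaviorSceneTruth",
    "make_trajectory",
    "make_behavior_frames",
    "make_event_signal",
    "write_fixture",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Parametric trajectory description.

    ``kind`` is one of ``constant_velocity`` (straight line at ``speed``
    units/s), ``circular`` (one full revolution of radius ``radius``), or
    ``bounded_random_walk`` (Gaussian steps of scale ``step_scale``
    reflected at the arena bounds).  ``duration_s`` fixes the frame count as
    ``round(duration_s · fps) + 1`` so the path spans exactly the requested
    time (n frames bound n−1 steps).
    """

    kind: str
    duration_s: float = 10.0
    fps: float = 30.0
    seed: int = 0
    speed: float = 2.0                 # units/s, constant_velocity
    heading_rad: float = 0.0
    start: tuple[float, float] = (10.0, 10.0)
    radius: float = 10.0               # circular
    center: tuple[float, float] = (30.0, 30.0)
    step_scale: float = 1.0            # units/frame, random walk
    arena: tuple[float, float] = (59.0, 59.0)
    bodypart: str = "snout"
    units: str = "cm"
    dropout_rate: float = 0.0          # fraction of frames given low likelihood

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps)) + 1


@dataclass
class TrajectoryTruth:
    """Closed-form kinematic ground truth for a generated trajectory."""

    total_distance: float
    mean_speed: float
    clean_xy: np.ndarray  # coordinates before any dropout corruption


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection at the walls."""
    span = hi - lo
    v = np.mod(values - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def make_trajectory(spec: TrajectorySpec) -> tuple[TrackingTable, TrajectoryTruth]:
    """Generate a tracking table plus its closed-form motion truth.

    The likelihood column is 1.0 everywhere; with ``dropout_rate > 0`` a
    seeded fraction of interior frames get likelihood 0.05 and corrupted
    coordinates (for p-cutoff conditioning tests), while the truth keeps
    the clean coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    if spec.kind == "constant_velocity":
        vx = spec.speed * np.cos(spec.heading_rad)
        vy = spec.speed * np.sin(spec.heading_rad)
        xy = np.column_stack([spec.start[0] + vx * t, spec.start[1] + vy * t])
        total = spec.speed * (n - 1) / spec.fps
    elif spec.kind == "circular":
        theta = 2 * np.pi * np.arange(n) / (n - 1)
        xy = np.column_stack(
            [spec.center[0] + spec.radius * np.cos(theta),
             spec.center[1] + spec.radius * np.sin(theta)]
        )
        # chord sum for one revolution in n−1 equal steps (exact)
        total = 2 * spec.radius * (n - 1) * np.sin(np.pi / (n - 1))
    elif spec.kind == "bounded_random_walk":
        steps = rng.normal(scale=spec.step_scale, size=(n - 1, 2))
        raw = np.vstack([spec.start, spec.start + np.cumsum(steps, axis=0)])
        xy = np.column_stack(
            [_reflect(raw[:, 0], 0, spec.arena[0]),
             _reflect(raw[:, 1], 0, spec.arena[1])]
        )
        total = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    else:
        raise ValueError(f"unknown trajectory kind {spec.kind!r}")

    clean = xy.copy()
    lik = np.ones(n)
    if spec.dropout_rate > 0:
        k = int(round(spec.dropout_rate * (n - 2)))
        bad = rng.choice(np.arange(1, n - 1), size=k, replace=False)
        lik[bad] = 0.05
        xy = xy.copy()
        xy[bad] += rng.normal(scale=50.0, size=(k, 2))  # tracker glitches

    df = pd.DataFrame(
        {
            (spec.bodypart, "x"): xy[:, 0],
            (spec.bodypart, "y"): xy[:, 1],
            (spec.bodypart, "likelihood"): lik,
        }
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    table = TrackingTable(df, fps=spec.fps, units=spec.units)
    truth = TrajectoryTruth(
        total_distance=float(total),
        mean_speed=float(total / ((n - 1) / spec.fps)),
        clean_xy=clean,
    )
    return table, truth


@dataclass(frozen=True)
class BehaviorSceneSpec:
    """Cluster-structured body-part scene with known labels.

    Each cluster has a fixed geometry template of ``n_parts`` body parts
    (a posture); frames are the template plus Gaussian coordinate noise,
    placed in the arena by a random rigid transform per frame.  When
    ``separation_noise_ratio`` is given the noise scale is derived so the
    minimum between-template feature distance is that multiple of the
    expected within-cluster feature spread; otherwise ``noise_scale`` is
    used directly.
    """

    n_clusters: int = 3
    n_parts: int = 4
    frames_per_cluster: int = 60
    separation_noise_ratio: Optional[float] = 10.0
    noise_scale: Optional[float] = None
    body_scale: float = 10.0           # template extent, coordinate units
    arena: tuple[float, float] = (59.0, 59.0)
    fps: float = 30.0
    seed: int = 0
    shuffle: bool = True               # interleave clusters in time


@dataclass
class BehaviorSceneTruth:
    """Generative labels and achieved separation/noise ratio."""

    labels: np.ndarray
    templates: np.ndarray              # (C, n_parts, 2) body-centric geometries
    noise_scale: float
    separation_noise_ratio: float      # min inter-template feature distance
                                       # over within-cluster RMS feature spread


def _template_features(templates: np.ndarray) -> np.ndarray:
    """Pairwise-distance feature vector of each template."""
    C, k, _ = templates.shape
    feats = []
    for c in range(C):
        D = cdist(templates[c], templates[c])
        iu = np.triu_indices(k, 1)
        feats.append(D[iu])
    return np.vstack(feats)


def make_behavior_frames(
    spec: BehaviorSceneSpec,
) -> tuple[TrackingTable, BehaviorSceneTruth]:
    """Generate posture-cluster frames whose identity lives only in geometry.

    Because every frame is independently rotated and translated, absolute
    coordinates are uninformative about the cluster — recovering the labels
    requires the translation/rotation-invariant pairwise-distance features.
    """
    if spec.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(spec.seed)
    C, k = spec.n_clusters, spec.n_parts
    # distinct random geometries, centred, at body scale
    templates = rng.uniform(-spec.body_scale / 2, spec.body_scale / 2, size=(C, k, 2))
    templates -= templates.mean(axis=1, keepdims=True)

    feats = _template_features(templates)
    sep = float(cdist(feats, feats)[np.triu_indices(C, 1)].min())
    m = k * (k - 1) // 2
    if spec.noise_scale is not None:
        sigma = spec.noise_scale
    else:
        if spec.separation_noise_ratio is None:
            raise ValueError("give either noise_scale or separation_noise_ratio")
        # within-cluster feature spread: each pair distance is perturbed with
        # sd ≈ sqrt(2)·σ, so the feature-vector RMS spread is ≈ sqrt(2m)·σ
        sigma = sep / (spec.separation_noise_ratio * np.sqrt(2 * m))
    spread = float(np.sqrt(2 * m) * sigma)
    achieved = sep / spread if spread > 0 else np.inf

    labels = np.repeat(np.arange(C), spec.frames_per_cluster)
    if spec.shuffle:
        labels = rng.permutation(labels)
    n = len(labels)
    frames = np.empty((n, k, 2))
    pad = spec.body_scale
    for i, c in enumerate(labels):
        pts = templates[c] + rng.normal(scale=sigma, size=(k, 2))
        ang = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = rng.uniform([pad, pad], [spec.arena[0] - pad, spec.arena[1] - pad])
        frames[i] = pts @ R.T + shift

    parts = [f"part{j}" for j in range(k)]
    cols = {}
    for j, part in enumerate(parts):
        cols[(part, "x")] = frames[:, j, 0]
        cols[(part, "y")] = frames[:, j, 1]
        cols[(part, "likelihood")] = np.ones(n)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    table = TrackingTable(df, fps=spec.fps, units="pixel")
    truth = BehaviorSceneTruth(
        labels=labels,
        templates=templates,
        noise_scale=float(sigma),
        separation_noise_ratio=float(achieved),
    )
    return table, truth


def make_event_signal(
    rate: float,
    duration_s: float,
    events: Sequence[tuple[float, float]],
    carrier_hz: float = 8.0,
    event_gain: float = 5.0,
    noise_sd: float = 1.0,
    base_amp: float = 1.0,
    seed: int = 0,
    n_channels: int = 1,
) -> SignalRecord:
    """Sinusoid-plus-noise signal whose carrier amplitude jumps inside events.

    Outside events the carrier has amplitude ``base_amp``; inside each
    (start_s, end_s) window it is multiplied by ``event_gain``.  With
    ``event_gain = 1`` the signal is stationary; with ``noise_sd = 0`` the
    in-event amplitude is exactly ``event_gain`` times baseline.
    """
    rng = np.random.default_rng(seed)
    n = int(round(rate * duration_s))
    t = np.arange(n) / rate
    amp = np.full(n, base_amp)
    for start, end in events:
        if start < 0 or end > duration_s:
            raise ValueError(f"event [{start}, {end}) outside signal duration")
        amp[(t >= start) & (t < end)] = base_amp * event_gain
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        data[ch] = amp * np.sin(2 * np.pi * carrier_hz * t + phase)
        data[ch] += rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0
    return SignalRecord(data=data, sampling_rate_hz=rate)


def write_fixture(
    table: TrackingTable,
    truth: object,
    path: str | Path,
    dialect: str = "dlc",
) -> Path:
    """Write a fixture table as CSV plus a JSON truth sidecar; returns the CSV path."""
    path = Path(path)
    write_tracking(table, path, dialect=dialect)

    def _jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
        return obj

    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(_jsonable(truth), indent=1))
    return path
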