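"""Coupling behavior to synchronized neural signals.

Two products: *epochs* — segments of a continuous recording cut at
behavioral event boundaries — and *spatial activity maps* — the mean of a
per-frame neural quantity (e.g. spike counts) binned by the animal's
position.

Alignment contract: video frame 0 corresponds to signal time ``t0_s``,
supplied by the user; there is no automatic sync-pulse detection.  Sample
indexing is half-open with round-to-nearest boundaries,
``[round((start − t0)·rate), round((end − t0)·rate))``, so that epochs cut
at a partition of the recording concatenate back to it sample-for-sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d

from .behavior import BehaviorIntervals
from .io_tracking import TrackingTable
from .spatial import InteractionEvent

__all__ = [
    "SignalRecord",
    "EpochSet",
    "SpatialActivityMap",
    "signal_subset",
    "spatial_activity",
    "read_signal_csv",
    "write_signal_csv",
    "write_epochs",
]


@dataclass
class SignalRecord:
    """Multi-channel sampled signal (channels × samples) with a rate.

    ``t0_s`` is the signal time of video frame 0 — the explicit alignment
    offset between the recording systems.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channels: Optional[list[str]] = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.channels is None:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochSet:
    """Chronologically numbered signal segments with their source intervals."""

    epochs: dict[int, np.ndarray]                 # epoch -> (channels, samples)
    intervals: dict[int, tuple[float, float]]     # epoch -> (start_s, end_s)
    labels: dict[int, object]                     # epoch -> area label / cluster / None
    sampling_rate_hz: float

    def __len__(self) -> int:
        return len(self.epochs)

    def concatenate(self) -> np.ndarray:
        """All epochs joined along time, in key order."""
        return np.concatenate([self.epochs[k] for k in sorted(self.epochs)], axis=1)

    def index_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.epochs):
            s, e = self.intervals[k]
            rows.append(
                {
                    "epoch": k,
                    "start_s": s,
                    "end_s": e,
                    "n_samples": self.epochs[k].shape[1],
                    "source_label": self.labels[k],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SpatialActivityMap:
    """Mean activity per spatial bin; NaN where the animal never went."""

    mean: np.ndarray
    visits: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    def argmax_bin(self) -> tuple[int, int]:
        """(ix, iy) of the bin with the highest mean activity."""
        flat = np.nanargmax(self.mean)
        return tuple(int(v) for v in np.unravel_index(flat, self.mean.shape))

    def bin_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            float((self.x_edges[ix] + self.x_edges[ix + 1]) / 2),
            float((self.y_edges[iy] + self.y_edges[iy + 1]) / 2),
        )


EventsLike = Union[
    Sequence[tuple[float, float]],
    Sequence[InteractionEvent],
    BehaviorIntervals,
]


def _events_to_seconds(
    events: EventsLike, fps: Optional[float], cluster: Optional[int]
) -> list[tuple[float, float, object]]:
    if isinstance(events, BehaviorIntervals):
        return events.seconds(cluster)
    events = list(events)
    if not events:
        return []
    if isinstance(events[0], InteractionEvent):
        if fps is None:
            raise ValueError("fps is required to convert frame-based events to seconds")
        return [
            (ev.start_frame / fps, (ev.end_frame + 1) / fps, ev.area_label)
            for ev in events
        ]
    return [(float(s), float(e), None) for s, e in events]


def signal_subset(
    s: SignalRecord,
    events: EventsLike,
    freq: Optional[float] = None,
    fps: Optional[float] = None,
    cluster: Optional[int] = None,
) -> EpochSet:
    """Extract signal epochs at behavioral event boundaries.

    ``events`` may be plain (start_s, end_s) pairs, a list of
    :class:`~pawtrack.spatial.InteractionEvent` (pass ``fps`` to convert
    frames to seconds), or a :class:`~pawtrack.behavior.BehaviorIntervals`
    (optionally restricted to one ``cluster``).  ``freq`` overrides the
    record's sampling rate when the caller knows better.

    Epoch ``i`` holds samples ``[round((start−t0)·freq), round((end−t0)·freq))``
    for all channels; keys are chronological epoch numbers starting at 0.
    """
    rate = freq if freq is not None else s.sampling_rate_hz
    secs = _events_to_seconds(events, fps, cluster)
    secs.sort(key=lambda x: x[0])
    epochs: dict[int, np.ndarray] = {}
    intervals: dict[int, tuple[float, float]] = {}
    labels: dict[int, object] = {}
    for k, (start, end, label) in enumerate(secs):
        i0 = int(round((start - s.t0_s) * rate))
        i1 = int(round((end - s.t0_s) * rate))
        if i0 < 0 or i1 > s.n_samples:
            raise ValueError(
                f"epoch {k} [{start}, {end}) s falls outside the signal "
                f"(0..{s.duration_s} s after t0 alignment)"
            )
        epochs[k] = s.data[:, i0:i1]
        intervals[k] = (start, end)
        labels[k] = label
    return EpochSet(
        epochs=epochs, intervals=intervals, labels=labels, sampling_rate_hz=rate
    )


def spatial_activity(
    t: TrackingTable,
    bodypart: str,
    activity: np.ndarray,
    bins: int | tuple[int, int] = 10,
    extent: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> SpatialActivityMap:
    """Mean per-frame activity binned by body-part position.

    ``activity`` is one number per frame — spike counts within the frame's
    duration, or a continuous signal already averaged per frame.  Bins the
    animal never visited are NaN in the mean grid; visit counts are
    returned alongside so the global mean can be recovered exactly as the
    visit-weighted average.
    """
    xy = t.xy(bodypart)
    activity = np.asarray(activity, float)
    if len(activity) != t.n_frames:
        raise ValueError(
            f"activity length {len(activity)} != n_frames {t.n_frames}"
        )
    valid = ~np.isnan(xy).any(axis=1) & ~np.isnan(activity)
    mean, x_edges, y_edges, _ = binned_statistic_2d(
        xy[valid, 0], xy[valid, 1], activity[valid],
        statistic="mean", bins=bins, range=extent,
    )
    visits, _, _, _ = binned_statistic_2d(
        xy[valid, 0], xy[valid, 1], None,
        statistic="count", bins=bins, range=extent,
    )
    return SpatialActivityMap(mean=mean, visits=visits,
                              x_edges=x_edges, y_edges=y_edges)


# ---------------------------------------------------------------------------
# plain-format IO
# ---------------------------------------------------------------------------

def read_signal_csv(path: str | Path, sidecar: str | Path | None = None) -> SignalRecord:
    """Read a channels-as-columns CSV plus a JSON sidecar (rate, t0, names).

    Vendor acquisition formats are expected to be pre-converted to this
    plain layout.  The sidecar defaults to ``<path>.json``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    return SignalRecord(
        data=df.to_numpy(float).T,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=meta.get("channels", list(df.columns)),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


def write_signal_csv(s: SignalRecord, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(s.data.T, columns=s.channels).to_csv(path, index=False)
    meta = {
        "sampling_rate_hz": s.sampling_rate_hz,
        "channels": s.channels,
        "t0_s": s.t0_s,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def write_epochs(es: EpochSet, directory: str | Path, prefix: str = "epoch") -> Path:
    """One CSV per epoch plus an index CSV; returns the index path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in sorted(es.epochs):
        pd.DataFrame(es.epochs[k].T).to_csv(
            directory / f"{prefix}_{k:04d}.csv", index=False
        )
    index_path = directory / f"{prefix}_index.csv"
    es.index_frame().to_csv(index_path, index=False)
    return index_path
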