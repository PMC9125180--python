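"""Occupancy maps, region-of-interest definitions, and interaction events.

An *interaction* is a maximal run of consecutive frames in which a chosen
body part (typically the snout) lies inside a named area.  Membership rules
are fixed so results are bit-reproducible: rectangles are half-open
(``origin <= p < origin + size``; a point on the right/bottom edge is
outside), circles are closed (``‖p − center‖ <= r``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_tracking import TrackingTable

__all__ = [
    "OccupancyMap",
    "AreaSpec",
    "InteractionEvent",
    "InteractionSummary",
    "occupancy",
    "define_fields",
    "import_posit_dict",
    "detect_interactions",
    "summarize_interactions",
    "events_to_frame",
    "write_events_bed",
]


@dataclass
class OccupancyMap:
    """2-D histogram of body-part positions (frames per spatial bin)."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bodypart: str

    @property
    def n_valid_frames(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AreaSpec:
    """A named rectangular or circular region in coordinate space.

    Rectangles are parameterised by top-left origin plus width/height
    (image convention: the origin is the visually upper-left corner),
    circles by center and radius.
    """

    label: str
    shape: str  # "rectangle" | "circle"
    origin_x: float = 0.0
    origin_y: float = 0.0
    width: float = 0.0
    height: float = 0.0
    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.shape == "rectangle":
            if self.width <= 0 or self.height <= 0:
                raise ValueError(f"area {self.label!r}: width and height must be > 0")
        elif self.shape == "circle":
            if self.radius <= 0:
                raise ValueError(f"area {self.label!r}: radius must be > 0")
        else:
            raise ValueError(f"area {self.label!r}: shape must be rectangle or circle")

    @classmethod
    def rectangle(cls, label: str, origin_x: float, origin_y: float,
                  width: float, height: float) -> "AreaSpec":
        return cls(label, "rectangle", origin_x=origin_x, origin_y=origin_y,
                   width=width, height=height)

    @classmethod
    def circle(cls, label: str, center_x: float, center_y: float,
               radius: float) -> "AreaSpec":
        return cls(label, "circle", center_x=center_x, center_y=center_y,
                   radius=radius)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 2) array of x, y points."""
        p = np.asarray(points, float)
        if self.shape == "rectangle":
            return (
                (p[:, 0] >= self.origin_x)
                & (p[:, 0] < self.origin_x + self.width)
                & (p[:, 1] >= self.origin_y)
                & (p[:, 1] < self.origin_y + self.height)
            )
        d = np.hypot(p[:, 0] - self.center_x, p[:, 1] - self.center_y)
        return d <= self.radius

    def outline(self, n_points: int = 64) -> np.ndarray:
        """Polygonal outline (closed) for plotting in coordinate space."""
        if self.shape == "rectangle":
            x0, y0 = self.origin_x, self.origin_y
            x1, y1 = x0 + self.width, y0 + self.height
            return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]])
        th = np.linspace(0, 2 * np.pi, n_points + 1)
        return np.column_stack(
            [self.center_x + self.radius * np.cos(th),
             self.center_y + self.radius * np.sin(th)]
        )

    def translated(self, dx: float, dy: float) -> "AreaSpec":
        if self.shape == "rectangle":
            return AreaSpec.rectangle(self.label, self.origin_x + dx,
                                      self.origin_y + dy, self.width, self.height)
        return AreaSpec.circle(self.label, self.center_x + dx,
                               self.center_y + dy, self.radius)


@dataclass(frozen=True)
class InteractionEvent:
    """One chronological visit to an area; frame bounds are inclusive."""

    area_label: str
    start_frame: int
    end_frame: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")


@dataclass
class InteractionSummary:
    """Per-area interaction count and total time, zero-filled for quiet areas."""

    table: pd.DataFrame  # index: area label; columns: n_interactions, total_time_s

    def __getitem__(self, label: str) -> pd.Series:
        return self.table.loc[label]


def occupancy(
    t: TrackingTable | Sequence[TrackingTable],
    bodypart: str,
    bins: int | tuple[int, int] = 10,
    extent: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> OccupancyMap:
    """2-D occupancy histogram of a body part over the arena.

    Accepts a single table or a sequence of tables (the latter pools frames
    across animals, the data behind an average-occupancy heatmap).  Bin
    edges are returned so rendering is exactly reproducible.  Frames with
    missing coordinates are excluded; ``Σ counts`` equals the number of
    valid frames.
    """
    tables = [t] if isinstance(t, TrackingTable) else list(t)
    xy = np.vstack([tab.xy(bodypart) for tab in tables])
    xy = xy[~np.isnan(xy).any(axis=1)]
    if len(xy) == 0:
        raise ValueError("no valid frames to histogram")
    if np.isscalar(bins):
        bins = (int(bins), int(bins))
    if min(bins) < 1:
        raise ValueError("need at least 1 bin per axis")
    counts, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=extent
    )
    return OccupancyMap(counts=counts, x_edges=x_edges, y_edges=y_edges,
                        bodypart=bodypart)


def define_fields(specs: Iterable[AreaSpec]) -> list[AreaSpec]:
    """Validate a set of areas (unique labels, positive dimensions)."""
    out = list(specs)
    labels = [a.label for a in out]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate area labels: {sorted(dupes)}")
    return out


def import_posit_dict(posit: dict[str, Sequence[float]]) -> list[AreaSpec]:
    """Best-effort importer for the legacy 8-element positional area format.

    Compatibility shim, heuristic: the legacy descriptor is an 8-vector per
    label whose semantics are only partially recoverable.  The last four
    entries are interpreted as ``x, y, width, height`` of a rectangle; the
    first four are ignored.  Prefer :class:`AreaSpec` constructors for new
    code.
    """
    out = []
    for label, vec in posit.items():
        if len(vec) != 8:
            raise ValueError(f"{label!r}: expected an 8-element descriptor")
        x, y, w, h = vec[4:]
        out.append(AreaSpec.rectangle(label, x, y, w, h))
    return define_fields(out)


def detect_interactions(
    t: TrackingTable,
    bodypart: str,
    areas: Sequence[AreaSpec],
    min_frames: int = 1,
) -> list[InteractionEvent]:
    """Detect area visits as maximal runs of consecutive inside frames.

    Events from all areas are merged and sorted chronologically by start
    frame (ties broken by area label).  ``min_frames`` optionally drops
    events shorter than a debounce length; default keeps everything.
    An empty list is a valid result.
    """
    areas = define_fields(areas)
    if not areas:
        raise ValueError("areas must be non-empty")
    xy = t.xy(bodypart)
    events: list[InteractionEvent] = []
    for area in areas:
        inside = area.contains(xy)
        # maximal runs of True
        padded = np.concatenate([[False], inside, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        for s, e in zip(starts, ends):
            if e - s + 1 < min_frames:
                continue
            events.append(
                InteractionEvent(
                    area_label=area.label,
                    start_frame=int(s),
                    end_frame=int(e),
                    duration_s=(int(e) - int(s) + 1) / t.fps,
                )
            )
    events.sort(key=lambda ev: (ev.start_frame, ev.area_label))
    return events


def summarize_interactions(
    events: Sequence[InteractionEvent], areas: Sequence[AreaSpec] | Sequence[str]
) -> InteractionSummary:
    """Per-area event count and total interaction time (0 for unvisited areas)."""
    labels = [a.label if isinstance(a, AreaSpec) else a for a in areas]
    table = pd.DataFrame(
        0.0, index=pd.Index(labels, name="area"),
        columns=["n_interactions", "total_time_s"],
    )
    for ev in events:
        if ev.area_label not in table.index:
            raise KeyError(f"event references unknown area {ev.area_label!r}")
        table.loc[ev.area_label, "n_interactions"] += 1
        table.loc[ev.area_label, "total_time_s"] += ev.duration_s
    table["n_interactions"] = table["n_interactions"].astype(int)
    return InteractionSummary(table=table)


def events_to_frame(events: Sequence[InteractionEvent], fps: float) -> pd.DataFrame:
    """Chronological event table (the beginning/end-of-interaction report)."""
    return pd.DataFrame(
        [
            {
                "area": ev.area_label,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "start_s": ev.start_frame / fps,
                "end_s": (ev.end_frame + 1) / fps,
                "duration_s": ev.duration_s,
            }
            for ev in events
        ],
        columns=["area", "start_frame", "end_frame", "start_s", "end_s", "duration_s"],
    )


def write_events_bed(events: Sequence[InteractionEvent], path: str | Path) -> None:
    """BED-like half-open intervals on the frame axis (chrom = area label)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.area_label}\t{ev.start_frame}\t{ev.end_frame + 1}\n")
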