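"""Reading, validating, conditioning, calibrating and windowing tracking tables.

The central container is :class:`TrackingTable`: per-frame x/y (and optional
likelihood) coordinates for a set of named body parts, produced by a pose
estimator such as DeepLabCut.  Coordinates follow the image convention —
origin at the top-left, y increasing downward — because that is what pose
estimators emit.  Frame indices are 0-based and contiguous; time windows are
half-open ``[start, end)``.

Two CSV dialects are supported:

``dlc``
    The DeepLabCut export: three header rows (``scorer`` / ``bodyparts`` /
    ``coords``) with the coords row cycling ``x, y, likelihood`` per part.
``plain``
    A single header row with ``<part>_x, <part>_y[, <part>_likelihood]``
    columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrackingTable",
    "CalibrationSpec",
    "TimeWindow",
    "FormatError",
    "SchemaError",
    "UnitsError",
    "read_tracking",
    "write_tracking",
    "apply_likelihood_cutoff",
    "pixels_to_cm",
    "select_time_window",
    "to_hdf5",
    "from_hdf5",
]

_COORDS = ("x", "y", "likelihood")


class FormatError(ValueError):
    """A file does not parse as the requested tracking dialect."""


class SchemaError(ValueError):
    """Parsed columns do not form a valid body-part schema."""


class UnitsError(ValueError):
    """An operation was applied to a table in the wrong coordinate units."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Isotropic pixel→cm calibration from one known physical reference.

    A single reference length measured both in pixels and centimetres; the
    derived scale is applied to both axes (no homography / lens correction).
    """

    reference_length_px: float
    reference_length_cm: float

    def __post_init__(self) -> None:
        if self.reference_length_px <= 0 or self.reference_length_cm <= 0:
            raise ValueError("calibration reference lengths must be > 0")

    @property
    def cm_per_px(self) -> float:
        return self.reference_length_cm / self.reference_length_px

    def inverse(self) -> "CalibrationSpec":
        return CalibrationSpec(self.reference_length_cm, self.reference_length_px)


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"require 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})"
            )


@dataclass
class TrackingTable:
    """Per-frame body-part coordinates with frame rate and unit metadata.

    Parameters
    ----------
    data
        DataFrame with a two-level column index ``(bodypart, coord)`` where
        coord is ``x``, ``y`` and optionally ``likelihood``, one row per
        frame, integer index ``0..n-1``.
    fps
        Frame rate in frames per second (> 0).
    units
        ``"pixel"`` or ``"cm"``.
    frame_offset
        Index of row 0 in the original (un-windowed) recording.
    """

    data: pd.DataFrame
    fps: float
    units: str = "pixel"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.units not in ("pixel", "cm"):
            raise ValueError(f"units must be 'pixel' or 'cm', got {self.units!r}")
        if self.data.columns.nlevels != 2:
            raise SchemaError("data must have (bodypart, coord) columns")
        for part in self.bodyparts:
            coords = set(self.data[part].columns)
            if "x" not in coords or "y" not in coords:
                raise SchemaError(
                    f"body part {part!r} must have both x and y columns, has {sorted(coords)}"
                )
            if not coords <= set(_COORDS):
                raise SchemaError(f"unknown coordinate columns for {part!r}: {sorted(coords - set(_COORDS))}")
        lik = self.data.loc[:, (slice(None), "likelihood")] if self.has_likelihood else None
        if lik is not None:
            vals = lik.to_numpy(float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
            if not ok.all():
                raise ValueError("likelihood values must lie in [0, 1]")
        # rebuild a contiguous 0-based frame index
        self.data = self.data.reset_index(drop=True)
        self.data.index.name = "frame"

    # -- introspection -------------------------------------------------
    @property
    def bodyparts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def has_likelihood(self) -> bool:
        return "likelihood" in self.data.columns.get_level_values(1)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def _require_part(self, part: str) -> None:
        if part not in self.bodyparts:
            raise KeyError(
                f"unknown body part {part!r}; available: {self.bodyparts}"
            )

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) float array of x, y for one body part."""
        self._require_part(part)
        return self.data[part][["x", "y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        self._require_part(part)
        if not self.has_likelihood:
            raise SchemaError("table has no likelihood columns")
        return self.data[part]["likelihood"].to_numpy(float)

    def with_data(self, data: pd.DataFrame, **kw) -> "TrackingTable":
        return TrackingTable(
            data,
            fps=kw.get("fps", self.fps),
            units=kw.get("units", self.units),
            frame_offset=kw.get("frame_offset", self.frame_offset),
        )


def _table_from_columns(cols: Mapping[tuple[str, str], np.ndarray], fps: float,
                        units: str = "pixel") -> TrackingTable:
    df = pd.DataFrame(dict(cols))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return TrackingTable(df, fps=fps, units=units)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_tracking(path: str | Path, dialect: str = "dlc", fps: float = 30.0) -> TrackingTable:
    """Read a tracking CSV into a validated :class:`TrackingTable` (pixel units).

    ``fps`` must be supplied by the caller — CSV tracking exports carry no
    frame-rate metadata.  The default matches a common 30 fps camera.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dlc":
        return _read_dlc(path, fps)
    if dialect == "plain":
        return _read_plain(path, fps)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'dlc' or 'plain')")


def _read_dlc(path: Path, fps: float) -> TrackingTable:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: not a 3-row-header DLC file ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected scorer/bodyparts/coords header rows")
    coords = df.columns.get_level_values(2)
    bad = sorted(set(coords) - set(_COORDS))
    if bad:
        raise FormatError(
            f"{path}: 'coords' header row contains {bad}, expected only x/y/likelihood"
        )
    df = df.droplevel(0, axis=1)  # drop the scorer level
    df.columns.names = ["bodyparts", "coords"]
    return TrackingTable(df.astype(float), fps=fps, units="pixel")


def _read_plain(path: Path, fps: float) -> TrackingTable:
    df = pd.read_csv(path, float_precision="round_trip")
    cols: dict[tuple[str, str], np.ndarray] = {}
    for name in df.columns:
        base, _, suffix = name.rpartition("_")
        if not base or suffix not in _COORDS:
            if name.lower() in ("frame", "index"):
                continue
            raise FormatError(
                f"{path}: column {name!r} does not end in _x/_y/_likelihood"
            )
        cols[(base, suffix)] = df[name].to_numpy(float)
    if not cols:
        raise FormatError(f"{path}: no body-part columns found in header row")
    return _table_from_columns(cols, fps=fps)


def write_tracking(t: TrackingTable, path: str | Path, dialect: str = "dlc",
                   scorer: str = "pawtrack") -> None:
    """Write a table in either CSV dialect; read→write→read is lossless."""
    path = Path(path)
    if dialect == "dlc":
        df = t.data.copy()
        df.columns = pd.MultiIndex.from_tuples(
            [(scorer, part, coord) for part, coord in df.columns],
            names=["scorer", "bodyparts", "coords"],
        )
        df.to_csv(path)
    elif dialect == "plain":
        flat = t.data.copy()
        flat.columns = [f"{part}_{coord}" for part, coord in flat.columns]
        flat.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def to_hdf5(t: TrackingTable, path: str | Path) -> None:
    """HDF5 mirror of the CSV schema (one dataset per part/coord + attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fps"] = t.fps
        f.attrs["units"] = t.units
        f.attrs["frame_offset"] = t.frame_offset
        for part, coord in t.data.columns:
            f.create_dataset(f"{part}/{coord}", data=t.data[(part, coord)].to_numpy(float))


def from_hdf5(path: str | Path) -> TrackingTable:
    import h5py

    cols: dict[tuple[str, str], np.ndarray] = {}
    with h5py.File(path, "r") as f:
        fps = float(f.attrs["fps"])
        units = str(f.attrs["units"])
        offset = int(f.attrs["frame_offset"])
        for part in f:
            for coord in f[part]:
                cols[(part, coord)] = f[part][coord][()]
    t = _table_from_columns(cols, fps=fps, units=units)
    t.frame_offset = offset
    return t


# ---------------------------------------------------------------------------
# conditioning / calibration / windowing
# ---------------------------------------------------------------------------

def apply_likelihood_cutoff(
    t: TrackingTable, pcut: float
) -> tuple[TrackingTable, dict[str, int]]:
    """Condition coordinates whose estimator likelihood falls below ``pcut``.

    Frames with ``likelihood < pcut`` get x and y replaced by linear
    interpolation between the nearest frames at or above the cutoff; runs
    touching the start or end of the recording take the nearest valid value.
    Interpolating (rather than dropping frames) keeps the kinematic series
    continuous, so downstream speed estimates are not corrupted by gaps.

    Returns the conditioned table and a per-part count of conditioned frames.
    The operation is idempotent at a fixed ``pcut``: the anchor frames are
    unchanged, so re-interpolating reproduces the same values.
    """
    if not 0 <= pcut <= 1:
        raise ValueError("pcut must lie in [0, 1]")
    if not t.has_likelihood:
        raise SchemaError("table has no likelihood columns to threshold")
    out = t.data.copy()
    counts: dict[str, int] = {}
    frames = np.arange(t.n_frames)
    for part in t.bodyparts:
        lik = t.likelihood(part)
        good = lik >= pcut
        if not good.any():
            raise ValueError(
                f"body part {part!r}: no frames with likelihood >= {pcut}"
            )
        counts[part] = int((~good).sum())
        if counts[part] == 0:
            continue
        for coord in ("x", "y"):
            vals = out[(part, coord)].to_numpy(float)
            # np.interp holds end values flat outside the anchor range,
            # which implements the nearest-valid boundary rule.
            vals[~good] = np.interp(frames[~good], frames[good], vals[good])
            out[(part, coord)] = vals
    return t.with_data(out), counts


def pixels_to_cm(t: TrackingTable, c: CalibrationSpec) -> TrackingTable:
    """Scale all coordinates from pixel space to centimetres.

    Likelihood columns are untouched.  Raises :class:`UnitsError` if the
    table is already calibrated.
    """
    if t.units != "pixel":
        raise UnitsError("table is already in cm; refusing to rescale")
    out = t.data.copy()
    scale = c.cm_per_px
    for part in t.bodyparts:
        for coord in ("x", "y"):
            out[(part, coord)] = out[(part, coord)] * scale
    return t.with_data(out, units="cm")


def select_time_window(t: TrackingTable, w: TimeWindow) -> TrackingTable:
    """Keep frames in ``[floor(start_s*fps), floor(end_s*fps))``.

    The frame index is re-zeroed and the original offset recorded in
    ``frame_offset`` (cumulative across repeated windowing).
    """
    if w.end_s > t.n_frames / t.fps + 1e-9:
        raise ValueError(
            f"window end {w.end_s} s exceeds recording duration {t.duration_s} s"
        )
    lo = int(np.floor(w.start_s * t.fps))
    hi = int(np.floor(w.end_s * t.fps))
    if hi <= lo:
        raise ValueError(f"window [{w.start_s}, {w.end_s}) selects no frames")
    out = t.data.iloc[lo:hi]
    return t.with_data(out, frame_offset=t.frame_offset + lo)
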