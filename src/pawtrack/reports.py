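"""Multi-animal unified reports: motion metrics plus area interactions."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .io_tracking import TimeWindow, TrackingTable
from .kinematics import motion_metrics
from .spatial import AreaSpec, detect_interactions, summarize_interactions

__all__ = ["build_report"]


def build_report(
    tables: Sequence[TrackingTable],
    names: Sequence[str],
    bodypart: str,
    areas: Optional[Sequence[AreaSpec]] = None,
    w: Optional[TimeWindow] = None,
) -> pd.DataFrame:
    """One row per animal: distance/speed summaries and per-area interactions.

    Each row is exactly what the single-animal operations return — the
    report is a concatenation, with no cross-animal computation.  When
    ``areas`` is omitted the interaction columns are omitted too.
    """
    if len(tables) != len(names):
        raise ValueError(
            f"{len(tables)} tables but {len(names)} names"
        )
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise ValueError(f"duplicate animal names: {dupes}")
    rows = []
    for table, name in zip(tables, names):
        t = table
        m = motion_metrics(t, bodypart, w=w)
        row: dict = {
            "name": name,
            "total_distance": m.total_distance,
            "mean_speed": m.mean_speed,
            "max_speed": m.max_speed,
            "units": m.units,
            "window_start_s": w.start_s if w else 0.0,
            "window_end_s": w.end_s if w else t.duration_s,
        }
        if areas is not None:
            from .io_tracking import select_time_window

            tw = select_time_window(t, w) if w else t
            events = detect_interactions(tw, bodypart, areas)
            summary = summarize_interactions(events, areas)
            for label in summary.table.index:
                row[f"{label}_n_interactions"] = int(
                    summary.table.loc[label, "n_interactions"]
                )
                row[f"{label}_total_time_s"] = float(
                    summary.table.loc[label, "total_time_s"]
                )
        rows.append(row)
    return pd.DataFrame(rows)
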