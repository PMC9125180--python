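"""Plot helpers rendered from the exported data products.

Every figure here is a thin matplotlib view of a value the library already
computed (trajectory triples, occupancy grids, event tables, embeddings,
linkage matrices) — tests and pipelines assert on the data, never the
images.  All functions take/return a matplotlib Axes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .behavior import BehaviorLabels, Embedding
from .neural import SpatialActivityMap
from .spatial import AreaSpec, InteractionEvent, OccupancyMap

__all__ = [
    "plot_trajectory",
    "plot_occupancy",
    "plot_interactions",
    "plot_embedding",
    "plot_dendrogram",
    "plot_spatial_activity",
    "plot_epoch_spectrogram",
]


def _ax(ax):
    return ax if ax is not None else plt.subplots()[1]


def plot_trajectory(points: pd.DataFrame, ax=None, cmap: str = "viridis"):
    """Scatter of (x, y) coloured by time; y axis inverted (image convention)."""
    ax = _ax(ax)
    sc = ax.scatter(points["x"], points["y"], c=points["time_s"], s=4, cmap=cmap)
    ax.invert_yaxis()
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    plt.colorbar(sc, ax=ax, label="time (s)")
    return ax


def plot_occupancy(m: OccupancyMap, ax=None, vmax: Optional[float] = None,
                   cmap: str = "magma"):
    ax = _ax(ax)
    im = ax.pcolormesh(m.x_edges, m.y_edges, m.counts.T, vmax=vmax, cmap=cmap)
    ax.invert_yaxis()
    plt.colorbar(im, ax=ax, label="frames")
    return ax


def plot_interactions(events: Sequence[InteractionEvent], fps: float, ax=None):
    """Interaction timeline: one horizontal lane per area."""
    ax = _ax(ax)
    labels = sorted({ev.area_label for ev in events})
    lane = {l: i for i, l in enumerate(labels)}
    for ev in events:
        ax.hlines(lane[ev.area_label], ev.start_frame / fps,
                  (ev.end_frame + 1) / fps, lw=6)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("time (s)")
    return ax


def plot_embedding(E: Embedding, labels: Optional[BehaviorLabels] = None, ax=None):
    ax = _ax(ax)
    c = labels.labels if labels is not None else None
    ax.scatter(E.coords[:, 0], E.coords[:, 1], c=c, s=5, cmap="tab20")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax


def plot_dendrogram(labels: BehaviorLabels, ax=None, **kw):
    ax = _ax(ax)
    dendrogram(labels.linkage, ax=ax,
               color_threshold=labels.distance_threshold, **kw)
    ax.axhline(labels.distance_threshold, ls="--", c="grey")
    ax.set_ylabel(f"Ward height ({labels.units} features)")
    return ax


def plot_spatial_activity(m: SpatialActivityMap, ax=None, cmap: str = "inferno"):
    ax = _ax(ax)
    im = ax.pcolormesh(m.x_edges, m.y_edges, m.mean.T, cmap=cmap)
    ax.invert_yaxis()
    plt.colorbar(im, ax=ax, label="mean activity")
    return ax


def plot_epoch_spectrogram(epoch: np.ndarray, rate: float, channel: int = 0,
                           ax=None, nperseg: int = 256):
    """Short-time spectrogram of one extracted epoch (documentation example)."""
    from scipy.signal import spectrogram

    ax = _ax(ax)
    f, t, S = spectrogram(np.asarray(epoch)[channel], fs=rate,
                          nperseg=min(nperseg, np.asarray(epoch).shape[1]))
    ax.pcolormesh(t, f, 10 * np.log10(S + 1e-12), shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax
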