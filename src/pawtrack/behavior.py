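"""Unsupervised per-frame behavior classification.

The classifier works on *pairwise body-part distances*: for each frame, the
Euclidean distance between every unordered pair of selected body parts.
Distances are invariant to where the animal is and which way it faces, so
frames with the same posture land near each other in feature space
regardless of position in the arena.

Frames are grouped by hierarchical agglomerative clustering with Ward
linkage, cut at a user-chosen merge-height threshold; clusters are what the
experimenter then inspects and names (rearing, grooming, ...).  For
visualisation the same features are embedded in 2-D with t-SNE, tuned by
two well-tested heuristics — PCA initialisation, learning rate ``n/12`` and
perplexity ``n/100`` (clamped below at 5 for small n) — and the embedding is
scored by
three structure-preservation metrics:

* **KNN** — mean fraction of each point's k nearest neighbours shared
  between feature space and embedding (local structure);
* **KNC** — mean fraction of each class's k nearest class centroids shared
  between the two spaces (mesoscale structure);
* **CPD** — Spearman correlation of pairwise distances on a random
  subsample (global structure).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .io_tracking import TrackingTable

__all__ = [
    "FeatureMatrix",
    "BehaviorLabels",
    "TSNEConfig",
    "Embedding",
    "EmbeddingQuality",
    "BehaviorIntervals",
    "pairwise_features",
    "cluster_frames",
    "gap_threshold",
    "tsne_config",
    "tsne_embed",
    "embedding_quality",
    "cluster_histogram",
    "behavior_intervals",
    "representative_frames",
]


@dataclass
class FeatureMatrix:
    """Frames × body-part-pair distance matrix.

    Columns are all unordered pairs of the selected parts in lexicographic
    order, ``k(k−1)/2`` of them for k parts; values carry the units of the
    source coordinates (px or cm).
    """

    values: np.ndarray
    pairs: list[tuple[str, str]]
    units: str = "pixel"

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}-{b}" for a, b in self.pairs]
        return pd.DataFrame(self.values, columns=cols).rename_axis("frame")


@dataclass
class BehaviorLabels:
    """Per-frame cluster assignment plus the full Ward merge tree.

    ``labels`` are dense ids ``0..C−1``, re-indexed so cluster 0 is the
    largest (ties broken by first-occurring frame).  ``linkage`` is the
    standard (n−1, 4) merge-tree matrix: children, merge height, new size.
    ``distance_threshold`` is in Ward merge-height units of the feature
    space — the same number means coarser granularity on cm features than
    on pixel features, so the units are echoed here.
    """

    labels: np.ndarray
    linkage: np.ndarray
    distance_threshold: float
    units: str = "pixel"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.labels}).rename_axis("frame")

    def linkage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child1", "child2", "height", "size"]
        )


@dataclass(frozen=True)
class TSNEConfig:
    """t-SNE hyperparameters from the size-based heuristics.

    ``learning_rate = n/12`` and ``perplexity = max(n/100, 5)``: the
    perplexity formula degenerates for small n (perplexity must stay well
    above 1), so it is clamped from below; the learning rate keeps the
    plain formula.  Initialisation is always the first two principal
    components, scaled to small variance.
    """

    n: int
    learning_rate: float
    perplexity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 1 <= self.perplexity < (self.n - 1) / 3:
            raise ValueError(
                f"perplexity {self.perplexity} invalid for n={self.n}; "
                "need 1 <= perplexity < (n-1)/3"
            )


def tsne_config(n: int, seed: int = 0) -> TSNEConfig:
    """Heuristic t-SNE configuration for ``n`` frames.

    Learning rate ``n/12``; perplexity ``n/100`` clamped below at 5 (the
    clamp engages for n < 500).
    """
    return TSNEConfig(
        n=n,
        learning_rate=n / 12,
        perplexity=max(n / 100, 5.0),
        seed=seed,
    )


@dataclass
class Embedding:
    """Frames × 2 t-SNE coordinates (unitless)."""

    coords: np.ndarray
    config: Optional[TSNEConfig] = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, columns=["dim1", "dim2"]).rename_axis("frame")


@dataclass
class EmbeddingQuality:
    """KNN / KNC / CPD structure-preservation scores with their parameters."""

    knn: float
    knc: float
    cpd: float
    k_local: int
    k_class: int
    cpd_subsample: int

    def to_dict(self) -> dict:
        return {
            "knn": self.knn, "knc": self.knc, "cpd": self.cpd,
            "k_local": self.k_local, "k_class": self.k_class,
            "cpd_subsample": self.cpd_subsample,
        }


@dataclass
class BehaviorIntervals:
    """Maximal frame runs per cluster; the bridge from labels to epochs."""

    intervals: dict[int, list[tuple[int, int]]]
    fps: float

    def seconds(self, cluster: Optional[int] = None) -> list[tuple[float, float, int]]:
        """(start_s, end_s, cluster) triples, half-open in time, chronological."""
        items = (
            [(c, runs) for c, runs in self.intervals.items()]
            if cluster is None
            else [(cluster, self.intervals[cluster])]
        )
        out = [
            (s / self.fps, (e + 1) / self.fps, c)
            for c, runs in items
            for s, e in runs
        ]
        out.sort()
        return out


# ---------------------------------------------------------------------------
# features and clustering
# ---------------------------------------------------------------------------

def pairwise_features(t: TrackingTable, bp_list: Sequence[str]) -> FeatureMatrix:
    """Distances between all unordered pairs of the listed body parts.

    Condition the table first: missing coordinates are rejected because a
    NaN distance would silently poison the clustering.
    """
    parts = list(bp_list)
    if len(parts) < 2:
        raise ValueError("need at least 2 body parts for pairwise distances")
    for p in parts:
        t._require_part(p)
    pairs = sorted(combinations(sorted(set(parts)), 2))
    if len(set(parts)) != len(parts):
        raise ValueError("bp_list contains duplicates")
    coords = {p: t.xy(p) for p in parts}
    cols = []
    for a, b in pairs:
        d = np.linalg.norm(coords[a] - coords[b], axis=1)
        cols.append(d)
    values = np.column_stack(cols)
    if np.isnan(values).any():
        raise ValueError("missing coordinates in feature window; condition the table first")
    return FeatureMatrix(values=values, pairs=pairs, units=t.units)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Dense 0..C−1 ids ordered by decreasing size, ties by first frame."""
    ids, first = np.unique(raw, return_index=True)
    sizes = np.array([(raw == i).sum() for i in ids])
    order = sorted(range(len(ids)), key=lambda j: (-sizes[j], first[j]))
    mapping = {ids[j]: rank for rank, j in enumerate(order)}
    return np.array([mapping[v] for v in raw], dtype=int)


def cluster_frames(
    F: FeatureMatrix, distance_threshold: float, standardize: bool = False
) -> BehaviorLabels:
    """Ward agglomerative clustering of frames, cut at a merge-height threshold.

    Clusters are the connected components left after removing every merge
    whose Ward height exceeds ``distance_threshold`` (a merge exactly at the
    threshold is kept).  ``standardize`` optionally z-scores each distance
    column first — Ward on raw distances weights long body segments more,
    which is sometimes, but not always, what you want.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be > 0")
    X = F.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames to cluster")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=distance_threshold, criterion="distance")
    return BehaviorLabels(
        labels=_relabel_by_size(raw),
        linkage=Z,
        distance_threshold=distance_threshold,
        units=F.units,
    )


def gap_threshold(Z: np.ndarray, n_clusters: int) -> float:
    """Midpoint of the merge-height gap that yields exactly ``n_clusters``.

    With n−1 monotone Ward merges, cutting between the (C)-th and (C−1)-th
    largest heights leaves C components; this returns the midpoint of that
    gap, a convenient data-driven threshold when the cluster count is known
    (as it is for synthetic scenes).
    """
    heights = np.sort(Z[:, 2])
    m = len(heights)
    if not 2 <= n_clusters <= m:
        raise ValueError(f"n_clusters must be in [2, {m}]")
    lo = heights[m - n_clusters]        # largest merge kept
    hi = heights[m - n_clusters + 1]    # smallest merge cut
    return float((lo + hi) / 2)


# ---------------------------------------------------------------------------
# embedding and quality
# ---------------------------------------------------------------------------

def tsne_embed(F: FeatureMatrix, cfg: Optional[TSNEConfig] = None,
               seed: int = 0) -> Embedding:
    """2-D t-SNE of the feature matrix with PCA initialisation.

    The embedding is initialised from the first two principal components
    scaled so PC1 has standard deviation 1e-4 (small enough that early
    exaggeration can organise the map, while keeping the global PCA
    arrangement).  With a fixed config and seed the output is
    bit-reproducible on the same input.
    """
    n = F.n_frames
    if n < 30:
        raise ValueError("need at least 30 frames to embed")
    if cfg is None:
        cfg = tsne_config(n, seed=seed)
    if cfg.n != n:
        raise ValueError(f"config built for n={cfg.n} but features have {n} frames")
    X = F.values
    pcs = PCA(n_components=2, svd_solver="full").fit_transform(X)
    scale = pcs[:, 0].std()
    init = pcs / (scale if scale > 0 else 1.0) * 1e-4
    coords = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        learning_rate=cfg.learning_rate,
        init=init,
        random_state=cfg.seed,
    ).fit_transform(X)
    return Embedding(coords=np.asarray(coords, float), config=cfg)


def _knn_sets(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    return idx[:, :k]


def embedding_quality(
    F: FeatureMatrix | np.ndarray,
    E: Embedding | np.ndarray,
    labels: Optional[BehaviorLabels | np.ndarray] = None,
    k_local: int = 10,
    k_class: Optional[int] = None,
    cpd_subsample: int = 1000,
    seed: int = 0,
) -> EmbeddingQuality:
    """Score how well an embedding preserves feature-space structure.

    KNN (local): for each point, the fraction of its ``k_local`` nearest
    neighbours in feature space that are also among its ``k_local`` nearest
    in the embedding, averaged over points.  KNC (mesoscale): per class, the
    fraction of its ``k_class`` nearest class centroids preserved between
    the two spaces (classes are the agglomerative clusters; no external
    labels exist in this pipeline).  CPD (global): Spearman correlation of
    pairwise distances over a seeded subsample of ``cpd_subsample`` points.

    KNC is NaN when labels are absent or fewer than 2 classes exist.
    """
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, float)
    Y = E.coords if isinstance(E, Embedding) else np.asarray(E, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature matrix and embedding must have equal rows")
    n = X.shape[0]
    if k_local >= n:
        raise ValueError("k_local must be smaller than the number of points")

    # KNN: shared nearest-neighbour fraction
    nx = _knn_sets(X, k_local)
    ny = _knn_sets(Y, k_local)
    overlap = np.array(
        [len(np.intersect1d(nx[i], ny[i], assume_unique=True)) for i in range(n)]
    )
    knn = float(overlap.mean() / k_local)

    # KNC: preserved nearest class centroids
    knc = float("nan")
    kc_used = 0
    if labels is not None:
        lab = labels.labels if isinstance(labels, BehaviorLabels) else np.asarray(labels)
        classes = np.unique(lab)
        C = len(classes)
        if C >= 2:
            kc_used = k_class if k_class is not None else min(4, C - 1)
            if kc_used >= C:
                raise ValueError("k_class must be smaller than the number of classes")
            cx = np.vstack([X[lab == c].mean(axis=0) for c in classes])
            cy = np.vstack([Y[lab == c].mean(axis=0) for c in classes])
            dx = cdist(cx, cx)
            dy = cdist(cy, cy)
            np.fill_diagonal(dx, np.inf)
            np.fill_diagonal(dy, np.inf)
            fracs = []
            for i in range(C):
                near_x = set(np.argsort(dx[i], kind="stable")[:kc_used])
                near_y = set(np.argsort(dy[i], kind="stable")[:kc_used])
                fracs.append(len(near_x & near_y) / kc_used)
            knc = float(np.mean(fracs))

    # CPD: rank correlation of subsampled pairwise distances
    rng = np.random.default_rng(seed)
    m = min(cpd_subsample, n)
    sub = rng.choice(n, size=m, replace=False)
    dX = pdist(X[sub])
    dY = pdist(Y[sub])
    cpd = float(spearmanr(dX, dY).statistic)

    return EmbeddingQuality(
        knn=knn, knc=knc, cpd=cpd,
        k_local=k_local, k_class=kc_used, cpd_subsample=m,
    )


# ---------------------------------------------------------------------------
# label products
# ---------------------------------------------------------------------------

def cluster_histogram(labels: BehaviorLabels | np.ndarray) -> pd.Series:
    """Frames per cluster, indexed by cluster id.

    Small clusters are the usual tell for mislabeled frames — the histogram
    is the first thing to inspect after classification.
    """
    lab = labels.labels if isinstance(labels, BehaviorLabels) else np.asarray(labels)
    counts = np.bincount(lab)
    return pd.Series(counts, index=pd.RangeIndex(len(counts), name="cluster"),
                     name="n_frames")


def behavior_intervals(labels: BehaviorLabels | np.ndarray,
                       fps: float) -> BehaviorIntervals:
    """Maximal frame runs per cluster — when each behavior was manifested."""
    lab = labels.labels if isinstance(labels, BehaviorLabels) else np.asarray(labels)
    out: dict[int, list[tuple[int, int]]] = {int(c): [] for c in np.unique(lab)}
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            out[int(lab[start])].append((start, i - 1))
            start = i
    return BehaviorIntervals(intervals=out, fps=fps)


def mode_filter(labels: np.ndarray, window: int = 5) -> np.ndarray:
    """Optional temporal mode filter over per-frame labels (odd window).

    Off by default everywhere — each frame is classified independently —
    but useful to suppress single-frame label flicker before inspection.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    lab = np.asarray(labels)
    half = window // 2
    out = lab.copy()
    for i in range(len(lab)):
        seg = lab[max(0, i - half): i + half + 1]
        vals, cnt = np.unique(seg, return_counts=True)
        out[i] = vals[np.argmax(cnt)]
    return out


def representative_frames(
    F: FeatureMatrix | np.ndarray,
    labels: BehaviorLabels | np.ndarray,
    per_cluster: int = 5,
    seed: int = 0,
) -> dict[int, list[int]]:
    """Frame indices to inspect per cluster, nearest the cluster medoid first.

    The medoid is the member frame minimising total feature-space distance
    to the rest of its cluster; frames are returned ordered by distance to
    the medoid (ties broken by a seeded shuffle, then frame index), at most
    ``per_cluster`` of them.  Inspection of actual video frames is the
    experimenter's job; this picks which ones to look at.
    """
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, float)
    lab = labels.labels if isinstance(labels, BehaviorLabels) else np.asarray(labels)
    rng = np.random.default_rng(seed)
    out: dict[int, list[int]] = {}
    for c in np.unique(lab):
        members = np.flatnonzero(lab == c)
        D = cdist(X[members], X[members])
        medoid_pos = int(np.argmin(D.sum(axis=1)))
        dists = D[medoid_pos]
        jitter = rng.permutation(len(members))
        order = sorted(range(len(members)), key=lambda j: (dists[j], jitter[j]))
        out[int(c)] = [int(members[j]) for j in order[:per_cluster]]
    return out
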