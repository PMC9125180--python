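import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from pawtrack import (
    BehaviorSceneSpec,
    behavior_intervals,
    cluster_frames,
    cluster_histogram,
    embedding_quality,
    gap_threshold,
    make_behavior_frames,
    pairwise_features,
    representative_frames,
    tsne_config,
    tsne_embed,
)
from pawtrack.behavior import FeatureMatrix, mode_filter

from conftest import make_table
from oracles import brute_ward


def _features(values):
    values = np.asarray(values, float)
    k = values.shape[1]
    pairs = [(f"p{i}", f"p{j}") for i in range(k) for j in range(i + 1, k)]
    return FeatureMatrix(values=values, pairs=pairs[: values.shape[1]])


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def test_pairwise_feature_shape_and_values():
    t = make_table({
        "snout": [(0, 0)], "ear_R": [(3, 4)], "ear_L": [(0, 5)], "tail": [(12, 0)],
    })
    F = pairwise_features(t, ["snout", "ear_R", "ear_L", "tail"])
    assert F.values.shape == (1, 6)  # 4 parts -> 6 unordered pairs
    cols = dict(zip(F.pairs, F.values[0]))
    assert cols[("ear_R", "snout")] == pytest.approx(5.0)
    assert cols[("snout", "tail")] == pytest.approx(12.0)


def test_features_invariant_under_rigid_motion():
    rng = np.random.default_rng(8)
    pts = {p: rng.integers(0, 50, size=(40, 2)).astype(float)
           for p in ["a", "b", "c"]}
    F0 = pairwise_features(make_table(pts), ["a", "b", "c"])
    # translation on an integer grid is bit-exact
    F1 = pairwise_features(
        make_table({p: xy + [100.0, -50.0] for p, xy in pts.items()}), ["a", "b", "c"]
    )
    np.testing.assert_array_equal(F0.values, F1.values)
    # rotate about an arbitrary point
    ang = 0.83
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    F2 = pairwise_features(
        make_table({p: (xy - 25) @ R.T + 25 for p, xy in pts.items()}), ["a", "b", "c"]
    )
    np.testing.assert_allclose(F2.values, F0.values, rtol=1e-9)


def test_features_reject_bad_inputs():
    t = make_table({"a": [(0, 0)], "b": [(1, 1)]})
    with pytest.raises(ValueError):
        pairwise_features(t, ["a"])
    with pytest.raises(KeyError):
        pairwise_features(t, ["a", "zz"])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_two_separated_clusters_recovered_exactly():
    table, truth = make_behavior_frames(
        BehaviorSceneSpec(n_clusters=2, frames_per_cluster=40,
                          separation_noise_ratio=10, seed=5)
    )
    F = pairwise_features(table, [f"part{i}" for i in range(4)])
    Z = cluster_frames(F, 1e9).linkage
    labels = cluster_frames(F, gap_threshold(Z, 2))
    assert labels.n_clusters == 2
    assert adjusted_rand_score(truth.labels, labels.labels) == 1.0


def test_threshold_above_root_gives_one_cluster():
    rng = np.random.default_rng(0)
    F = _features(rng.normal(size=(30, 3)))
    labels = cluster_frames(F, 1e9)
    assert labels.n_clusters == 1
    with pytest.raises(ValueError):
        cluster_frames(F, 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_merge_tree_matches_brute_force_ward(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 41))
    X = rng.normal(size=(n, int(rng.integers(2, 7))))
    Z = cluster_frames(_features(X), 1.0).linkage
    Zb = brute_ward(X)
    np.testing.assert_array_equal(np.sort(Z[:, :2], axis=1), Zb[:, :2])
    np.testing.assert_allclose(Z[:, 2], Zb[:, 2], rtol=1e-9)
    np.testing.assert_array_equal(Z[:, 3], Zb[:, 3])


def test_labels_dense_and_ordered_by_size():
    table, _ = make_behavior_frames(
        BehaviorSceneSpec(n_clusters=3, frames_per_cluster=30, seed=2)
    )
    F = pairwise_features(table, [f"part{i}" for i in range(4)])
    Z = cluster_frames(F, 1e9).linkage
    labels = cluster_frames(F, gap_threshold(Z, 3))
    counts = cluster_histogram(labels)
    assert list(counts.index) == list(range(labels.n_clusters))
    assert (counts.to_numpy()[:-1] >= counts.to_numpy()[1:]).all()
    assert counts.sum() == labels.n_frames


# ---------------------------------------------------------------------------
# t-SNE heuristics and embedding
# ---------------------------------------------------------------------------

def test_heuristic_arithmetic_large_n():
    cfg = tsne_config(1200)
    assert cfg.learning_rate == pytest.approx(100.0)   # 1200/12
    assert cfg.perplexity == pytest.approx(12.0)       # 1200/100


def test_heuristic_clamps_small_n():
    cfg = tsne_config(300)
    assert cfg.learning_rate == pytest.approx(25.0)  # n/12, no clamp
    assert cfg.perplexity == 5.0  # perplexity clamp engages below n = 500
    assert tsne_config(499).perplexity == 5.0
    assert tsne_config(501).perplexity > 5.0


def test_embedding_separates_well_separated_clusters():
    table, truth = make_behavior_frames(
        BehaviorSceneSpec(n_clusters=2, frames_per_cluster=60,
                          separation_noise_ratio=10, seed=3)
    )
    F = pairwise_features(table, [f"part{i}" for i in range(4)])
    E = tsne_embed(F, tsne_config(F.n_frames, seed=0))
    # nearest-centroid classification in the embedding recovers the labels
    c0 = E.coords[truth.labels == 0].mean(axis=0)
    c1 = E.coords[truth.labels == 1].mean(axis=0)
    pred = (np.linalg.norm(E.coords - c1, axis=1)
            < np.linalg.norm(E.coords - c0, axis=1)).astype(int)
    assert adjusted_rand_score(truth.labels, pred) == 1.0


def test_embedding_requires_enough_frames():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        tsne_embed(_features(rng.normal(size=(10, 3))))


# ---------------------------------------------------------------------------
# embedding quality
# ---------------------------------------------------------------------------

def _identity_setup(n=200, seed=0):
    rng = np.random.default_rng(seed)
    informative = rng.normal(size=(n, 2))
    X = np.column_stack([informative, np.zeros((n, 3))])
    return _features(X), informative


def test_identity_embedding_scores_perfectly():
    F, E = _identity_setup()
    lab = (E[:, 0] > 0).astype(int)
    q = embedding_quality(F, E, lab, k_local=10, cpd_subsample=150, seed=0)
    assert q.knn == pytest.approx(1.0)
    assert q.cpd == pytest.approx(1.0)
    assert q.knc == pytest.approx(1.0)


def test_quality_invariant_under_isometry_of_embedding():
    F, E = _identity_setup(seed=1)
    ang = 1.1
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    E2 = 3.7 * (E @ R.T) + [50.0, -2.0]
    q1 = embedding_quality(F, E, k_local=10, cpd_subsample=150, seed=0)
    q2 = embedding_quality(F, E2, k_local=10, cpd_subsample=150, seed=0)
    assert q1.knn == pytest.approx(q2.knn)
    assert q1.cpd == pytest.approx(q2.cpd)


def test_permuted_embedding_scores_at_null_level():
    n, k = 500, 10
    F, E = _identity_setup(n=n, seed=2)
    rng = np.random.default_rng(0)
    knns, cpds = [], []
    for s in range(10):
        perm = rng.permutation(n)
        q = embedding_quality(F, E[perm], k_local=k, cpd_subsample=300, seed=s)
        knns.append(q.knn)
        cpds.append(q.cpd)
    null = k / (n - 1)  # expected shared-neighbour fraction for random ranks
    assert np.mean(knns) == pytest.approx(null, abs=3 * null)
    assert abs(np.mean(cpds)) < 0.1


def test_quality_parameter_validation():
    F, E = _identity_setup(n=50)
    with pytest.raises(ValueError):
        embedding_quality(F, E, k_local=50)
    with pytest.raises(ValueError):
        embedding_quality(F, E[:-1])


# ---------------------------------------------------------------------------
# label products
# ---------------------------------------------------------------------------

def test_cluster_histogram_and_intervals_examples():
    counts = cluster_histogram(np.array([0, 0, 1]))
    assert counts.to_dict() == {0: 2, 1: 1}
    iv = behavior_intervals(np.array([0, 0, 1, 1, 0]), fps=2.0)
    assert iv.intervals == {0: [(0, 1), (4, 4)], 1: [(2, 3)]}
    # seconds view is half-open
    assert iv.seconds(1) == [(1.0, 2.0, 1)]


def test_intervals_partition_frames():
    rng = np.random.default_rng(5)
    lab = rng.integers(0, 4, size=300)
    iv = behavior_intervals(lab, fps=30.0)
    covered = np.zeros(300, dtype=int)
    for c, runs in iv.intervals.items():
        for s, e in runs:
            covered[s:e + 1] += 1
            assert (lab[s:e + 1] == c).all()
    assert (covered == 1).all()


def test_mode_filter_removes_single_frame_flicker():
    lab = np.array([0, 0, 1, 0, 0])
    np.testing.assert_array_equal(mode_filter(lab, 3), [0, 0, 0, 0, 0])


def test_representative_frames_medoid_order():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 5))
    lab = np.array([0] * 25 + [1] * 14 + [2])
    reps = representative_frames(_features(X), lab, per_cluster=5, seed=0)
    assert reps[2] == [39]  # singleton cluster yields its only frame
    for c, idx in reps.items():
        assert (lab[idx] == c).all()
    # brute-force: medoid minimises summed distance, order follows distance
    members = np.flatnonzero(lab == 0)
    D = np.linalg.norm(X[members][:, None] - X[members][None], axis=2)
    medoid = members[np.argmin(D.sum(axis=1))]
    assert reps[0][0] == medoid
    d_to_medoid = {m: np.linalg.norm(X[m] - X[medoid]) for m in members}
    expected = sorted(members, key=lambda m: d_to_medoid[m])[:5]
    assert sorted(reps[0]) == sorted(int(m) for m in expected)
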