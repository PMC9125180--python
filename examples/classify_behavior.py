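"""Unsupervised behavior classification on a posture-cluster scene.

Generates frames from four distinct body-part geometries placed at random
positions and orientations, classifies them from pairwise distances alone,
embeds them with the heuristic-tuned t-SNE, and scores the embedding.
"""

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

scene = BehaviorSceneSpec(n_clusters=4, n_parts=4, frames_per_cluster=60,
                          separation_noise_ratio=8.0, seed=2)
table, truth = make_behavior_frames(scene)
print(f"{table.n_frames} frames, 4 generative posture clusters, "
      f"separation/noise ratio {truth.separation_noise_ratio:.1f}")

bp_list = ["part0", "part1", "part2", "part3"]
F = pairwise_features(table, bp_list)          # 4 parts -> 6 distance columns

# cut the Ward tree inside the merge-height gap that leaves 4 clusters
Z = cluster_frames(F, distance_threshold=1e9).linkage
threshold = gap_threshold(Z, 4)
labels = cluster_frames(F, threshold)
print(f"Ward threshold {threshold:.1f} ({labels.units} feature units) "
      f"-> {labels.n_clusters} clusters")
print("frames per cluster:", cluster_histogram(labels).to_dict())
print("ARI vs generative labels:",
      adjusted_rand_score(truth.labels, labels.labels))

cfg = tsne_config(F.n_frames, seed=0)
E = tsne_embed(F, cfg)
q = embedding_quality(F, E, labels, cpd_subsample=200, seed=0)
print(f"t-SNE (lr={cfg.learning_rate:.0f}, perplexity={cfg.perplexity:.0f}): "
      f"KNN={q.knn:.2f} KNC={q.knc:.2f} CPD={q.cpd:.2f}")
# KNN/KNC/CPD near 1 mean the map preserves local, mesoscale and global
# structure of the posture features

iv = behavior_intervals(labels, table.fps)
runs0 = iv.intervals[0][:3]
print(f"cluster 0 first runs (frames): {runs0}")
reps = representative_frames(F, labels, per_cluster=3, seed=0)
print(f"frames to inspect per cluster: {reps}")
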