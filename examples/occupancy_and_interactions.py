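"""Arena occupancy and object-interaction events on a random-walk fixture.

Simulates an open-field session, bins the snout positions into an
occupancy histogram, defines two objects, and reports every visit.
"""

from pawtrack import (
    AreaSpec,
    TrajectorySpec,
    detect_interactions,
    events_to_frame,
    make_trajectory,
    occupancy,
    summarize_interactions,
)

table, _ = make_trajectory(TrajectorySpec(
    kind="bounded_random_walk", duration_s=120, fps=30, step_scale=1.0,
    arena=(59, 59), seed=16))

occ = occupancy(table, "snout", bins=10, extent=((0, 59), (0, 59)))
print(f"occupancy grid {occ.counts.shape}, total frames binned "
      f"{occ.n_valid_frames} of {table.n_frames}")
print(f"most occupied bin holds {int(occ.counts.max())} frames")

objects = [
    AreaSpec.rectangle("obj_A", 10, 10, 12, 12),
    AreaSpec.circle("obj_B", 45, 45, 8),
]
events = detect_interactions(table, "snout", objects)
print(f"\n{len(events)} interaction events (chronological):")
print(events_to_frame(events, table.fps).head().to_string(index=False))

summary = summarize_interactions(events, objects)
print("\nper-object totals (count and seconds inside):")
print(summary.table.to_string())
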