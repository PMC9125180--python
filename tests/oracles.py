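"""Independent brute-force oracles used to check the library implementations.

Everything here is written against the definitions, not the library code:
plain Python/numpy loops, O(n²)–O(n³) where that is the simplest faithful
form.  Tests compare the fast implementations against these.
"""

from __future__ import annotations

import numpy as np


def interp_gaps_oracle(x: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Walk each sub-threshold gap and linearly interpolate across it.

    Boundary runs (gap touching either end) take the nearest valid value.
    """
    x = x.astype(float).copy()
    n = len(x)
    i = 0
    while i < n:
        if good[i]:
            i += 1
            continue
        j = i
        while j < n and not good[j]:
            j += 1
        prev_idx = i - 1  # last valid before the gap, -1 if none
        next_idx = j if j < n else -1
        for k in range(i, j):
            if prev_idx < 0 and next_idx < 0:
                raise ValueError("no valid frames at all")
            elif prev_idx < 0:
                x[k] = x[next_idx]
            elif next_idx < 0:
                x[k] = x[prev_idx]
            else:
                frac = (k - prev_idx) / (next_idx - prev_idx)
                x[k] = x[prev_idx] + frac * (x[next_idx] - x[prev_idx])
        i = j
    return x


def brute_ward(X: np.ndarray) -> np.ndarray:
    """O(n³) Ward agglomeration from first principles.

    At each step merges the pair of clusters whose merge distance
    sqrt(2·|A||B|/(|A|+|B|)) · ‖c_A − c_B‖ (the square root of twice the
    increase in total within-cluster sum of squares) is minimal.  Returns
    the standard (n−1, 4) linkage matrix with children sorted per row.
    """
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    cent = {i: X[i].astype(float) for i in range(n)}
    size = {i: 1 for i in range(n)}
    Z = []
    nxt = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = np.sqrt(2 * size[a] * size[b] / (size[a] + size[b])) * \
                    np.linalg.norm(cent[a] - cent[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[nxt] = members
        cent[nxt] = X[members].mean(axis=0)
        size[nxt] = len(members)
        Z.append((min(a, b), max(a, b), d, len(members)))
        nxt += 1
    return np.array(Z)


def interactions_oracle(xy: np.ndarray, areas, fps: float):
    """Per-frame membership test + run-length scan, one area at a time.

    Returns (area_label, start_frame, end_frame) triples sorted like the
    implementation's contract: by start frame, ties by label.
    """
    events = []
    for area in areas:
        run_start = None
        for i in range(len(xy) + 1):
            inside = i < len(xy) and _point_in(area, xy[i])
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                events.append((area.label, run_start, i - 1))
                run_start = None
    events.sort(key=lambda e: (e[1], e[0]))
    return events


def _point_in(area, p) -> bool:
    if area.shape == "rectangle":
        return (area.origin_x <= p[0] < area.origin_x + area.width
                and area.origin_y <= p[1] < area.origin_y + area.height)
    return np.hypot(p[0] - area.center_x, p[1] - area.center_y) <= area.radius
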