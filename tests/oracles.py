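"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately recompute quantities by naive enumeration (per-millisecond
discretization, per-cell hill climbing) so they share no code path with the
implementations they check.
"""

import numpy as np

from sausi.vocabulary import BEHAVIOR_REGISTRY, SNIFF_SUBTYPES, STATE

MS = 1000


def ms_state_duration(events, behavior: str, span) -> tuple[float, int]:
    """Duration by counting 1 ms ticks of each event interval clipped to the
    span (events accumulate independently, as the metric defines)."""
    t0 = int(round(span[0] * MS))
    t1 = int(round(span[1] * MS))
    total = 0.0
    count = 0
    for e in events:
        if e.behavior != behavior or e.event_type != STATE:
            continue
        count += 1
        a = max(t0, int(round(e.onset * MS)))
        b = min(t1, int(round(e.offset * MS)))
        total += max(0, b - a) / MS
    return total, count


def ms_point_count(events, behavior: str, span) -> int:
    return sum(
        1
        for e in events
        if e.behavior == behavior
        and e.event_type != STATE
        and span[0] <= e.onset < span[1]
    )


def ms_all_sniff(events, span) -> float:
    return sum(ms_state_duration(events, b, span)[0] for b in SNIFF_SUBTYPES)


def ms_first_shelter(events, entry_time: float | None, span) -> float:
    cutoff = span[1] if entry_time is None else entry_time
    total = 0.0
    for e in events:
        if e.behavior != "Tunnel Shelter":
            continue
        a = max(span[0], e.onset)
        b = min(cutoff, e.offset)
        ticks = int(round(b * MS)) - int(round(a * MS))
        total += max(0, ticks) / MS
    return total


def brute_force_basins(density: np.ndarray) -> np.ndarray:
    """Per-cell hill climbing: from each cell repeatedly move to the best of
    itself and its 8 neighbors (max density; ties to the lowest flat index)
    until a fixed point; return the peak flat index per cell."""
    H, W = density.shape
    out = np.empty((H, W), dtype=int)
    for i in range(H):
        for j in range(W):
            ci, cj = i, j
            while True:
                best_v = density[ci, cj]
                best = (ci, cj)
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = ci + di, cj + dj
                        if not (0 <= ni < H and 0 <= nj < W):
                            continue
                        v = density[ni, nj]
                        if v > best_v or (
                            v == best_v and ni * W + nj < best[0] * W + best[1]
                        ):
                            best_v = v
                            best = (ni, nj)
                if best == (ci, cj):
                    break
                ci, cj = best
            out[i, j] = ci * W + cj
    return out
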