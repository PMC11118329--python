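"""Threat-imminence analysis: behavior aligned to nose-nose distance.

Defensive behaviors in the assay order along proximity to the social
stimulus: hesitancy behaviors (tunnel sheltering, reversing) dominate at
large distance before engagement, while social fear (freezing, reactivity)
appears at close range during and after sniffing.  This module quantifies
that continuum by binning test-phase frames on nose-nose distance and
computing per-behavior occurrence rates per bin, and by producing raster
structures (behavior intervals + the distance trace on a common time axis)
for single-session visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_sessions import EthogramEvent, EventLog, SessionRecord
from .vocabulary import POINT, STATE, allowed_actor, event_type_of


@dataclass
class ImminenceProfile:
    """Per-distance-bin behavior rates.

    ``rates`` holds, per behavior: for state behaviors the fraction of bin
    frames with the behavior active (in [0, 1]); for point behaviors the
    event rate per bin-second.  Bins with no frames are flagged NaN, not
    zero.
    """

    bin_edges: np.ndarray
    frame_counts: np.ndarray          # frames per bin
    rates: pd.DataFrame               # bins x behaviors
    behavior_types: dict[str, str]    # behavior -> 'state' | 'point'
    fps: float


def _active_mask(
    events: EventLog, behavior: str, times: np.ndarray
) -> np.ndarray:
    active = np.zeros(len(times), dtype=bool)
    for e in events.for_behavior(behavior):
        active |= (times >= e.onset) & (times <= e.offset)
    return active


def distance_bin_profile(
    session: SessionRecord,
    distance: np.ndarray,
    bins: np.ndarray,
    behaviors: list[str] | None = None,
) -> ImminenceProfile:
    """Bin test-phase frames by nose-nose distance and compute per-behavior
    rates per bin.  Frames with invalid (NaN) distance are excluded, not
    imputed.  Bin membership is half-open ``[lo, hi)``."""
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2 or not np.all(np.diff(bins) > 0):
        raise ValueError("bins must be strictly increasing edges")
    fps = session.trajectory.fps
    times = session.trajectory.times
    t0, t1 = session.test_span
    distance = np.asarray(distance, dtype=float)
    sel = (times >= t0) & (times < t1) & np.isfinite(distance)
    d = distance[sel]
    t = times[sel]
    which = np.digitize(d, bins) - 1          # -1 / n_bins-1 edge handling below
    in_range = (which >= 0) & (d < bins[-1])
    which = which[in_range]
    t = t[in_range]
    n_bins = len(bins) - 1
    frame_counts = np.bincount(which, minlength=n_bins)

    if behaviors is None:
        behaviors = sorted({e.behavior for e in session.events})
    btypes = {b: event_type_of(b) for b in behaviors}
    rates = pd.DataFrame(
        index=pd.IntervalIndex.from_breaks(bins, closed="left"),
        columns=behaviors, dtype=float,
    )
    empty = frame_counts == 0
    for b in behaviors:
        if btypes[b] == STATE:
            active = _active_mask(session.events, b, t)
            num = np.bincount(which[active], minlength=n_bins)
            vals = np.where(empty, np.nan, num / np.maximum(frame_counts, 1))
        else:
            # assign each point event to the bin of its nearest valid frame
            counts = np.zeros(n_bins)
            for e in session.events.for_behavior(b):
                if not (t0 <= e.onset < t1) or len(t) == 0:
                    continue
                j = int(np.argmin(np.abs(t - e.onset)))
                if abs(t[j] - e.onset) <= 1.0 / fps:
                    counts[which[j]] += 1
            bin_seconds = frame_counts / fps
            vals = np.where(empty, np.nan, counts / np.maximum(bin_seconds, 1e-12))
        rates[b] = vals
    return ImminenceProfile(
        bin_edges=bins,
        frame_counts=frame_counts,
        rates=rates,
        behavior_types=btypes,
        fps=fps,
    )


def default_bins(arena_diagonal: float, width: float = 2.0) -> np.ndarray:
    """Distance bin edges: fixed-width bins from 0 to the arena diagonal."""
    n = int(np.ceil(arena_diagonal / width))
    return np.arange(0, (n + 1) * width, width, dtype=float)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


@dataclass
class SessionRaster:
    """Time-aligned behavior intervals and distance trace for one session.

    Lossless: :meth:`to_event_log` reconstructs the original event log.
    """

    intervals: dict[str, list[tuple[float, float]]]   # state behaviors
    points: dict[str, list[float]]                    # point behaviors
    times: np.ndarray
    distance: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def to_event_log(self) -> EventLog:
        events = []
        for b, spans in self.intervals.items():
            for onset, offset in spans:
                events.append(
                    EthogramEvent(b, allowed_actor(b), STATE, onset, offset)
                )
        for b, onsets in self.points.items():
            for onset in onsets:
                events.append(EthogramEvent(b, allowed_actor(b), POINT, onset))
        return EventLog(events)

    def to_frame(self) -> pd.DataFrame:
        """Serializable long-format table (kind, behavior, onset, offset)."""
        rows = []
        for b, spans in self.intervals.items():
            rows += [
                {"kind": "state", "behavior": b, "onset": s, "offset": e}
                for s, e in spans
            ]
        for b, onsets in self.points.items():
            rows += [
                {"kind": "point", "behavior": b, "onset": s, "offset": np.nan}
                for s in onsets
            ]
        return pd.DataFrame(rows, columns=["kind", "behavior", "onset", "offset"])


def session_raster(
    session: SessionRecord, distance: np.ndarray
) -> SessionRaster:
    """Build the raster structure for one scored session."""
    intervals: dict[str, list[tuple[float, float]]] = {}
    points: dict[str, list[float]] = {}
    for e in session.events:
        if e.event_type == STATE:
            intervals.setdefault(e.behavior, []).append((e.onset, e.offset))
        else:
            points.setdefault(e.behavior, []).append(e.onset)
    return SessionRaster(
        intervals=intervals,
        points=points,
        times=session.trajectory.times,
        distance=np.asarray(distance, dtype=float),
        subject_id=session.subject_id,
        condition=session.condition,
    )
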