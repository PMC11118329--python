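"""Ethogram metrics: per-session behavioral scores.

Computes every entry of the behavior-score table from a session's event log
and trajectory: sniffing durations (with the ``All Sniff`` composite =
face + body + anogenital + tail), conspecific sniff bouts, social reactivity
(% of conspecific sniff bouts answered by a dart/flinch/jump), social
freezing, tunnel hesitancy (first-entry sheltering, reversing, latency to
the social chamber), prosocial initiations, social-chamber preference,
grooming, non-social freezing, aggression, jumps, and baseline thigmotaxis.

Span conventions: spans are half-open ``[start, end)`` for point-event
inclusion; state intervals are clipped to the span for durations.  Ratio
metrics with an empty denominator (reactivity with zero conspecific sniffs)
and latencies for subjects that never enter the social chamber are *flagged*
as NaN rather than guessed; downstream z-scoring skips flagged entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .io_sessions import (
    ArenaGeometry,
    EventLog,
    KeypointTrajectory,
    SessionConfig,
    SessionRecord,
)
from .vocabulary import ALL_SNIFF, POINT, SNIFF_SUBTYPES, STATE, canonical_behavior, event_type_of

Span = tuple[float, float]

ZONE_ORDER = ("home", "tunnel", "social", "unknown")


@dataclass
class ZoneSequence:
    """Per-frame arena-zone labels for one animal's reference node."""

    labels: np.ndarray  # array of str, one of ZONE_ORDER
    fps: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U7")
        known = np.isin(self.labels, ZONE_ORDER)
        if not known.all():
            bad = sorted(set(self.labels[~known]))
            raise ValueError(f"unknown zone labels {bad}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def entries(self, zone: str) -> np.ndarray:
        """Frame indices at which the animal enters *zone*."""
        inz = self.labels == zone
        if inz.size == 0:
            return np.array([], dtype=int)
        starts = np.flatnonzero(inz & ~np.concatenate(([False], inz[:-1])))
        return starts

    def first_entry_time(self, zone: str, span: Span) -> float:
        """Time (s) of the first frame labelled *zone* within half-open *span*,
        or NaN if the zone is never visited."""
        t = self.times
        in_span = (t >= span[0]) & (t < span[1])
        hits = np.flatnonzero(in_span & (self.labels == zone))
        return float(t[hits[0]]) if hits.size else float("nan")

    def zone_time(self, zone: str, span: Span) -> float:
        """Total time (s) spent in *zone* within *span*, one frame = 1/fps s."""
        t = self.times
        sel = (t >= span[0]) & (t < span[1])
        return float(np.count_nonzero(self.labels[sel] == zone)) / self.fps


def classify_zones(
    traj: KeypointTrajectory,
    arena: ArenaGeometry,
    reference: str = "trunk",
    animal: str = "experimental",
) -> ZoneSequence:
    """Assign each frame to home / tunnel / social by point-in-polygon test
    of the reference node (trunk by default, the stable single-node proxy for
    whole-body chamber membership).  Frames with an invalid reference node
    are labelled ``unknown``."""
    xy, valid = traj.node(animal, reference)
    labels = np.full(traj.n_frames, "unknown", dtype="U7")
    if valid.any():
        pts = shapely.points(xy[valid, 0], xy[valid, 1])
        out = np.full(int(valid.sum()), "unknown", dtype="U7")
        for name, poly in (
            ("home", arena.home_chamber),
            ("tunnel", arena.tunnel),
            ("social", arena.social_chamber),
        ):
            hit = shapely.covers(poly, pts)
            out[(out == "unknown") & hit] = name
        labels[valid] = out
    return ZoneSequence(labels, traj.fps)


# ---------------------------------------------------------------------------
# event-log metrics
# ---------------------------------------------------------------------------


def _overlap(onset: float, offset: float, span: Span) -> float:
    return max(0.0, min(offset, span[1]) - max(onset, span[0]))


def state_duration(events: EventLog, behavior: str, span: Span) -> float:
    """Total duration (s) of a state behavior's intervals clipped to *span*.

    ``'All Sniff'`` is accepted as a composite and equals the sum of the four
    sniff subtype durations.
    """
    if behavior.strip().lower() == ALL_SNIFF.lower():
        return sum(state_duration(events, b, span) for b in SNIFF_SUBTYPES)
    behavior = canonical_behavior(behavior)
    if event_type_of(behavior) != STATE:
        raise TypeError(f"{behavior!r} is a point behavior; use point_count")
    return sum(
        _overlap(e.onset, e.offset, span) for e in events.for_behavior(behavior)
    )


def point_count(events: EventLog, behavior: str, span: Span) -> int:
    """Number of point events of *behavior* with onset in half-open *span*."""
    behavior = canonical_behavior(behavior)
    if event_type_of(behavior) != POINT:
        raise TypeError(f"{behavior!r} is a state behavior; use state_duration")
    return sum(
        1 for e in events.for_behavior(behavior) if span[0] <= e.onset < span[1]
    )


def social_reactivity_pct(events: EventLog, span: Span) -> float:
    """Reactivity bouts as a percentage of conspecific sniff bouts;
    NaN (flagged undefined) when the conspecific never sniffed."""
    sniffs = point_count(events, "Conspecific Sniff", span)
    if sniffs == 0:
        return float("nan")
    reacts = point_count(events, "Social Reactivity", span)
    return 100.0 * reacts / sniffs


def chamber_preference_pct(zones: ZoneSequence, span: Span) -> float:
    """Social-chamber time as a percentage of the full span length (tunnel
    and unknown frames count in the denominator only)."""
    length = span[1] - span[0]
    if length <= 0:
        raise ValueError("span must be non-empty")
    return 100.0 * zones.zone_time("social", span) / length


@dataclass
class TunnelHesitancy:
    first_shelter_s: float
    reverse_count: int
    reverse_s: float
    latency_to_social_s: float  # NaN = never entered the social chamber


def tunnel_hesitancy(events: EventLog, zones: ZoneSequence, span: Span) -> TunnelHesitancy:
    """Hesitancy metrics for the test phase.

    ``first_shelter_s`` sums *all* tunnel-shelter intervals preceding the
    first social-chamber entry (sheltering can happen on several crossings
    before the animal commits); intervals are clipped at the entry time.
    If the animal never enters, latency is flagged NaN and all shelters count.
    """
    entry = zones.first_entry_time("social", span)
    cutoff = span[1] if np.isnan(entry) else entry
    first_shelter = sum(
        _overlap(e.onset, e.offset, (span[0], cutoff))
        for e in events.for_behavior("Tunnel Shelter")
    )
    reverses = [
        e for e in events.for_behavior("Reverse in Tunnel")
        if _overlap(e.onset, e.offset, span) > 0 or span[0] <= e.onset < span[1]
    ]
    reverse_s = sum(_overlap(e.onset, e.offset, span) for e in reverses)
    latency = float("nan") if np.isnan(entry) else entry - span[0]
    return TunnelHesitancy(
        first_shelter_s=float(first_shelter),
        reverse_count=len(reverses),
        reverse_s=float(reverse_s),
        latency_to_social_s=latency,
    )


def nose_distance_series(traj: KeypointTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Euclidean nose-nose distance (cm) between the two animals,
    with a validity mask (False where either nose is untracked)."""
    xy_e, v_e = traj.node("experimental", "nose")
    xy_c, v_c = traj.node("conspecific", "nose")
    valid = v_e & v_c
    dist = np.full(traj.n_frames, np.nan)
    dist[valid] = np.hypot(
        xy_e[valid, 0] - xy_c[valid, 0], xy_e[valid, 1] - xy_c[valid, 1]
    )
    return dist, valid


def thigmotaxis_pct(
    traj: KeypointTrajectory,
    arena: ArenaGeometry,
    span: Span,
    margin_cm: float = 2.0,
) -> float:
    """Percentage of valid baseline frames with the trunk within
    ``margin_cm`` of the home-chamber wall."""
    xy, valid = traj.node("experimental", "trunk")
    t = traj.times
    sel = valid & (t >= span[0]) & (t < span[1])
    if not sel.any():
        return float("nan")
    pts = shapely.points(xy[sel, 0], xy[sel, 1])
    d = shapely.distance(pts, arena.home_chamber.exterior)
    return 100.0 * float(np.count_nonzero(d <= margin_cm)) / int(sel.sum())


# ---------------------------------------------------------------------------
# full score table
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "face_sniff_s",
    "body_sniff_s",
    "anogenital_sniff_s",
    "tail_sniff_s",
    "all_sniff_s",
    "conspecific_sniff_bouts",
    "social_reactivity_pct",
    "social_freeze_s",
    "first_tunnel_shelter_s",
    "reverse_count",
    "reverse_s",
    "latency_to_social_s",
    "prosocial_initiations",
    "chamber_preference_pct",
    "groom_s",
    "nonsocial_freeze_baseline_s",
    "nonsocial_freeze_test_s",
    "aggression_s",
    "jump_count",
    "thigmotaxis_pct",
]


def score_session(
    session: SessionRecord, config: SessionConfig | None = None
) -> pd.Series:
    """Compute the full behavior-score row for one session.

    Social metrics are evaluated on the test span, baseline-only metrics
    (non-social freezing, thigmotaxis) on the baseline span; non-social
    freezing is reported for both phases.
    """
    config = config or SessionConfig()
    events = session.events
    base = session.baseline_span
    test = session.test_span
    zones = classify_zones(session.trajectory, config.arena)
    hes = tunnel_hesitancy(events, zones, test)
    row = {
        "face_sniff_s": state_duration(events, "Face Sniff", test),
        "body_sniff_s": state_duration(events, "Body Sniff", test),
        "anogenital_sniff_s": state_duration(events, "Anogenital Sniff", test),
        "tail_sniff_s": state_duration(events, "Tail Sniff", test),
        "all_sniff_s": state_duration(events, ALL_SNIFF, test),
        "conspecific_sniff_bouts": point_count(events, "Conspecific Sniff", test),
        "social_reactivity_pct": social_reactivity_pct(events, test),
        "social_freeze_s": state_duration(events, "Social Freeze", test),
        "first_tunnel_shelter_s": hes.first_shelter_s,
        "reverse_count": hes.reverse_count,
        "reverse_s": hes.reverse_s,
        "latency_to_social_s": hes.latency_to_social_s,
        "prosocial_initiations": point_count(events, "Social Initiation", test),
        "chamber_preference_pct": chamber_preference_pct(zones, test),
        "groom_s": state_duration(events, "Groom", test),
        "nonsocial_freeze_baseline_s": state_duration(events, "Non-social Freeze", base),
        "nonsocial_freeze_test_s": state_duration(events, "Non-social Freeze", test),
        "aggression_s": state_duration(events, "Aggression", test),
        "jump_count": point_count(events, "Jump", test),
        "thigmotaxis_pct": thigmotaxis_pct(
            session.trajectory, config.arena, base, config.thigmotaxis_margin_cm
        ),
    }
    return pd.Series(row, index=SCORE_COLUMNS, name=session.subject_id)


def score_cohort(
    sessions: list[SessionRecord], config: SessionConfig | None = None
) -> pd.DataFrame:
    """Score a list of sessions into one table (subject_id index, plus
    ``condition`` and ``sex`` metadata columns)."""
    rows = []
    meta = []
    for s in sessions:
        rows.append(score_session(s, config))
        meta.append({"condition": s.condition, "sex": s.sex})
    table = pd.DataFrame(rows)
    table.index.name = "subject_id"
    md = pd.DataFrame(meta, index=table.index)
    return pd.concat([md, table], axis=1)
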