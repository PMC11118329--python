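"""Ethogram metrics: printed-formula examples, oracle spot checks, invariances."""

import numpy as np
import pandas as pd
import pytest

from sausi.ethogram import (
    ZoneSequence,
    chamber_preference_pct,
    classify_zones,
    nose_distance_series,
    point_count,
    score_session,
    social_reactivity_pct,
    state_duration,
    tunnel_hesitancy,
)
from sausi.io_sessions import (
    ArenaGeometry,
    EthogramEvent,
    EventLog,
    KeypointTrajectory,
    SessionRecord,
)
from sausi.vocabulary import SNIFF_SUBTYPES

from conftest import make_trajectory, random_event_log
from oracles import ms_all_sniff, ms_point_count, ms_state_duration

TEST = (180.0, 780.0)


def ev(behavior, onset, offset=None, actor="experimental"):
    etype = "state" if offset is not None else "point"
    return EthogramEvent(behavior, actor, etype, onset, offset)


# ---------------------------------------------------------------------------
# durations and counts
# ---------------------------------------------------------------------------


def test_single_interval_duration():
    log = EventLog([ev("Social Freeze", 192.0, 194.5)])
    assert state_duration(log, "Social Freeze", TEST) == pytest.approx(2.5)


def test_all_sniff_is_sum_of_subtypes():
    """All Sniff = face + body + anogenital + tail sniff."""
    log = EventLog([
        ev("Face Sniff", 200, 203),
        ev("Body Sniff", 210, 212),
        ev("Anogenital Sniff", 220, 221),
        ev("Tail Sniff", 230, 230.5),
    ])
    assert state_duration(log, "All Sniff", TEST) == pytest.approx(6.5)
    total = sum(state_duration(log, b, TEST) for b in SNIFF_SUBTYPES)
    assert state_duration(log, "All Sniff", TEST) == total


def test_interval_clipped_by_span():
    log = EventLog([ev("Groom", 770.0, 790.0)])
    assert state_duration(log, "Groom", TEST) == pytest.approx(10.0)


def test_duration_rejects_point_label():
    with pytest.raises(TypeError):
        state_duration(EventLog(), "Jump", TEST)


def test_point_count_and_boundary_rule():
    """Half-open span: events exactly at span end are excluded."""
    log = EventLog([
        ev("Social Initiation", 200.0),
        ev("Social Initiation", 300.0),
        ev("Social Initiation", 780.0),   # at span end
        ev("Social Initiation", 180.0),   # at span start: included
    ])
    assert point_count(log, "Social Initiation", TEST) == 3
    assert point_count(EventLog(), "Social Initiation", TEST) == 0
    with pytest.raises(TypeError):
        point_count(log, "Groom", TEST)


def test_social_reactivity_ratio():
    """Reactivity = reactivity bouts / conspecific sniffs * 100%."""
    sniffs = [ev("Conspecific Sniff", 200 + i, actor="conspecific") for i in range(10)]
    reacts = [ev("Social Reactivity", 250.0), ev("Social Reactivity", 260.0)]
    assert social_reactivity_pct(EventLog(sniffs + reacts), TEST) == pytest.approx(20.0)
    assert social_reactivity_pct(EventLog(sniffs[:5]), TEST) == pytest.approx(0.0)
    # empty denominator is flagged, not an error and not zero
    assert np.isnan(social_reactivity_pct(EventLog(reacts), TEST))


# ---------------------------------------------------------------------------
# zones
# ---------------------------------------------------------------------------


def _pinned_traj(x, y, n=60, fps=30.0):
    coords = np.zeros((n, 2, 8, 2))
    coords[..., 0] = x
    coords[..., 1] = y
    return KeypointTrajectory(coords, np.ones((n, 2, 8), bool), fps)


def test_zones_pinned_at_social_centroid():
    arena = ArenaGeometry()
    cx, cy = arena.social_chamber.centroid.coords[0]
    zones = classify_zones(_pinned_traj(cx, cy), arena)
    assert (zones.labels == "social").all()


def test_zone_path_home_tunnel_social():
    """A straight walk yields one entry per zone, in order."""
    arena = ArenaGeometry()
    n = 90
    xs = np.linspace(10, 65, n)
    coords = np.zeros((n, 2, 8, 2))
    coords[..., 0] = xs[:, None, None]
    coords[..., 1] = 15.0
    traj = KeypointTrajectory(coords, np.ones((n, 2, 8), bool), 30.0)
    zones = classify_zones(traj, arena)
    assert list(zones.labels[[0, n // 2, -1]]) == ["home", "tunnel", "social"]
    for zone in ("home", "tunnel", "social"):
        assert len(zones.entries(zone)) == 1


def test_zone_invalid_reference_is_unknown():
    arena = ArenaGeometry()
    traj = _pinned_traj(15, 15, n=10)
    traj.valid[4, 0, 4] = False
    traj.coords[4, 0, 4] = np.nan
    zones = classify_zones(traj, arena)
    assert zones.labels[4] == "unknown"
    assert (np.delete(zones.labels, 4) == "home").all()


def test_chamber_preference_values():
    fps = 30.0
    n = int(600 * fps)
    labels = np.full(n, "home", dtype="U7")
    labels[: n // 2] = "social"
    zones = ZoneSequence(labels, fps)
    assert chamber_preference_pct(zones, (0, 600)) == pytest.approx(50.0)
    zones_all_home = ZoneSequence(np.full(n, "home", dtype="U7"), fps)
    assert chamber_preference_pct(zones_all_home, (0, 600)) == pytest.approx(0.0)
    # 45 s social, 540 s home, 15 s tunnel -> 7.5 %
    labels = np.concatenate([
        np.full(int(45 * fps), "social"),
        np.full(int(540 * fps), "home"),
        np.full(int(15 * fps), "tunnel"),
    ])
    zones = ZoneSequence(labels, fps)
    assert chamber_preference_pct(zones, (0, 600)) == pytest.approx(7.5)


def test_zone_percentages_sum_to_100(si_session, tiny_cfg):
    rec, _ = si_session
    zones = classify_zones(rec.trajectory, tiny_cfg.arena)
    span = rec.test_span
    total = sum(
        100.0 * zones.zone_time(z, span) / (span[1] - span[0])
        for z in ("home", "tunnel", "social", "unknown")
    )
    assert total == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# tunnel hesitancy
# ---------------------------------------------------------------------------


def _zones_with_entry(entry_t, fps=30.0, span=TEST):
    n = int(span[1] * fps)
    labels = np.full(n, "home", dtype="U7")
    if entry_t is not None:
        labels[int(entry_t * fps):] = "social"
    return ZoneSequence(labels, fps)


def test_first_shelter_sums_all_pre_entry_intervals():
    """Sheltering can happen on several crossings before committing."""
    log = EventLog([
        ev("Tunnel Shelter", 185.0, 200.0),
        ev("Tunnel Shelter", 210.0, 220.0),
    ])
    zones = _zones_with_entry(221.0)
    hes = tunnel_hesitancy(log, zones, TEST)
    assert hes.first_shelter_s == pytest.approx(25.0)
    assert hes.latency_to_social_s == pytest.approx(41.0)


def test_shelter_after_first_entry_excluded():
    log = EventLog([
        ev("Tunnel Shelter", 185.0, 200.0),
        ev("Tunnel Shelter", 230.0, 240.0),   # after entry
    ])
    zones = _zones_with_entry(221.0)
    assert tunnel_hesitancy(log, zones, TEST).first_shelter_s == pytest.approx(15.0)


def test_never_entering_flags_latency():
    log = EventLog([
        ev("Tunnel Shelter", 185.0, 200.0),
        ev("Tunnel Shelter", 700.0, 720.0),
    ])
    zones = _zones_with_entry(None)
    hes = tunnel_hesitancy(log, zones, TEST)
    assert np.isnan(hes.latency_to_social_s)
    assert hes.first_shelter_s == pytest.approx(35.0)


def test_reverse_metrics():
    log = EventLog([
        ev("Reverse in Tunnel", 190.0, 191.5),
        ev("Reverse in Tunnel", 205.0, 206.0),
    ])
    hes = tunnel_hesitancy(log, _zones_with_entry(300.0), TEST)
    assert hes.reverse_count == 2
    assert hes.reverse_s == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# nose distance
# ---------------------------------------------------------------------------


def test_nose_distance_345_triangle():
    traj = _pinned_traj(0, 0, n=3)
    traj.coords[:, 0, 0] = [0.0, 0.0]
    traj.coords[:, 1, 0] = [3.0, 4.0]
    dist, valid = nose_distance_series(traj)
    assert dist[0] == pytest.approx(5.0)
    traj.coords[:, 1, 0] = [0.0, 0.0]
    dist, _ = nose_distance_series(traj)
    assert dist[0] == pytest.approx(0.0)
    traj.valid[1, 0, 0] = False
    dist, valid = nose_distance_series(traj)
    assert not valid[1] and np.isnan(dist[1])
    assert valid[0] and valid[2]


# ---------------------------------------------------------------------------
# score_session behavior
# ---------------------------------------------------------------------------


def test_empty_event_log_scores(tiny_cfg, gh_session):
    rec, _ = gh_session
    empty = SessionRecord(
        subject_id="e", sex="F", condition="GH",
        trajectory=rec.trajectory, events=EventLog(),
        baseline_span=rec.baseline_span, test_span=rec.test_span,
    )
    row = score_session(empty, tiny_cfg.session_config())
    assert row["all_sniff_s"] == 0
    assert row["jump_count"] == 0
    assert np.isnan(row["social_reactivity_pct"])
    assert np.isfinite(row["chamber_preference_pct"])


def test_score_row_deterministic(tiny_cfg, gh_session):
    rec, _ = gh_session
    r1 = score_session(rec, tiny_cfg.session_config())
    r2 = score_session(rec, tiny_cfg.session_config())
    pd.testing.assert_series_equal(r1, r2)


def test_metrics_invariant_to_event_order():
    rng = np.random.default_rng(3)
    log = random_event_log(rng)
    shuffled = EventLog(list(rng.permutation(np.array(log.events, dtype=object))))
    for b in ("Social Freeze", "All Sniff", "Groom"):
        assert state_duration(log, b, TEST) == state_duration(shuffled, b, TEST)
    assert point_count(log, "Jump", TEST) == point_count(shuffled, "Jump", TEST)


def test_oracle_spot_check_random_logs():
    """Metrics match per-millisecond brute force on a handful of random logs
    (the full 200-log sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        log = random_event_log(rng)
        for b in ("Social Freeze", "Groom", "Aggression", "Tunnel Shelter"):
            expect, count = ms_state_duration(log.events, b, TEST)
            assert state_duration(log, b, TEST) == pytest.approx(
                expect, abs=1e-3 * max(count, 1)
            )
        assert state_duration(log, "All Sniff", TEST) == pytest.approx(
            ms_all_sniff(log.events, TEST), abs=1e-3 * len(log)
        )
        for b in ("Jump", "Social Initiation", "Conspecific Sniff"):
            assert point_count(log, b, TEST) == ms_point_count(log.events, b, TEST)
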