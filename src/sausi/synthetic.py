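"""Synthetic two-mouse session generator.

Simulates the full assay structure — a 3-minute solo baseline for the
experimental mouse followed by a 10-minute dyadic test with a conspecific in
the social chamber — as a semi-Markov sequence of behavioral segments
(idle, locomotion, tunnel sheltering and reversing, approach + sniffing,
social freezing, grooming, aggression) with condition-dependent parameters,
and renders it into 8-node keypoint trajectories plus a ground-truth event
log.

Movement model: the body center moves along straight polyline legs at a
state-specific speed (or holds position for stationary states); heading
follows the direction of motion.  The skeleton is rigid within each
behavioral segment: per segment the generator draws an elongation factor,
a head-yaw angle (front nodes rotated about the trunk) and a body-bend
angle (rear nodes rotated about the trunk), so postures differ by state —
which is what gives the downstream angle-feature embedding its structure —
while node-pair distances stay constant within a segment in the noise-free
limit.  Gaussian keypoint jitter and random missing points are added on top.

The default group contrast (GH = group-housed vs SI = isolated) is an
invented calibration, not a measured one: isolation multiplies the
freeze-on-sniff probability x10, reactivity x3, mean tunnel-shelter dwell
x4 and aggression propensity x5, and halves prosocial initiation propensity,
leaving chamber preference parameters untouched.  These magnitudes were
chosen once to give clearly separated groups at realistic cohort sizes
(18 per group); see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .io_sessions import (
    ANIMAL_NAMES,
    N_ANIMALS,
    N_NODES,
    ArenaGeometry,
    EthogramEvent,
    EventLog,
    KeypointTrajectory,
    SessionConfig,
    SessionRecord,
)
from .vocabulary import CONSPECIFIC, EXPERIMENTAL, POINT, STATE

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionParams:
    """Behavioral propensities for one housing condition."""

    p_freeze_given_sniff: float = 0.06
    p_react_given_sniff: float = 0.08
    initiation_weight: float = 2.0     # approach-and-sniff propensity
    shelter_mean_s: float = 3.0        # mean tunnel-shelter dwell
    p_reverse: float = 0.12            # tunnel reverse probability per crossing
    aggression_weight: float = 0.10
    conspecific_sniff_rate_per_min: float = 5.0
    home_visit_weight: float = 0.6

    def __post_init__(self) -> None:
        for name in ("p_freeze_given_sniff", "p_react_given_sniff", "p_reverse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "initiation_weight",
            "shelter_mean_s",
            "aggression_weight",
            "conspecific_sniff_rate_per_min",
            "home_visit_weight",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_conditions() -> dict[str, ConditionParams]:
    gh = ConditionParams()
    si = replace(
        gh,
        p_freeze_given_sniff=min(1.0, gh.p_freeze_given_sniff * 10),
        p_react_given_sniff=min(1.0, gh.p_react_given_sniff * 3),
        shelter_mean_s=gh.shelter_mean_s * 4,
        initiation_weight=gh.initiation_weight * 0.5,
        aggression_weight=gh.aggression_weight * 5,
        p_reverse=min(1.0, gh.p_reverse * 2),
    )
    return {"GH": gh, "SI": si}


@dataclass
class GeneratorConfig:
    """Session structure, arena, condition parameters, and noise levels."""

    fps: float = 30.0
    baseline_s: float = 180.0
    test_s: float = 600.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    conditions: dict[str, ConditionParams] = field(default_factory=default_conditions)
    jitter_sd_cm: float = 0.12
    missing_rate: float = 0.01
    swap_rate: float = 0.0   # identity-swap windows per frame; 0 = clean tracks

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.baseline_s <= 0 or self.test_s <= 0:
            raise ValueError("fps and phase lengths must be positive")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.swap_rate <= 1:
            raise ValueError("noise rates must be in [0, 1]")
        if self.jitter_sd_cm < 0:
            raise ValueError("jitter sd must be >= 0")

    @property
    def baseline_span(self) -> tuple[float, float]:
        return (0.0, self.baseline_s)

    @property
    def test_span(self) -> tuple[float, float]:
        return (self.baseline_s, self.baseline_s + self.test_s)

    @property
    def n_frames(self) -> int:
        return int(round((self.baseline_s + self.test_s) * self.fps))

    def session_config(self) -> SessionConfig:
        return SessionConfig(
            arena=self.arena,
            baseline_span=self.baseline_span,
            test_span=self.test_span,
            fps=self.fps,
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style testing."""

    condition: str
    state_exp: np.ndarray      # per-frame behavioral state, experimental mouse
    state_consp: np.ndarray    # per-frame state, conspecific ('absent' in baseline)
    zone_true: np.ndarray      # per-frame arena zone of the noise-free body center
    summaries: pd.Series       # behavior-score columns recomputed from the truth
    segments_exp: list[tuple[int, int, str]] = field(default_factory=list)
    swap_windows: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# skeleton rendering
# ---------------------------------------------------------------------------

_BASE_OFFSETS = np.array(
    [
        [3.5, 0.0],    # nose
        [2.4, 0.0],    # head
        [2.0, 0.9],    # left_ear
        [2.0, -0.9],   # right_ear
        [0.0, 0.0],    # trunk
        [-1.6, 1.0],   # left_hip
        [-1.6, -1.0],  # right_hip
        [-3.2, 0.0],   # tail_base
    ]
)
_FRONT = np.array([0, 1, 2, 3])
_REAR = np.array([5, 6, 7])


@dataclass(frozen=True)
class _Posture:
    """State-specific posture distribution.

    ``yaw`` rotates nose + ears about the head node (head cocking), ``bend``
    rotates the rear nodes about the trunk (spine curl), ``spread`` scales
    hip width (hunching widens the stance); all sampled once per segment so
    the skeleton is rigid within a segment.
    """

    elong: float
    yaw_mean: float
    yaw_sd: float
    bend_mean: float
    bend_sd: float
    spread_mean: float
    spread_sd: float


_POSTURES: dict[str, _Posture] = {
    "idle": _Posture(1.00, 0.00, 0.15, 0.15, 0.10, 1.00, 0.05),
    "locomote": _Posture(1.08, 0.00, 0.08, 0.05, 0.05, 1.00, 0.04),
    "approach": _Posture(1.15, 0.00, 0.05, 0.03, 0.03, 1.00, 0.04),
    "sniff": _Posture(1.25, 0.45, 0.10, 0.05, 0.05, 1.00, 0.04),
    "social_freeze": _Posture(0.72, 0.00, 0.03, 0.85, 0.06, 1.45, 0.05),
    "nonsocial_freeze": _Posture(0.75, 0.00, 0.03, 0.85, 0.06, 1.45, 0.05),
    "tunnel_shelter": _Posture(0.80, 0.00, 0.05, 0.50, 0.06, 1.25, 0.05),
    "tunnel_reverse": _Posture(0.95, 0.00, 0.08, 0.30, 0.05, 1.10, 0.05),
    "groom": _Posture(0.68, 0.80, 0.15, 1.20, 0.12, 0.80, 0.05),
    "aggress": _Posture(1.10, 0.30, 0.20, 0.30, 0.15, 1.10, 0.08),
}
_HEAD_IDX = 1
_HIP_IDX = np.array([5, 6])


@dataclass
class _Plan:
    """Render plan for one behavioral segment of one animal."""

    f0: int
    f1: int
    state: str
    waypoints: np.ndarray          # (k, 2); k == 1 means hold position
    heading: float | None = None   # fixed heading for stationary segments
    posture_state: str | None = None


def _polyline(waypoints: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample *n* points at uniform arc length along a polyline; return
    positions and per-point tangent headings."""
    w = np.asarray(waypoints, dtype=float)
    if len(w) == 1 or n == 1:
        pos = np.tile(w[-1], (n, 1))
        return pos, np.full(n, np.nan)
    seg = np.diff(w, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        pos = np.tile(w[0], (n, 1))
        return pos, np.full(n, np.nan)
    cum = np.concatenate(([0.0], np.cumsum(seg_len)))
    s = np.linspace(0.0, total, n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pos = w[idx] + seg[idx] * frac[:, None]
    heading = np.arctan2(seg[idx, 1], seg[idx, 0])
    return pos, heading


def _render_animal(
    plans: list[_Plan], n_frames: int, rng: np.random.Generator, jitter_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render plans into node coordinates.

    Returns ``(coords (n, 8, 2), valid (n, 8), centers (n, 2))``; frames not
    covered by any plan stay invalid (the conspecific's baseline).
    """
    coords = np.full((n_frames, N_NODES, 2), np.nan)
    valid = np.zeros((n_frames, N_NODES), dtype=bool)
    centers = np.full((n_frames, 2), np.nan)
    last_heading = rng.uniform(-math.pi, math.pi)
    for plan in plans:
        n = plan.f1 - plan.f0
        if n <= 0:
            continue
        pos, tangent = _polyline(plan.waypoints, n)
        heading = np.where(
            np.isnan(tangent),
            plan.heading if plan.heading is not None else last_heading,
            tangent,
        )
        last_heading = float(heading[-1])
        pst = _POSTURES[plan.posture_state or plan.state]
        elong = max(0.4, rng.normal(pst.elong, 0.04))
        yaw = rng.choice([-1.0, 1.0]) * rng.normal(pst.yaw_mean, pst.yaw_sd)
        bend = rng.choice([-1.0, 1.0]) * rng.normal(pst.bend_mean, pst.bend_sd)
        spread = max(0.3, rng.normal(pst.spread_mean, pst.spread_sd))
        local = _BASE_OFFSETS.copy()
        local[:, 0] *= elong
        local[_HIP_IDX, 1] *= spread
        # spine curl: rear nodes rotate about the trunk
        cb, sb = math.cos(bend), math.sin(bend)
        local[_REAR] = local[_REAR] @ np.array([[cb, sb], [-sb, cb]])
        # head cock: nose and ears rotate about the head node
        cy, sy = math.cos(yaw), math.sin(yaw)
        head = local[_HEAD_IDX].copy()
        front = np.array([0, 2, 3])  # nose and ears
        rel = local[front] - head
        local[front] = head + rel @ np.array([[cy, sy], [-sy, cy]])
        ch, sh = np.cos(heading), np.sin(heading)
        # world = center + R(heading) @ local, vectorized over frames and nodes
        wx = pos[:, 0:1] + local[None, :, 0] * ch[:, None] - local[None, :, 1] * sh[:, None]
        wy = pos[:, 1:2] + local[None, :, 0] * sh[:, None] + local[None, :, 1] * ch[:, None]
        coords[plan.f0 : plan.f1, :, 0] = wx
        coords[plan.f0 : plan.f1, :, 1] = wy
        valid[plan.f0 : plan.f1] = True
        centers[plan.f0 : plan.f1] = pos
    if jitter_sd > 0:
        jitter = rng.normal(0.0, jitter_sd, size=coords.shape)
        coords = np.where(valid[:, :, None], coords + jitter, coords)
    return coords, valid, centers


# ---------------------------------------------------------------------------
# timeline construction
# ---------------------------------------------------------------------------

_SPEED = {"locomote": 8.0, "approach": 12.0, "tunnel_reverse": 6.0, "cross": 8.0}
_SNIFF_SUBTYPE_P = (
    ("Face Sniff", 0.35),
    ("Body Sniff", 0.30),
    ("Anogenital Sniff", 0.25),
    ("Tail Sniff", 0.10),
)
_JUMP_RATE_PER_MIN = 0.2


class _Timeline:
    """Frame-gridded segment/event accumulator for one animal."""

    def __init__(self, fps: float):
        self.fps = fps
        self.plans: list[_Plan] = []
        self.events: list[EthogramEvent] = []
        self.f = 0

    def t(self, frame: int) -> float:
        return frame / self.fps

    def frames(self, dur_s: float) -> int:
        return max(1, int(round(dur_s * self.fps)))

    def add(
        self,
        state: str,
        n_frames: int,
        waypoints: np.ndarray,
        heading: float | None = None,
        posture_state: str | None = None,
        behavior: str | None = None,
    ) -> tuple[int, int]:
        f0, f1 = self.f, self.f + n_frames
        self.plans.append(_Plan(f0, f1, state, np.atleast_2d(waypoints), heading, posture_state))
        if behavior is not None:
            self.events.append(
                EthogramEvent(behavior, EXPERIMENTAL, STATE, self.t(f0), self.t(f1))
            )
        self.f = f1
        return f0, f1

    def point(self, behavior: str, frame: int, actor: str = EXPERIMENTAL) -> None:
        self.events.append(EthogramEvent(behavior, actor, POINT, self.t(frame)))


def _interior_point(
    poly, rng: np.random.Generator, margin: float = 4.0
) -> np.ndarray:
    x0, y0, x1, y1 = poly.bounds
    m = min(margin, (x1 - x0) / 2 - 0.5, (y1 - y0) / 2 - 0.5)
    for _ in range(64):
        p = rng.uniform((x0 + m, y0 + m), (x1 - m, y1 - m))
        if poly.covers(shapely.Point(p)):
            return p
    return np.array(poly.centroid.coords[0])


def _wall_point(poly, rng: np.random.Generator, inset: float = 2.0) -> np.ndarray:
    """A point *inset* cm inside the polygon boundary (wall-hugging target)."""
    x0, y0, x1, y1 = poly.bounds
    side = rng.integers(4)
    if side == 0:
        return np.array([rng.uniform(x0 + inset, x1 - inset), y0 + inset])
    if side == 1:
        return np.array([rng.uniform(x0 + inset, x1 - inset), y1 - inset])
    if side == 2:
        return np.array([x0 + inset, rng.uniform(y0 + inset, y1 - inset)])
    return np.array([x1 - inset, rng.uniform(y0 + inset, y1 - inset)])


def _move_frames(a: np.ndarray, b: np.ndarray, speed: float, fps: float) -> int:
    return max(1, int(round(np.hypot(*(b - a)) / speed * fps)))


def _build_experimental(
    cfg: GeneratorConfig, params: ConditionParams, rng: np.random.Generator,
    consp_centers: np.ndarray,
) -> _Timeline:
    arena = cfg.arena
    fps = cfg.fps
    tl = _Timeline(fps)
    home, tunnel, social = arena.home_chamber, arena.tunnel, arena.social_chamber
    hx0, hy0, hx1, hy1 = home.bounds
    tx0, ty0, tx1, ty1 = tunnel.bounds
    tunnel_mid_y = (ty0 + ty1) / 2
    tunnel_home_end = np.array([tx0 + 2.0, tunnel_mid_y])
    tunnel_social_end = np.array([tx1 - 2.0, tunnel_mid_y])

    pos = _interior_point(home, rng)
    baseline_end_f = int(round(cfg.baseline_s * fps))
    test_end_f = cfg.n_frames

    def maybe_jumps(f0: int, f1: int) -> None:
        dur_min = (f1 - f0) / fps / 60.0
        for _ in range(rng.poisson(_JUMP_RATE_PER_MIN * dur_min)):
            tl.point("Jump", int(rng.integers(f0, f1)))

    # --- baseline: solo exploration of the home chamber -------------------
    while tl.f < baseline_end_f:
        state = rng.choice(
            ["idle", "locomote", "groom", "nonsocial_freeze"],
            p=[0.35, 0.40, 0.15, 0.10],
        )
        if state == "locomote":
            target = (
                _wall_point(home, rng)
                if rng.random() < 0.5
                else _interior_point(home, rng)
            )
            n = min(_move_frames(pos, target, _SPEED["locomote"], fps),
                    baseline_end_f - tl.f)
            f0, f1 = tl.add("locomote", n, np.array([pos, target]))
            pos = target
        else:
            dur = rng.exponential({"idle": 4.0, "groom": 5.0, "nonsocial_freeze": 3.0}[state])
            n = min(tl.frames(dur), baseline_end_f - tl.f)
            behavior = {"groom": "Groom", "nonsocial_freeze": "Non-social Freeze"}.get(state)
            f0, f1 = tl.add(state, n, pos, heading=rng.uniform(-math.pi, math.pi),
                            behavior=behavior)
        maybe_jumps(f0, f1)

    # --- test phase A: tunnel hesitancy loop ------------------------------
    entered = False
    while tl.f < test_end_f and not entered:
        # explore home briefly, then walk to the tunnel mouth
        dwell = min(tl.frames(rng.uniform(1.5, 5.0)), test_end_f - tl.f)
        tl.add("idle", dwell, pos, heading=rng.uniform(-math.pi, math.pi))
        if tl.f >= test_end_f:
            break
        n = min(_move_frames(pos, tunnel_home_end, _SPEED["locomote"], fps),
                test_end_f - tl.f)
        tl.add("locomote", n, np.array([pos, tunnel_home_end]))
        pos = tunnel_home_end
        if tl.f >= test_end_f:
            break
        # shelter in the tunnel
        dur = max(0.5, rng.exponential(params.shelter_mean_s))
        n = min(tl.frames(dur), test_end_f - tl.f)
        tl.add("tunnel_shelter", n, pos, heading=0.0, behavior="Tunnel Shelter")
        if tl.f >= test_end_f:
            break
        if rng.random() < params.p_reverse:
            back = _interior_point(home, rng)
            n = min(_move_frames(pos, back, _SPEED["tunnel_reverse"], fps),
                    test_end_f - tl.f)
            tl.add("tunnel_reverse", n, np.array([pos, back]),
                   behavior="Reverse in Tunnel")
            pos = back
        else:
            target = _interior_point(social, rng)
            n = min(_move_frames(pos, target, _SPEED["cross"], fps), test_end_f - tl.f)
            tl.add("locomote", n, np.array([pos, tunnel_social_end, target]))
            pos = target
            entered = True

    # --- test phase B: dyadic interaction ---------------------------------
    weights = {
        "idle": 3.0,
        "locomote": 3.0,
        "groom": 0.5,
        "approach_sniff": params.initiation_weight,
        "aggress": params.aggression_weight,
        "home_visit": params.home_visit_weight,
    }
    names = list(weights)
    pvec = np.array([weights[k] for k in names])
    pvec = pvec / pvec.sum()
    sniff_scale = 60.0 / max(params.conspecific_sniff_rate_per_min, 1e-9)

    def consp_at(frame: int) -> np.ndarray:
        c = consp_centers[min(frame, len(consp_centers) - 1)]
        if np.any(np.isnan(c)):
            return np.array(social.centroid.coords[0])
        return c

    while tl.f < test_end_f and entered:
        state = names[int(rng.choice(len(names), p=pvec))]
        if state in ("idle", "locomote"):
            planned = rng.exponential(4.0) if state == "idle" else rng.uniform(1.5, 4.0)
            if state == "locomote":
                target = _interior_point(social, rng)
                n_planned = min(
                    _move_frames(pos, target, _SPEED["locomote"], fps),
                    test_end_f - tl.f,
                )
            else:
                target = pos
                n_planned = min(tl.frames(planned), test_end_f - tl.f)
            # a conspecific sniff may interrupt an unengaged segment
            t_sniff = rng.exponential(sniff_scale)
            f_sniff = max(1, int(round(t_sniff * fps)))
            if f_sniff < n_planned:
                n = f_sniff
                if state == "locomote":
                    cut, _ = _polyline(np.array([pos, target]), n_planned)
                    waypts = np.array([pos, cut[n - 1]])
                    tl.add("locomote", n, waypts)
                    pos = cut[n - 1]
                else:
                    tl.add("idle", n, pos, heading=rng.uniform(-math.pi, math.pi))
                sniff_f = tl.f
                tl.point("Conspecific Sniff", sniff_f, actor=CONSPECIFIC)
                u = rng.random()
                if u < params.p_freeze_given_sniff:
                    dur = rng.uniform(1.5, 4.0)
                    n = min(tl.frames(dur), test_end_f - tl.f)
                    if n > 0:
                        head = consp_at(sniff_f) - pos
                        tl.add(
                            "social_freeze", n, pos,
                            heading=math.atan2(head[1], head[0]),
                            behavior="Social Freeze",
                        )
                elif u < params.p_freeze_given_sniff + params.p_react_given_sniff:
                    tl.point("Social Reactivity", min(tl.f + 3, test_end_f - 1))
                    dart = _interior_point(social, rng)
                    n = min(_move_frames(pos, dart, 20.0, fps), test_end_f - tl.f)
                    if n > 0:
                        tl.add("locomote", n, np.array([pos, dart]))
                        pos = dart
            else:
                if state == "locomote":
                    tl.add("locomote", n_planned, np.array([pos, target]))
                    pos = target
                else:
                    tl.add("idle", n_planned, pos, heading=rng.uniform(-math.pi, math.pi))
        elif state == "groom":
            n = min(tl.frames(rng.exponential(4.0)), test_end_f - tl.f)
            tl.add("groom", n, pos, heading=rng.uniform(-math.pi, math.pi),
                   behavior="Groom")
        elif state == "approach_sniff":
            target_c = consp_at(tl.f + int(0.5 * fps))
            gap = np.hypot(*(target_c - pos))
            side = target_c + rng.normal(0, 0.5, 2)
            stop = target_c + (pos - target_c) / max(gap, 1e-6) * 2.5
            n = min(_move_frames(pos, stop, _SPEED["approach"], fps), test_end_f - tl.f)
            f0, _ = tl.add("approach", n, np.array([pos, stop]))
            if gap > 8.0:  # closed the gap from more than one body length
                tl.point("Social Initiation", f0)
            pos = stop
            if tl.f < test_end_f:
                subtype = rng.choice(
                    [b for b, _ in _SNIFF_SUBTYPE_P],
                    p=[p for _, p in _SNIFF_SUBTYPE_P],
                )
                n = min(tl.frames(rng.uniform(1.5, 4.0)), test_end_f - tl.f)
                head = side - pos
                tl.add("sniff", n, pos, heading=math.atan2(head[1], head[0]),
                       posture_state="sniff", behavior=str(subtype))
        elif state == "aggress":
            target_c = consp_at(tl.f)
            stop = target_c + rng.normal(0, 1.0, 2)
            n = min(_move_frames(pos, stop, _SPEED["approach"], fps), test_end_f - tl.f)
            tl.add("approach", n, np.array([pos, stop]))
            pos = stop
            if tl.f < test_end_f:
                n = min(tl.frames(rng.uniform(1.0, 3.0)), test_end_f - tl.f)
                head = target_c - pos
                tl.add("aggress", n, pos, heading=math.atan2(head[1], head[0]),
                       behavior="Aggression")
        elif state == "home_visit":
            n = min(
                _move_frames(pos, tunnel_social_end, _SPEED["cross"], fps),
                test_end_f - tl.f,
            )
            tl.add("locomote", n, np.array([pos, tunnel_social_end]))
            pos = tunnel_social_end
            if tl.f < test_end_f and rng.random() < 0.4:
                n = min(tl.frames(max(0.5, rng.exponential(1.5))), test_end_f - tl.f)
                tl.add("tunnel_shelter", n, pos, heading=math.pi,
                       behavior="Tunnel Shelter")
            if tl.f < test_end_f:
                back = _interior_point(home, rng)
                n = min(_move_frames(pos, back, _SPEED["cross"], fps), test_end_f - tl.f)
                tl.add("locomote", n, np.array([pos, tunnel_home_end, back]))
                pos = back
            f_home0 = tl.f
            if tl.f < test_end_f:
                n = min(tl.frames(rng.exponential(6.0)), test_end_f - tl.f)
                tl.add("idle", n, pos, heading=rng.uniform(-math.pi, math.pi))
                maybe_jumps(f_home0, tl.f)
            if tl.f < test_end_f:
                n = min(
                    _move_frames(pos, tunnel_home_end, _SPEED["cross"], fps),
                    test_end_f - tl.f,
                )
                tl.add("locomote", n, np.array([pos, tunnel_home_end]))
                pos = tunnel_home_end
            if tl.f < test_end_f:
                target = _interior_point(social, rng)
                n = min(_move_frames(pos, target, _SPEED["cross"], fps),
                        test_end_f - tl.f)
                tl.add("locomote", n, np.array([pos, tunnel_social_end, target]))
                pos = target

    # a subject that never committed to the social chamber idles out phase A
    if tl.f < test_end_f:
        tl.add("idle", test_end_f - tl.f, pos, heading=0.0)
    return tl


def _build_conspecific(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> _Timeline:
    """Independent wander of the stimulus mouse inside the social chamber
    during the test phase only."""
    tl = _Timeline(cfg.fps)
    tl.f = int(round(cfg.baseline_s * cfg.fps))  # absent during baseline
    social = cfg.arena.social_chamber
    pos = _interior_point(social, rng)
    end_f = cfg.n_frames
    while tl.f < end_f:
        if rng.random() < 0.55:
            target = _interior_point(social, rng)
            n = min(_move_frames(pos, target, 6.0, cfg.fps), end_f - tl.f)
            tl.add("locomote", n, np.array([pos, target]))
            pos = target
        else:
            n = min(tl.frames(rng.exponential(3.0)), end_f - tl.f)
            tl.add("idle", n, pos, heading=rng.uniform(-math.pi, math.pi))
    return tl


# ---------------------------------------------------------------------------
# ground-truth summaries
# ---------------------------------------------------------------------------


def _truth_summaries(
    events: list[EthogramEvent],
    zone_true: np.ndarray,
    cfg: GeneratorConfig,
) -> pd.Series:
    """Recompute the behavior-score row directly from the generated events
    and the noise-free zone sequence (simple independent arithmetic)."""
    b0, b1 = cfg.baseline_span
    t0, t1 = cfg.test_span
    fps = cfg.fps

    def dur(name: str, span: tuple[float, float]) -> float:
        return sum(
            max(0.0, min(e.offset, span[1]) - max(e.onset, span[0]))
            for e in events
            if e.behavior == name and e.event_type == STATE
        )

    def cnt(name: str, span: tuple[float, float]) -> int:
        return sum(
            1
            for e in events
            if e.behavior == name and e.event_type == POINT
            and span[0] <= e.onset < span[1]
        )

    test = (t0, t1)
    times = np.arange(len(zone_true)) / fps
    in_test = (times >= t0) & (times < t1)
    social_hits = np.flatnonzero(in_test & (zone_true == "social"))
    entry_t = times[social_hits[0]] if social_hits.size else float("nan")
    cutoff = t1 if math.isnan(entry_t) else float(entry_t)
    first_shelter = sum(
        max(0.0, min(e.offset, cutoff) - max(e.onset, t0))
        for e in events
        if e.behavior == "Tunnel Shelter"
    )
    sniff_parts = [dur(b, test) for b, _ in _SNIFF_SUBTYPE_P]
    consp = cnt("Conspecific Sniff", test)
    react = cnt("Social Reactivity", test)
    reverse_events = [
        e for e in events
        if e.behavior == "Reverse in Tunnel"
        and (max(0.0, min(e.offset, t1) - max(e.onset, t0)) > 0 or t0 <= e.onset < t1)
    ]
    row = {
        "face_sniff_s": sniff_parts[0],
        "body_sniff_s": sniff_parts[1],
        "anogenital_sniff_s": sniff_parts[2],
        "tail_sniff_s": sniff_parts[3],
        "all_sniff_s": sum(sniff_parts),
        "conspecific_sniff_bouts": consp,
        "social_reactivity_pct": (100.0 * react / consp) if consp else float("nan"),
        "social_freeze_s": dur("Social Freeze", test),
        "first_tunnel_shelter_s": first_shelter,
        "reverse_count": len(reverse_events),
        "reverse_s": sum(
            max(0.0, min(e.offset, t1) - max(e.onset, t0)) for e in reverse_events
        ),
        "latency_to_social_s": float("nan") if math.isnan(entry_t) else entry_t - t0,
        "prosocial_initiations": cnt("Social Initiation", test),
        "chamber_preference_pct": 100.0
        * np.count_nonzero(in_test & (zone_true == "social"))
        / fps
        / (t1 - t0),
        "groom_s": dur("Groom", test),
        "nonsocial_freeze_baseline_s": dur("Non-social Freeze", (b0, b1)),
        "nonsocial_freeze_test_s": dur("Non-social Freeze", test),
        "aggression_s": dur("Aggression", test),
        "jump_count": cnt("Jump", test),
        "thigmotaxis_pct": float("nan"),  # jitter-dependent; no noise-free truth
    }
    return pd.Series(row)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_session(
    config: GeneratorConfig,
    condition: str,
    seed: int | np.random.SeedSequence,
    subject_id: str | None = None,
    sex: str = "F",
) -> tuple[SessionRecord, GroundTruth]:
    """Simulate one session under *condition*; identical inputs give
    bit-identical output."""
    if condition not in config.conditions:
        raise KeyError(
            f"unknown condition {condition!r}; configured: "
            f"{sorted(config.conditions)}"
        )
    params = config.conditions[condition]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n_frames = config.n_frames

    consp_tl = _build_conspecific(config, rng)
    consp_coords, consp_valid, consp_centers = _render_animal(
        consp_tl.plans, n_frames, rng, config.jitter_sd_cm
    )
    exp_tl = _build_experimental(config, params, rng, consp_centers)
    exp_coords, exp_valid, exp_centers = _render_animal(
        exp_tl.plans, n_frames, rng, config.jitter_sd_cm
    )

    coords = np.stack([exp_coords, consp_coords], axis=1)
    valid = np.stack([exp_valid, consp_valid], axis=1)
    coords[~valid] = np.nan
    traj = KeypointTrajectory(coords, valid, config.fps)

    if config.missing_rate > 0 or config.swap_rate > 0:
        traj, swap_windows = inject_artifacts(
            traj, config.missing_rate, config.swap_rate, rng
        )
    else:
        swap_windows = []

    events = sorted(exp_tl.events + consp_tl.events, key=lambda e: e.onset)
    log = EventLog(events)

    state_exp = np.full(n_frames, "idle", dtype="U16")
    for p in exp_tl.plans:
        state_exp[p.f0 : p.f1] = p.state
    state_consp = np.full(n_frames, "absent", dtype="U16")
    for p in consp_tl.plans:
        state_consp[p.f0 : p.f1] = p.state

    zone_true = np.full(n_frames, "unknown", dtype="U7")
    ok = ~np.isnan(exp_centers[:, 0])
    pts = shapely.points(exp_centers[ok, 0], exp_centers[ok, 1])
    z = np.full(int(ok.sum()), "unknown", dtype="U7")
    for name, poly in (
        ("home", config.arena.home_chamber),
        ("tunnel", config.arena.tunnel),
        ("social", config.arena.social_chamber),
    ):
        hit = shapely.covers(poly, pts)
        z[(z == "unknown") & hit] = name
    zone_true[ok] = z

    truth = GroundTruth(
        condition=condition,
        state_exp=state_exp,
        state_consp=state_consp,
        zone_true=zone_true,
        summaries=_truth_summaries(events, zone_true, config),
        segments_exp=[(p.f0, p.f1, p.state) for p in exp_tl.plans],
        swap_windows=swap_windows,
    )
    record = SessionRecord(
        subject_id=subject_id or f"{condition}-{ss.entropy}",
        sex=sex,
        condition=condition,
        trajectory=traj,
        events=log,
        baseline_span=config.baseline_span,
        test_span=config.test_span,
    )
    return record, truth


def simulate_cohort(
    config: GeneratorConfig,
    n_per_group: int,
    conditions: tuple[str, str] = ("GH", "SI"),
    seed: int = 0,
) -> list[tuple[SessionRecord, GroundTruth]]:
    """Simulate a balanced two-condition cohort.  Per-session seeds are
    spawned from the master seed, so sessions are independent yet the whole
    cohort is reproducible from one integer."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(2 * n_per_group)
    out = []
    k = 0
    for condition in conditions:
        for i in range(n_per_group):
            rec, truth = simulate_session(
                config, condition, children[k],
                subject_id=f"{condition}-{i:02d}",
                sex="F",
            )
            out.append((rec, truth))
            k += 1
    return out


def inject_artifacts(
    traj: KeypointTrajectory,
    missing_rate: float,
    swap_rate: float,
    seed: int | np.random.Generator,
) -> tuple[KeypointTrajectory, list[tuple[int, int]]]:
    """Degrade a trajectory with random missing points and identity swaps.

    ``missing_rate`` is the per-(frame, animal, node) probability of marking
    a cell invalid; ``swap_rate`` is the per-frame probability of *starting*
    a contiguous window (0.5–3 s) in which the two animals' coordinates are
    exchanged.  Returns the degraded copy and the list of swap windows
    (half-open frame ranges), so tests can undo them: re-swapping the
    reported windows restores the original.
    """
    if not 0 <= missing_rate <= 1 or not 0 <= swap_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = traj.copy()
    swap_windows: list[tuple[int, int]] = []
    if swap_rate > 0:
        starts = np.flatnonzero(rng.random(out.n_frames) < swap_rate)
        last_end = -1
        for f0 in starts:
            if f0 < last_end:
                continue
            f1 = min(out.n_frames, f0 + int(rng.uniform(0.5, 3.0) * out.fps))
            out.coords[f0:f1] = out.coords[f0:f1, ::-1]
            out.valid[f0:f1] = out.valid[f0:f1, ::-1]
            swap_windows.append((int(f0), int(f1)))
            last_end = f1
    if missing_rate > 0:
        drop = rng.random(out.valid.shape) < missing_rate
        out.valid[drop] = False
        out.coords[~out.valid] = np.nan
    return out, swap_windows
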