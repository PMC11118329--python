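"""Session data model and file I/O.

The package operates on three kinds of session data:

* :class:`KeypointTrajectory` — per-frame planar coordinates for 8 skeleton
  nodes on each of the two animals (experimental subject and conspecific
  stimulus), with a validity mask marking untracked points;
* :class:`EventLog` — manually or synthetically scored behavioral events,
  either start-stop (state) or instantaneous (point), with labels drawn from
  the closed vocabulary in :mod:`sausi.vocabulary`;
* :class:`ArenaGeometry` / :class:`SessionConfig` — the two-chamber + tunnel
  arena and the session phase structure (a 3-minute solo baseline followed
  by a 10-minute dyadic test by default).

Conventions: origin at the arena's top-left corner, x rightward, y downward,
units cm after scaling; times in seconds from session start; state events are
closed intervals ``[onset, offset]``.

Keypoint files come in two dialects: a minimal HDF5 layout (datasets
``tracks`` of shape ``animal x frame x node x 2`` plus ``node_names`` and
``track_names``) and a wide CSV (``frame`` column followed by
``animal.node.x`` / ``animal.node.y`` columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .vocabulary import (
    CONSPECIFIC,
    EXPERIMENTAL,
    POINT,
    STATE,
    VocabularyError,
    allowed_actor,
    canonical_behavior,
    event_type_of,
)

#: fixed 8-node skeleton, front to back
NODE_NAMES: tuple[str, ...] = (
    "nose",
    "head",
    "left_ear",
    "right_ear",
    "trunk",
    "left_hip",
    "right_hip",
    "tail_base",
)

ANIMAL_NAMES: tuple[str, str] = (EXPERIMENTAL, CONSPECIFIC)

N_NODES = len(NODE_NAMES)
N_ANIMALS = 2


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class SchemaError(ValueError):
    """A parsed file violates the fixed 2-animal / 8-node schema."""


class RecordError(ValueError):
    """A single event record is internally inconsistent."""


class GeometryError(ValueError):
    """Arena or phase configuration is geometrically invalid."""


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class KeypointTrajectory:
    """Per-frame keypoint coordinates for the two animals.

    Parameters
    ----------
    coords
        Array of shape ``(frames, 2, 8, 2)``: frame x animal x node x (x, y),
        in cm.  Entries where ``valid`` is False may be NaN.
    valid
        Boolean array of shape ``(frames, 2, 8)``; False marks missing or
        untracked points.
    fps
        Acquisition rate in frames per second.
    """

    coords: np.ndarray
    valid: np.ndarray
    fps: float
    node_names: tuple[str, ...] = NODE_NAMES
    animal_names: tuple[str, str] = ANIMAL_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.coords.ndim != 4 or self.coords.shape[1:] != (N_ANIMALS, N_NODES, 2):
            raise SchemaError(
                f"coords must have shape (frames, {N_ANIMALS}, {N_NODES}, 2), "
                f"got {self.coords.shape}"
            )
        if self.valid.shape != self.coords.shape[:3]:
            raise SchemaError(
                f"valid mask shape {self.valid.shape} does not match coords"
            )
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        bad = self.valid & ~np.isfinite(self.coords).all(axis=3)
        if bad.any():
            raise ValueError("coords must be finite wherever valid is true")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from session start."""
        return np.arange(self.n_frames) / self.fps

    def node_index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def animal_index(self, name: str) -> int:
        try:
            return self.animal_names.index(name)
        except ValueError:
            raise KeyError(f"unknown animal {name!r}") from None

    def node(self, animal: str, node: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(xy, valid)`` series for one node of one animal."""
        a, n = self.animal_index(animal), self.node_index(node)
        return self.coords[:, a, n, :], self.valid[:, a, n]

    def copy(self) -> "KeypointTrajectory":
        return KeypointTrajectory(
            self.coords.copy(), self.valid.copy(), self.fps,
            self.node_names, self.animal_names,
        )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EthogramEvent:
    """One scored behavioral event.

    State events span ``[onset, offset]`` seconds; point events are
    instantaneous and carry ``offset=None``.
    """

    behavior: str
    actor: str
    event_type: str
    onset: float
    offset: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", canonical_behavior(self.behavior))
        if self.actor not in (EXPERIMENTAL, CONSPECIFIC):
            raise RecordError(f"unknown actor {self.actor!r}")
        expected_type = event_type_of(self.behavior)
        if self.event_type != expected_type:
            raise RecordError(
                f"{self.behavior!r} is a {expected_type} behavior, "
                f"not {self.event_type!r}"
            )
        if self.actor != allowed_actor(self.behavior):
            raise RecordError(
                f"{self.behavior!r} must be scored for actor "
                f"{allowed_actor(self.behavior)!r}"
            )
        if self.event_type == STATE:
            if self.offset is None:
                raise RecordError(f"state event {self.behavior!r} needs an offset")
            if self.offset < self.onset:
                raise RecordError(
                    f"offset {self.offset} precedes onset {self.onset} "
                    f"for {self.behavior!r}"
                )
        elif self.offset is not None:
            raise RecordError(f"point event {self.behavior!r} cannot carry an offset")

    @property
    def duration(self) -> float:
        return 0.0 if self.offset is None else self.offset - self.onset


class EventLog:
    """An onset-sorted sequence of :class:`EthogramEvent`."""

    def __init__(self, events: Iterable[EthogramEvent] = ()) -> None:
        self.events: list[EthogramEvent] = sorted(events, key=lambda e: e.onset)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[EthogramEvent]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventLog) and self.events == other.events

    def for_behavior(self, behavior: str) -> list[EthogramEvent]:
        behavior = canonical_behavior(behavior)
        return [e for e in self.events if e.behavior == behavior]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "behavior": e.behavior,
                    "actor": e.actor,
                    "event_type": e.event_type,
                    "onset": e.onset,
                    "offset": np.nan if e.offset is None else e.offset,
                }
                for e in self.events
            ],
            columns=["behavior", "actor", "event_type", "onset", "offset"],
        )


# ---------------------------------------------------------------------------
# arena and session configuration
# ---------------------------------------------------------------------------


def _rect(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


@dataclass
class ArenaGeometry:
    """Two chambers joined by a tunnel, in cm.

    Default dimensions: a 30x30 home chamber and a 30x30 social chamber
    joined by a 15x6 tunnel centred on the shared wall.
    """

    home_chamber: Polygon = field(default_factory=lambda: _rect(0, 0, 30, 30))
    tunnel: Polygon = field(default_factory=lambda: _rect(30, 12, 45, 18))
    social_chamber: Polygon = field(default_factory=lambda: _rect(45, 0, 75, 30))
    px_to_cm: float = 1.0

    def __post_init__(self) -> None:
        if not self.px_to_cm > 0:
            raise GeometryError("px_to_cm scale must be positive")
        zones = [self.home_chamber, self.tunnel, self.social_chamber]
        names = ["home_chamber", "tunnel", "social_chamber"]
        for i in range(3):
            for j in range(i + 1, 3):
                inter = zones[i].intersection(zones[j])
                if inter.area > 1e-9:
                    raise GeometryError(
                        f"chamber polygons {names[i]} and {names[j]} overlap"
                    )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs, ys = [], []
        for poly in (self.home_chamber, self.tunnel, self.social_chamber):
            x0, y0, x1, y1 = poly.bounds
            xs += [x0, x1]
            ys += [y0, y1]
        return min(xs), min(ys), max(xs), max(ys)

    @property
    def diagonal(self) -> float:
        x0, y0, x1, y1 = self.bounds
        return float(np.hypot(x1 - x0, y1 - y0))

    def zone_of(self, x: float, y: float) -> str:
        p = Point(x, y)
        for name, poly in (
            ("home", self.home_chamber),
            ("tunnel", self.tunnel),
            ("social", self.social_chamber),
        ):
            if poly.covers(p):
                return name
        return "unknown"


@dataclass
class SessionConfig:
    """Phase structure and analysis parameters for one session."""

    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    baseline_span: tuple[float, float] = (0.0, 180.0)
    test_span: tuple[float, float] = (180.0, 780.0)
    fps: float = 30.0
    max_gap_s: float = 0.5
    thigmotaxis_margin_cm: float = 2.0

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_span
        t0, t1 = self.test_span
        if not (b0 <= b1 <= t0 <= t1):
            raise GeometryError(
                f"baseline {self.baseline_span} must end before test "
                f"{self.test_span} begins"
            )
        for name in ("fps", "max_gap_s", "thigmotaxis_margin_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SessionRecord:
    """One subject's full session: metadata, trajectory, and event log."""

    subject_id: str
    sex: str
    condition: str
    trajectory: KeypointTrajectory
    events: EventLog
    baseline_span: tuple[float, float] = (0.0, 180.0)
    test_span: tuple[float, float] = (180.0, 780.0)

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be non-empty")
        if not self.baseline_span[1] <= self.test_span[0]:
            raise GeometryError("baseline must end before test begins")


# ---------------------------------------------------------------------------
# keypoint file I/O
# ---------------------------------------------------------------------------


def _csv_columns() -> list[str]:
    cols = ["frame"]
    for animal in ANIMAL_NAMES:
        for node in NODE_NAMES:
            cols += [f"{animal}.{node}.x", f"{animal}.{node}.y"]
    return cols


def read_keypoints(
    path: str | Path, schema: str = "wide-csv", *, fps: float = 30.0,
    px_to_cm: float = 1.0,
) -> KeypointTrajectory:
    """Read a keypoint trajectory file.

    Parameters
    ----------
    schema
        ``'hdf5-tracks'`` or ``'wide-csv'`` (see module docstring).
    px_to_cm
        Scale applied to raw coordinates; outputs are always cm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "hdf5-tracks":
        coords, valid = _read_hdf5(path)
    elif schema == "wide-csv":
        coords, valid = _read_wide_csv(path)
    else:
        raise ValueError(f"unknown keypoint schema {schema!r}")
    coords = coords * px_to_cm
    coords[~valid] = np.nan
    return KeypointTrajectory(coords, valid, fps)


def _read_hdf5(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        for name in ("tracks", "node_names", "track_names"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        tracks = np.asarray(f["tracks"], dtype=float)
        node_names = [_as_str(v) for v in f["node_names"][()]]
        track_names = [_as_str(v) for v in f["track_names"][()]]
    if tracks.ndim != 4 or tracks.shape[3] != 2:
        raise FormatError(
            f"{path}: tracks must be (animal, frame, node, 2), got {tracks.shape}"
        )
    if tracks.shape[0] != N_ANIMALS or len(track_names) != N_ANIMALS:
        raise SchemaError(
            f"{path}: expected {N_ANIMALS} tracks, found {tracks.shape[0]}"
        )
    if tracks.shape[2] != N_NODES or node_names != list(NODE_NAMES):
        raise SchemaError(
            f"{path}: expected nodes {list(NODE_NAMES)}, found {node_names}"
        )
    coords = np.transpose(tracks, (1, 0, 2, 3))  # frame x animal x node x 2
    valid = np.all(np.isfinite(coords), axis=3)
    return coords, valid


def _as_str(v: object) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_wide_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    expected = _csv_columns()
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise SchemaError(
            f"{path}: wide-csv columns mismatch (missing {missing}, extra {extra})"
        )
    frames = df["frame"].to_numpy()
    if len(frames) and not np.all(np.diff(frames) > 0):
        bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 1
        raise FormatError(f"{path}: frame index not strictly increasing at row {bad}")
    n = len(df)
    coords = np.empty((n, N_ANIMALS, N_NODES, 2))
    for a, animal in enumerate(ANIMAL_NAMES):
        for k, node in enumerate(NODE_NAMES):
            coords[:, a, k, 0] = df[f"{animal}.{node}.x"]
            coords[:, a, k, 1] = df[f"{animal}.{node}.y"]
    valid = np.all(np.isfinite(coords), axis=3)
    return coords, valid


def write_keypoints(
    traj: KeypointTrajectory, path: str | Path, schema: str = "wide-csv"
) -> Path:
    """Write a trajectory in one of the supported dialects (inverse of read)."""
    path = Path(path)
    coords = traj.coords.copy()
    coords[~traj.valid] = np.nan
    if schema == "hdf5-tracks":
        with h5py.File(path, "w") as f:
            f.create_dataset("tracks", data=np.transpose(coords, (1, 0, 2, 3)))
            f.create_dataset(
                "node_names", data=np.array(traj.node_names, dtype="S")
            )
            f.create_dataset(
                "track_names", data=np.array(traj.animal_names, dtype="S")
            )
    elif schema == "wide-csv":
        data: dict[str, np.ndarray] = {"frame": np.arange(traj.n_frames)}
        for a, animal in enumerate(ANIMAL_NAMES):
            for k, node in enumerate(NODE_NAMES):
                data[f"{animal}.{node}.x"] = coords[:, a, k, 0]
                data[f"{animal}.{node}.y"] = coords[:, a, k, 1]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown keypoint schema {schema!r}")
    return path


# ---------------------------------------------------------------------------
# event log I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["behavior", "actor", "event_type", "onset", "offset"]


def read_events(path: str | Path) -> EventLog:
    """Read a scored event CSV (columns behavior, actor, event_type, onset, offset)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        offset = None if pd.isna(row.offset) else float(row.offset)
        try:
            events.append(
                EthogramEvent(
                    behavior=str(row.behavior),
                    actor=str(row.actor).strip().lower(),
                    event_type=str(row.event_type).strip().lower(),
                    onset=float(row.onset),
                    offset=offset,
                )
            )
        except VocabularyError:
            raise
        except RecordError as exc:
            raise RecordError(f"{path} row {i + 2}: {exc}") from exc
    return EventLog(events)


def write_events(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    # %.17g guarantees exact float round trip through the CSV
    log.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------


def load_session_config(path: str | Path | None = None) -> SessionConfig:
    """Load a session config JSON; absent keys fall back to defaults
    (180 s baseline, 600 s test, 30 fps, default arena)."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = json.load(fh)
    return session_config_from_dict(doc)


def session_config_from_dict(doc: dict) -> SessionConfig:
    arena_doc = doc.get("arena", {})
    arena_kwargs: dict = {}
    for key in ("home_chamber", "tunnel", "social_chamber"):
        if key in arena_doc:
            arena_kwargs[key] = Polygon(arena_doc[key])
    if "px_to_cm" in arena_doc:
        arena_kwargs["px_to_cm"] = float(arena_doc["px_to_cm"])
    arena = ArenaGeometry(**arena_kwargs)

    kwargs: dict = {"arena": arena}
    if "baseline_span" in doc:
        kwargs["baseline_span"] = tuple(float(v) for v in doc["baseline_span"])
    if "test_span" in doc:
        kwargs["test_span"] = tuple(float(v) for v in doc["test_span"])
    for key in ("fps", "max_gap_s", "thigmotaxis_margin_cm"):
        if key in doc:
            kwargs[key] = float(doc[key])
    return SessionConfig(**kwargs)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def write_scores(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a behavior-score table (one subject per row, indexed by subject_id)."""
    if table.empty:
        raise ValueError("refusing to write an empty score table")
    if table.index.duplicated().any():
        dupes = sorted(set(table.index[table.index.duplicated()]))
        raise ValueError(f"duplicate subject ids: {dupes}")
    path = Path(path)
    table.to_csv(path, index_label="subject_id", float_format="%.10g")
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
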