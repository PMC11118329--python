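"""Unsupervised behavior mapping from keypoint trajectories.

Pipeline: gap interpolation of the validity-masked tracks -> posture angle
features (interior joint angles per animal plus the inter-animal relative
heading) -> z-normalization over pooled frames -> PCA to the smallest
dimensionality capturing a target variance fraction -> a 2-D manifold
embedding (UMAP by contract; a deterministic PCA fallback is available as a
pluggable backend) -> Gaussian kernel density on a regular grid -> watershed
of the negated density into regions by steepest-ascent basin assignment ->
per-subject region occupancy -> per-region group statistics and logistic
decoding of group membership from occupancy fractions.

The watershed is implemented directly as hill climbing on the density grid:
every cell points to its highest 8-neighbor (ties broken toward the lowest
flat index), chains are collapsed by pointer jumping, and each local maximum
seeds one region.  Regions are numbered 1..K by descending peak density.
Regions smaller than a minimum area are merged into the neighbor with the
densest shared boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .aversion import DecoderReport, HousingDecoder, TTestResult, group_ttest
from .ethogram import SCORE_COLUMNS  # noqa: F401  (re-exported convenience)
from .io_sessions import KeypointTrajectory, SessionRecord

# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def interpolate_tracks(
    traj: KeypointTrajectory, max_gap_s: float = 0.5
) -> KeypointTrajectory:
    """Linearly interpolate invalid gaps up to ``max_gap_s`` per node.

    Gaps longer than the limit, and gaps at the start or end of a track
    (no anchor on one side), stay invalid and are excluded downstream.
    """
    out = traj.copy()
    max_gap = int(round(max_gap_s * traj.fps))
    n = traj.n_frames
    for a in range(traj.coords.shape[1]):
        for k in range(traj.coords.shape[2]):
            v = out.valid[:, a, k]
            if v.all() or not v.any():
                continue
            invalid = ~v
            # run-length encode invalid stretches
            edges = np.flatnonzero(np.diff(invalid.astype(np.int8)))
            starts = np.concatenate(([0], edges + 1))
            ends = np.concatenate((edges + 1, [n]))
            for s, e in zip(starts, ends):
                if not invalid[s]:
                    continue
                if s == 0 or e == n or (e - s) > max_gap:
                    continue
                left, right = s - 1, e
                frac = (np.arange(s, e) - left) / (right - left)
                for ax in range(2):
                    lo = out.coords[left, a, k, ax]
                    hi = out.coords[right, a, k, ax]
                    out.coords[s:e, a, k, ax] = lo + frac * (hi - lo)
                out.valid[s:e, a, k] = True
    return out


# ---------------------------------------------------------------------------
# angle features
# ---------------------------------------------------------------------------

#: (a, b, c): interior angle at b — head flexion, ear spread, spine bend, hip spread
DEFAULT_TRIPLETS: tuple[tuple[str, str, str], ...] = (
    ("nose", "head", "trunk"),
    ("left_ear", "head", "right_ear"),
    ("head", "trunk", "tail_base"),
    ("left_hip", "trunk", "right_hip"),
)


@dataclass
class FeatureMatrix:
    """Per-frame posture features with provenance back to source frames."""

    values: np.ndarray          # (n_frames_kept, n_features)
    feature_names: list[str]
    frame_index: np.ndarray     # indices into the source trajectory
    flagged: np.ndarray         # True where the source frame had any missing
                                # or interpolated coordinate
    normalized: bool = False


def _interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 1e-12) & (nv > 1e-12)
    cosang = np.full(len(u), np.nan)
    dots = np.einsum("ij,ij->i", u, v)
    cosang[ok] = np.clip(dots[ok] / (nu[ok] * nv[ok]), -1.0, 1.0)
    return np.arccos(cosang)


def angle_features(
    traj: KeypointTrajectory,
    triplets: tuple[tuple[str, str, str], ...] = DEFAULT_TRIPLETS,
    include_derivatives: bool = False,
    frames: np.ndarray | None = None,
    flagged: np.ndarray | None = None,
) -> FeatureMatrix:
    """Joint-angle features for both animals plus the inter-animal relative
    heading (cosine of the heading difference, rotation invariant).

    Frames with any required node invalid, or with a degenerate (coincident
    point) triplet, are dropped.  ``frames`` restricts/subsamples the frames
    considered; ``flagged`` carries per-frame source-quality flags through.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames)
    sub = traj.coords[frames]          # (n, 2, 8, 2)
    sub_valid = traj.valid[frames]
    names: list[str] = []
    cols: list[np.ndarray] = []
    needed = np.zeros(sub_valid.shape[1:], dtype=bool)  # (2, 8)
    for a, animal in enumerate(traj.animal_names):
        for (pa, pb, pc) in triplets:
            ia, ib, ic = (traj.node_index(x) for x in (pa, pb, pc))
            needed[a, [ia, ib, ic]] = True
            ang = _interior_angle(
                sub[:, a, ia], sub[:, a, ib], sub[:, a, ic]
            )
            cols.append(ang)
            names.append(f"{animal}:{pa}-{pb}-{pc}")
        ih, it = traj.node_index("head"), traj.node_index("trunk")
        needed[a, [ih, it]] = True
    h = []
    for a in range(2):
        d = sub[:, a, traj.node_index("head")] - sub[:, a, traj.node_index("trunk")]
        h.append(np.arctan2(d[:, 1], d[:, 0]))
    cols.append(np.cos(h[0] - h[1]))
    names.append("relative_heading_cos")

    X = np.column_stack(cols)
    # keep frames where every needed node of both animals is valid and no
    # angle came out degenerate
    needed_ok = np.ones(len(frames), dtype=bool)
    for a in range(2):
        needed_ok &= sub_valid[:, a, :][:, needed[a]].all(axis=1)
    keep = needed_ok & np.all(np.isfinite(X), axis=1)
    if include_derivatives:
        dX = np.vstack([np.zeros((1, X.shape[1])), np.diff(X, axis=0)])
        X = np.column_stack([X, dX])
        names = names + [f"d_{n}" for n in names[: dX.shape[1]]]
    if flagged is None:
        flagged = np.zeros(traj.n_frames, dtype=bool)
    return FeatureMatrix(
        values=X[keep],
        feature_names=names,
        frame_index=frames[keep],
        flagged=np.asarray(flagged)[frames][keep],
    )


def normalize_features(F: FeatureMatrix) -> FeatureMatrix:
    """Z-normalize each feature over the pooled frames (constant features
    are centred and left at zero spread)."""
    mu = F.values.mean(axis=0)
    sd = F.values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return FeatureMatrix(
        values=(F.values - mu) / sd,
        feature_names=list(F.feature_names),
        frame_index=F.frame_index.copy(),
        flagged=F.flagged.copy(),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# dimensionality reduction and embedding
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    projections: np.ndarray
    loadings: np.ndarray            # (k, n_features)
    explained_variance_ratio: np.ndarray
    n_components: int


def pca_reduce(X: np.ndarray, variance_fraction: float = 0.95) -> PCAResult:
    """Project onto the smallest number of principal components capturing at
    least ``variance_fraction`` of total variance.  Deterministic sign
    convention: each component's largest-magnitude loading is positive."""
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, proj.shape[1])
    load = pca.components_[:k].copy()
    proj = proj[:, :k].copy()
    for i in range(k):
        j = int(np.argmax(np.abs(load[i])))
        if load[i, j] < 0:
            load[i] *= -1
            proj[:, i] *= -1
    return PCAResult(
        projections=proj,
        loadings=load,
        explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
        n_components=k,
    )


def embed_2d(
    X: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    backend: str = "umap",
) -> np.ndarray:
    """Embed into 2-D.  Contract, not algorithmic identity: identical inputs
    and seed give identical output, and well-separated clusters stay
    separated.  Backends: ``'umap'`` (default) or ``'pca'`` (deterministic
    linear fallback)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} frames, got {X.shape[0]}"
        )
    if backend == "pca":
        k = min(2, X.shape[1])
        res = pca_reduce(X, 1.0)
        out = np.zeros((X.shape[0], 2))
        out[:, :k] = res.projections[:, :k]
        return out
    if backend != "umap":
        raise ValueError(f"unknown embedding backend {backend!r}")
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


# ---------------------------------------------------------------------------
# density watershed
# ---------------------------------------------------------------------------


@dataclass
class BehaviorMap:
    """2-D embedded frames, their density grid, and watershed regions."""

    embedding: np.ndarray           # (n, 2)
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray             # (H, W), integrates to ~1
    labels: np.ndarray              # (H, W) region ids 1..K
    region_ids: list[int]
    peak_density: dict[int, float]
    point_regions: np.ndarray       # (n,) region id per embedded frame
    bandwidth: float = float("nan")
    excluded_regions: set[int] = field(default_factory=set)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


_NEIGHBOR_SHIFTS = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
]


def steepest_ascent_basins(density: np.ndarray) -> np.ndarray:
    """Assign every grid cell to the local maximum reached by repeatedly
    stepping to the highest-density cell among its 8 neighbors and itself
    (ties toward the lowest flat index).  Returns an array of flat indices
    of each cell's basin peak."""
    d = np.asarray(density, dtype=float)
    H, W = d.shape
    pad = np.full((H + 2, W + 2), -np.inf)
    pad[1:-1, 1:-1] = d
    best = d.copy()
    flat = np.arange(H * W).reshape(H, W)
    parent = flat.copy()
    for di, dj in _NEIGHBOR_SHIFTS:
        nb = pad[1 + di : 1 + di + H, 1 + dj : 1 + dj + W]
        nb_idx = flat + di * W + dj
        better = (nb > best) | ((nb == best) & (nb > -np.inf) & (nb_idx < parent))
        best = np.where(better, nb, best)
        parent = np.where(better, nb_idx, parent)
    parent = parent.ravel()
    # pointer jumping to the fixed point
    while True:
        nxt = parent[parent]
        if np.array_equal(nxt, parent):
            break
        parent = nxt
    return parent.reshape(H, W)


def _order_regions(peaks: np.ndarray, density: np.ndarray) -> tuple[np.ndarray, list[int], dict[int, float]]:
    """Relabel basin-peak indices to region ids 1..K by descending peak
    density (ties by flat index for stability)."""
    d = density.ravel()
    roots = np.unique(peaks)
    order = sorted(roots, key=lambda r: (-d[r], r))
    lut = {root: i + 1 for i, root in enumerate(order)}
    labels = np.vectorize(lut.get)(peaks)
    region_ids = [lut[r] for r in order]
    peak_density = {lut[r]: float(d[r]) for r in order}
    return labels.astype(int), region_ids, peak_density


def _merge_small_regions(
    labels: np.ndarray, density: np.ndarray, min_cells: int
) -> np.ndarray:
    """Merge regions below the area threshold into the neighboring region
    with the densest shared boundary."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = [i for i, c in zip(ids, counts) if c < min_cells]
        if not small or len(ids) == 1:
            return labels
        # merge the smallest first
        target = small[int(np.argmin([counts[list(ids).index(i)] for i in small]))]
        mask = labels == target
        best_nb, best_d = None, -np.inf
        H, W = labels.shape
        for di, dj in _NEIGHBOR_SHIFTS:
            src = mask[
                max(0, -di) : H - max(0, di), max(0, -dj) : W - max(0, dj)
            ]
            nb_lab = labels[
                max(0, di) : H - max(0, -di), max(0, dj) : W - max(0, -dj)
            ]
            nb_den = density[
                max(0, di) : H - max(0, -di), max(0, dj) : W - max(0, -dj)
            ]
            sel = src & (nb_lab != target)
            if sel.any():
                k = int(np.argmax(np.where(sel, nb_den, -np.inf)))
                dmax = np.where(sel, nb_den, -np.inf).ravel()[k]
                if dmax > best_d:
                    best_d = dmax
                    best_nb = int(nb_lab.ravel()[k])
        if best_nb is None:  # isolated region; leave it
            return labels
        labels[mask] = best_nb
    return labels


def segment_density(
    embedding: np.ndarray,
    grid_size: int = 200,
    bandwidth: float | None = None,
    bandwidth_factor: float = 1.0,
    min_region_area_frac: float = 0.001,
    pad_frac: float = 0.05,
) -> BehaviorMap:
    """Kernel-density estimate of the embedding on a regular grid, then
    watershed into regions by steepest-ascent basins.

    The density is a binned Gaussian KDE: points are histogrammed on a
    ``grid_size x grid_size`` grid over the padded bounding box and smoothed
    with a Gaussian kernel.  Default bandwidth is Scott's rule times
    ``bandwidth_factor``.  Regions covering fewer cells than
    ``min_region_area_frac`` of the occupied cells are merged into their
    densest-boundary neighbor; surviving regions are numbered 1..K by
    descending peak density.
    """
    pts = np.asarray(embedding, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("embedding must be a non-empty (n, 2) array")
    n = len(pts)
    if bandwidth is None:
        sd = pts.std(axis=0, ddof=1 if n > 1 else 0).mean()
        sd = sd if sd > 0 else 1.0
        bandwidth = float(sd * n ** (-1.0 / 6.0) * bandwidth_factor)  # Scott, 2-D
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    y0, y1 = pts[:, 1].min(), pts[:, 1].max()
    span_x = (x1 - x0) or 1.0
    span_y = (y1 - y0) or 1.0
    x_edges = np.linspace(x0 - pad_frac * span_x, x1 + pad_frac * span_x, grid_size + 1)
    y_edges = np.linspace(y0 - pad_frac * span_y, y1 + pad_frac * span_y, grid_size + 1)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    density = gaussian_filter(hist, sigma=(bandwidth / dx, bandwidth / dy), mode="constant")
    total = density.sum() * dx * dy
    if total > 0:
        density = density / total

    peaks = steepest_ascent_basins(density)
    labels, region_ids, peak_density = _order_regions(peaks, density)
    occupied = int(np.count_nonzero(hist))
    min_cells = max(1, int(np.ceil(min_region_area_frac * occupied)))
    labels = _merge_small_regions(labels, density, min_cells)
    # renumber surviving regions by descending peak density
    surviving = np.unique(labels)
    order = sorted(surviving, key=lambda r: -peak_density[r])
    lut = {old: i + 1 for i, old in enumerate(order)}
    labels = np.vectorize(lut.get)(labels).astype(int)
    region_ids = [lut[o] for o in order]
    peak_density = {lut[o]: peak_density[o] for o in order}

    ix = np.clip(np.searchsorted(x_edges, pts[:, 0], side="right") - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(y_edges, pts[:, 1], side="right") - 1, 0, grid_size - 1)
    point_regions = labels[ix, iy]
    return BehaviorMap(
        embedding=pts,
        x_edges=x_edges,
        y_edges=y_edges,
        density=density,
        labels=labels,
        region_ids=sorted(region_ids),
        peak_density=peak_density,
        point_regions=point_regions,
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# occupancy and decoding
# ---------------------------------------------------------------------------


def occupancy_profiles(bmap: BehaviorMap, subjects: np.ndarray) -> pd.DataFrame:
    """Per-subject fraction of frames in each region.

    ``subjects`` assigns each embedded frame to a subject id.  Fractions sum
    to 1 per subject (every frame falls in exactly one region).
    """
    subjects = np.asarray(subjects)
    if len(subjects) != len(bmap.point_regions):
        raise ValueError("subjects must align with embedded frames")
    df = pd.DataFrame({"subject": subjects, "region": bmap.point_regions})
    counts = df.groupby(["subject", "region"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=bmap.region_ids, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"subjects with zero frames: {bad}")
    frac = counts.div(totals, axis=0)
    frac.columns = [f"region_{r}" for r in frac.columns]
    frac.index.name = "subject_id"
    return frac


def default_excluded_regions(
    bmap: BehaviorMap, flagged: np.ndarray, threshold: float = 0.5
) -> set[int]:
    """Regions whose member frames are mostly (> threshold) flagged as
    missing-or-interpolated in the source tracks — the outlier/missing-point
    analogue of map regions dominated by tracking failures."""
    flagged = np.asarray(flagged, dtype=bool)
    out: set[int] = set()
    for r in bmap.region_ids:
        sel = bmap.point_regions == r
        if sel.any() and flagged[sel].mean() > threshold:
            out.add(r)
    return out


def region_stats_and_decode(
    profiles: pd.DataFrame,
    labels,
    excluded_regions: set[int] | frozenset[int] = frozenset(),
    l2_strength: float = 1.0,
) -> tuple[pd.DataFrame, DecoderReport]:
    """Per-region two-tailed t-tests plus logistic decoding of group
    membership from the non-excluded occupancy fractions."""
    excluded_cols = {f"region_{r}" for r in excluded_regions}
    keep = [c for c in profiles.columns if c not in excluded_cols]
    if not keep:
        raise ValueError("all regions excluded")
    labels = np.asarray(labels)
    rows = []
    for col in keep:
        res: TTestResult = group_ttest(profiles[col].to_numpy(), labels)
        rows.append({"region": col, "t": res.t, "p": res.p, "df": res.df,
                     "degenerate": res.degenerate})
    stats = pd.DataFrame(rows).set_index("region")
    dec = HousingDecoder(l2_strength=l2_strength)
    dec.fit(profiles[keep], labels)
    return stats, dec.report()


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class CohortMap:
    """End-to-end mapping result for a cohort."""

    map: BehaviorMap
    occupancy: pd.DataFrame          # subjects x regions
    subject_labels: pd.Series        # condition per subject
    pca: PCAResult
    excluded_regions: set[int]
    frame_subjects: np.ndarray


class BehaviorMapper(BaseEstimator):
    """Scikit-learn style wrapper for the feature -> map stage.

    ``fit(X)`` takes an already-normalized feature matrix and produces the
    fitted attributes ``pca_``, ``embedding_`` and ``map_``.
    """

    def __init__(
        self,
        variance_fraction: float = 0.95,
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        grid_size: int = 200,
        bandwidth_factor: float = 1.0,
        min_region_area_frac: float = 0.001,
        backend: str = "umap",
        random_state: int = 0,
    ):
        self.variance_fraction = variance_fraction
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.grid_size = grid_size
        self.bandwidth_factor = bandwidth_factor
        self.min_region_area_frac = min_region_area_frac
        self.backend = backend
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "BehaviorMapper":
        self.pca_ = pca_reduce(X, self.variance_fraction)
        self.embedding_ = embed_2d(
            self.pca_.projections,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            seed=self.random_state,
            backend=self.backend,
        )
        self.map_ = segment_density(
            self.embedding_,
            grid_size=self.grid_size,
            bandwidth_factor=self.bandwidth_factor,
            min_region_area_frac=self.min_region_area_frac,
        )
        return self


def map_cohort(
    sessions: list[SessionRecord],
    stride: int = 60,
    max_gap_s: float = 0.5,
    mapper: BehaviorMapper | None = None,
    seed: int = 0,
) -> CohortMap:
    """Run the full unsupervised pipeline on a cohort.

    Test-phase frames are subsampled at ``stride`` (default one frame per
    two seconds at 30 fps) before pooling, which preserves occupancy
    fractions in expectation while keeping the embedding tractable.
    """
    if mapper is None:
        mapper = BehaviorMapper(random_state=seed)
    feats = []
    subj = []
    labels = {}
    for rec in sessions:
        src_flag = ~rec.trajectory.valid.all(axis=(1, 2))
        traj = interpolate_tracks(rec.trajectory, max_gap_s)
        fps = traj.fps
        f0 = int(round(rec.test_span[0] * fps))
        f1 = min(int(round(rec.test_span[1] * fps)), traj.n_frames)
        frames = np.arange(f0, f1, stride)
        F = angle_features(traj, frames=frames, flagged=src_flag)
        feats.append(F)
        subj.append(np.repeat(rec.subject_id, len(F.frame_index)))
        labels[rec.subject_id] = rec.condition
    pooled = FeatureMatrix(
        values=np.vstack([F.values for F in feats]),
        feature_names=feats[0].feature_names,
        frame_index=np.concatenate([F.frame_index for F in feats]),
        flagged=np.concatenate([F.flagged for F in feats]),
    )
    pooled = normalize_features(pooled)
    frame_subjects = np.concatenate(subj)
    mapper.fit(pooled.values)
    bmap = mapper.map_
    occupancy = occupancy_profiles(bmap, frame_subjects)
    excluded = default_excluded_regions(bmap, pooled.flagged)
    bmap.excluded_regions = excluded
    subject_labels = pd.Series(
        {s: labels[s] for s in occupancy.index}, name="condition"
    )
    return CohortMap(
        map=bmap,
        occupancy=occupancy,
        subject_labels=subject_labels,
        pca=mapper.pca_,
        excluded_regions=excluded,
        frame_subjects=frame_subjects,
    )
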