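"""Interpolation, angle features, PCA, embedding, watershed, occupancy."""

import numpy as np
import pandas as pd
import pytest

from sausi.behavior_map import (
    BehaviorMapper,
    angle_features,
    default_excluded_regions,
    embed_2d,
    interpolate_tracks,
    normalize_features,
    occupancy_profiles,
    pca_reduce,
    region_stats_and_decode,
    segment_density,
    steepest_ascent_basins,
)
from sausi.io_sessions import KeypointTrajectory

from conftest import make_trajectory
from oracles import brute_force_basins


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def _traj_with_gap(gap_frames, n=20):
    coords = np.zeros((n, 2, 8, 2))
    coords[..., 0] = np.arange(n)[:, None, None]
    valid = np.ones((n, 2, 8), bool)
    s = 5
    valid[s : s + gap_frames, 0, 0] = False
    coords[~valid] = np.nan
    return KeypointTrajectory(coords, valid, fps=30.0), s


def test_interpolation_linear_fill():
    """3-frame gap between x=4 and x=8 fills with 5, 6, 7."""
    traj, s = _traj_with_gap(3)
    traj.coords[s - 1, 0, 0] = [4.0, 0.0]
    traj.coords[s + 3, 0, 0] = [8.0, 0.0]
    out = interpolate_tracks(traj, max_gap_s=0.5)
    assert out.valid[s : s + 3, 0, 0].all()
    np.testing.assert_allclose(out.coords[s : s + 3, 0, 0, 0], [5.0, 6.0, 7.0])


def test_interpolation_respects_max_gap():
    traj, s = _traj_with_gap(10)
    out = interpolate_tracks(traj, max_gap_s=0.1)  # 3 frames at 30 fps
    assert not out.valid[s : s + 10, 0, 0].any()


def test_interpolation_identity_on_valid():
    traj = make_trajectory(n_frames=15, seed=3)
    out = interpolate_tracks(traj)
    np.testing.assert_array_equal(out.coords, traj.coords)
    np.testing.assert_array_equal(out.valid, traj.valid)


# ---------------------------------------------------------------------------
# angle features
# ---------------------------------------------------------------------------


def _posed_traj(nose, head, trunk, n=5):
    coords = np.tile(np.array([5.0, 5.0]), (n, 2, 8, 1))
    coords[:, :, 0] = nose
    coords[:, :, 1] = head
    coords[:, :, 4] = trunk
    coords[:, :, 7] = trunk + np.array([-1.0, 0.0])  # tail behind trunk
    return KeypointTrajectory(coords, np.ones((n, 2, 8), bool), 30.0)


def test_angle_collinear_is_pi():
    traj = _posed_traj([2.0, 0.0], [1.0, 0.0], [0.0, 0.0])
    F = angle_features(traj)
    j = F.feature_names.index("experimental:nose-head-trunk")
    np.testing.assert_allclose(F.values[:, j], np.pi, atol=1e-9)


def test_angle_right_angle():
    traj = _posed_traj([1.0, 1.0], [1.0, 0.0], [0.0, 0.0])
    F = angle_features(traj)
    j = F.feature_names.index("experimental:nose-head-trunk")
    np.testing.assert_allclose(F.values[:, j], np.pi / 2, atol=1e-9)


def test_angle_rotation_translation_invariance(gh_session):
    """Global rigid motion of all coordinates leaves angle features
    unchanged to 1e-9."""
    rec, _ = gh_session
    traj = interpolate_tracks(rec.trajectory)
    frames = np.arange(1000, 2200, 10)
    F0 = angle_features(traj, frames=frames)
    rng = np.random.default_rng(0)
    for _ in range(3):
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = rng.uniform(-50, 50, 2)
        rot = traj.copy()
        rot.coords = traj.coords @ R.T + shift
        F1 = angle_features(rot, frames=frames)
        np.testing.assert_allclose(F1.values, F0.values, atol=1e-9)


def test_degenerate_triplet_dropped():
    traj = _posed_traj([1.0, 0.0], [1.0, 0.0], [0.0, 0.0])  # nose == head
    F = angle_features(traj)
    assert len(F.frame_index) == 0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_line_needs_one_component():
    rng = np.random.default_rng(0)
    t = rng.normal(size=400)
    X = np.column_stack([t, 2 * t]) + rng.normal(0, 1e-6, (400, 2))
    res = pca_reduce(X, 0.95)
    assert res.n_components == 1
    assert res.explained_variance_ratio[0] > 0.999


def test_pca_matches_analytic_eigendecomposition():
    """Explained variances equal eigenvalues of the sample covariance."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(300, 3)) @ np.array(
        [[2.0, 0.3, 0.0], [0.0, 1.0, 0.1], [0.0, 0.0, 0.5]]
    )
    res = pca_reduce(X, 1.0)
    cov = np.cov(X, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    explained = res.explained_variance_ratio * eig.sum()
    np.testing.assert_allclose(explained, eig, rtol=1e-8)


def test_pca_isotropic_spreads_variance():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10_000, 4))
    res = pca_reduce(X, 1.0)
    assert res.explained_variance_ratio.max() < 0.30


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 4))
    a = pca_reduce(X, 0.9)
    b = pca_reduce(X, 0.9)
    np.testing.assert_array_equal(a.projections, b.projections)
    for row in a.loadings:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_bad_fraction():
    with pytest.raises(ValueError):
        pca_reduce(np.zeros((5, 2)), 0.0)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def _two_clusters(n=500, sep=10.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, d))
    b = rng.normal(0, 1, (n, d))
    b[:, 0] += sep
    return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]


def test_embedding_preserves_separated_clusters():
    """>=95% of points keep a same-cluster embedded nearest neighbor."""
    X, labels = _two_clusters()
    E = embed_2d(X, seed=0)
    from scipy.spatial import cKDTree

    tree = cKDTree(E)
    _, nn = tree.query(E, k=2)
    purity = np.mean(labels[nn[:, 1]] == labels)
    assert purity >= 0.95


def test_embedding_deterministic_given_seed():
    X, _ = _two_clusters(n=150)
    np.testing.assert_array_equal(embed_2d(X, seed=3), embed_2d(X, seed=3))


def test_embedding_degenerate_duplicates():
    X = np.tile(np.array([[1.0, 2.0, 3.0]]), (60, 1))
    E = embed_2d(X, seed=0)
    assert np.all(np.isfinite(E))


def test_embedding_too_few_frames():
    with pytest.raises(ValueError, match="n_neighbors"):
        embed_2d(np.zeros((5, 3)), n_neighbors=15)


def test_pca_backend_fallback():
    X, labels = _two_clusters(n=100)
    E = embed_2d(X, backend="pca")
    assert E.shape == (200, 2)
    np.testing.assert_array_equal(E, embed_2d(X, backend="pca"))


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------


def test_single_gaussian_single_region():
    """A unimodal density yields exactly one watershed region (bandwidth
    chosen so the KDE itself is unimodal; at undersmoothed bandwidths the
    estimated density genuinely has extra modes)."""
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 1, (800, 2))
    bmap = segment_density(pts, grid_size=80, bandwidth=0.8)
    assert bmap.n_regions == 1


def test_two_separated_clusters_two_regions():
    rng = np.random.default_rng(1)
    pts = np.vstack([
        rng.normal(0, 1, (600, 2)),
        rng.normal(0, 1, (600, 2)) + [25.0, 0.0],
    ])
    bmap = segment_density(pts, grid_size=120, bandwidth=0.8)
    assert bmap.n_regions == 2
    # each cluster's points share one region
    left = bmap.point_regions[:600]
    right = bmap.point_regions[600:]
    assert len(set(left)) == 1 and len(set(right)) == 1
    assert left[0] != right[0]


def test_basin_assignment_matches_brute_force():
    """Pointer-jumping basins equal naive per-cell hill climbing on random
    grids (a 10-grid spot check; the 100-grid sweep runs in acceptance)."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        H, W = rng.integers(5, 40, 2)
        density = rng.random((H, W))
        np.testing.assert_array_equal(
            steepest_ascent_basins(density), brute_force_basins(density)
        )


def test_bad_bandwidth():
    with pytest.raises(ValueError):
        segment_density(np.zeros((10, 2)), bandwidth=-1.0)


def test_density_integrates_to_one():
    rng = np.random.default_rng(3)
    bmap = segment_density(rng.normal(0, 1, (500, 2)), grid_size=100)
    dx = bmap.x_edges[1] - bmap.x_edges[0]
    dy = bmap.y_edges[1] - bmap.y_edges[0]
    assert bmap.density.sum() * dx * dy == pytest.approx(1.0, abs=1e-6)
    assert (bmap.density >= 0).all()


# ---------------------------------------------------------------------------
# occupancy and decoding
# ---------------------------------------------------------------------------


def _planted_profiles(seed, n_per_group=18, n_regions=8, planted=3, factor=2.0):
    """Dirichlet occupancy profiles with one region's weight multiplied in
    the second group."""
    rng = np.random.default_rng(seed)
    alpha = np.full(n_regions, 5.0)
    gh = rng.dirichlet(alpha, n_per_group)
    alpha_si = alpha.copy()
    alpha_si[planted] *= factor
    si = rng.dirichlet(alpha_si, n_per_group)
    prof = pd.DataFrame(
        np.vstack([gh, si]),
        columns=[f"region_{i + 1}" for i in range(n_regions)],
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    labels = np.array(["GH"] * n_per_group + ["SI"] * n_per_group)
    return prof, labels, f"region_{planted + 1}"


def test_occupancy_single_region():
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 0.5, (200, 2))
    bmap = segment_density(pts, grid_size=60, bandwidth=0.6)
    prof = occupancy_profiles(bmap, np.repeat("s1", 200))
    assert prof.loc["s1"].sum() == pytest.approx(1.0)
    assert prof.loc["s1"].max() == pytest.approx(1.0)


def test_occupancy_sums_to_one_per_subject():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 2, (900, 2))
    subjects = np.repeat([f"s{i}" for i in range(9)], 100)
    bmap = segment_density(pts, grid_size=80)
    prof = occupancy_profiles(bmap, subjects)
    np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)


def test_planted_region_detected_by_ttest_and_decoder():
    prof, labels, planted = _planted_profiles(seed=0)
    stats, rep = region_stats_and_decode(prof, labels)
    assert stats.loc[planted, "p"] < 0.05
    assert rep.ranked_features().index[0] == planted


def test_excluding_planted_region_drops_accuracy():
    accs_full, accs_abl = [], []
    for seed in range(8):
        prof, labels, planted = _planted_profiles(seed=seed)
        _, full = region_stats_and_decode(prof, labels)
        _, ablated = region_stats_and_decode(
            prof, labels, excluded_regions={int(planted.split("_")[1])}
        )
        accs_full.append(full.training_accuracy)
        accs_abl.append(ablated.training_accuracy)
    assert np.mean(accs_abl) < np.mean(accs_full)


def test_all_regions_excluded_errors():
    prof, labels, _ = _planted_profiles(seed=1, n_regions=3, planted=0)
    with pytest.raises(ValueError, match="excluded"):
        region_stats_and_decode(prof, labels, excluded_regions={1, 2, 3})


def test_default_exclusion_flags_degraded_regions():
    """A region fed mostly by flagged (missing/interpolated) frames is
    excluded by default."""
    rng = np.random.default_rng(5)
    good = rng.normal(0, 1, (400, 2))
    bad = rng.normal(0, 1, (400, 2)) + [25.0, 0.0]
    pts = np.vstack([good, bad])
    flagged = np.r_[np.zeros(400, bool), rng.random(400) < 0.9]
    bmap = segment_density(pts, grid_size=100)
    excl = default_excluded_regions(bmap, flagged)
    bad_region = bmap.point_regions[600]
    assert bad_region in excl
    assert bmap.point_regions[0] not in excl
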