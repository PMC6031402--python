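"""Trajectory metrics, complex shape basis and crossing statistics,
each checked against an independent oracle."""

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from melanosim.analysis import (
    _mannwhitney_p,
    coefficient_spectrum,
    compare_sets,
    compute_metrics,
    count_crossings,
    expand_in_basis,
    extract_basis,
    reconstruct,
    spectrum_slope,
)
from melanosim.simulator import Trajectory


def _traj(points, cell_id=0, dt=5.0):
    return Trajectory(cell_id=cell_id, positions=np.asarray(points, dtype=float), dt=dt)


class TestMetrics:
    def test_straight_line(self):
        m = compute_metrics(_traj([(0, 0), (1, 0), (2, 0)], dt=5.0))
        assert m.total_distance == pytest.approx(2)
        assert m.euclidean_distance == pytest.approx(2)
        assert m.directionality == pytest.approx(1)
        assert m.mean_speed == pytest.approx(2 / 10)

    def test_out_and_back(self):
        m = compute_metrics(_traj([(0, 0), (1, 0), (0, 0)]))
        assert m.euclidean_distance == 0
        assert m.directionality == 0

    def test_stationary_is_undefined(self):
        m = compute_metrics(_traj([(1, 1), (1, 1)]))
        assert np.isnan(m.directionality)

    def test_against_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(36, 2))
        m = compute_metrics(_traj(pts, dt=5.0))
        total = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(35)
        )
        assert m.total_distance == pytest.approx(total)
        assert m.euclidean_distance == pytest.approx(float(np.hypot(*(pts[-1] - pts[0]))))
        assert m.directionality == pytest.approx(m.euclidean_distance / total)
        assert m.mean_speed == pytest.approx(total / (35 * 5.0))
        assert m.euclidean_distance <= m.total_distance
        assert 0 <= m.directionality <= 1


def _random_set(rng, n=12, t=10, scale=1.0):
    steps = rng.normal(0, scale, size=(n, t - 1, 2))
    pos = np.concatenate(
        [rng.uniform(0, 10, (n, 1, 2)), np.cumsum(steps, axis=1) + rng.uniform(0, 10, (n, 1, 2))],
        axis=1,
    )
    return [_traj(pos[i], cell_id=i) for i in range(n)]


class TestBasis:
    def test_identical_straight_lines_are_rank_one(self):
        trajs = [
            _traj([(x0, y0), (x0 + 1, y0 + 1), (x0 + 2, y0 + 2)], cell_id=i)
            for i, (x0, y0) in enumerate([(0, 0), (3, 1), (5, 5), (7, 2)])
        ]
        basis = extract_basis(trajs)
        assert basis.mean_moduli[0] > 0
        assert np.all(basis.mean_moduli[1:] < 1e-10)
        recon = reconstruct(basis, basis.coefficients, k=1)
        z = np.stack([t.positions[:, 0] + 1j * t.positions[:, 1] for t in trajs])
        z -= z[:, :1]
        assert np.allclose(recon, z, atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        trajs = _random_set(rng)
        basis = extract_basis(trajs)
        z = np.stack([t.positions[:, 0] + 1j * t.positions[:, 1] for t in trajs])
        z -= z[:, :1]
        assert np.abs(reconstruct(basis, basis.coefficients) - z).max() < 1e-8

    def test_orthonormality(self, rng):
        basis = extract_basis(_random_set(rng))
        g = basis.basis_functions @ basis.basis_functions.conj().T
        assert np.allclose(g, np.eye(len(g)), atol=1e-10)

    def test_mean_moduli_nonincreasing(self, rng):
        basis = extract_basis(_random_set(rng, n=30))
        assert np.all(np.diff(basis.mean_moduli) <= 1e-12)

    def test_subspace_recovery(self, rng):
        """Sets built from 3 orthonormal complex sequences are recovered with
        principal angles below 1e-2 rad despite small noise."""
        t = 12
        raw = rng.normal(size=(t, 3)) + 1j * rng.normal(size=(t, 3))
        raw[0] = 0  # start-anchored world: first sample is the origin
        q, _ = np.linalg.qr(raw)
        coeff = rng.normal(size=(40, 3)) + 1j * rng.normal(size=(40, 3))
        z = coeff @ q.T * 10
        z += (rng.normal(size=z.shape) + 1j * rng.normal(size=z.shape)) * 1e-4
        trajs = [
            _traj(np.column_stack([zz.real, zz.imag]), cell_id=i)
            for i, zz in enumerate(z)
        ]
        basis = extract_basis(trajs, n_components=3)
        # principal angles between recovered and generating 3-dim subspaces
        m = basis.basis_functions.conj() @ q
        sv = np.linalg.svd(m, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.all(angles < 1e-2)

    def test_rotation_equivariance(self, rng):
        trajs = _random_set(rng)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = [
            _traj(t.positions @ rot.T, cell_id=t.cell_id, dt=t.dt) for t in trajs
        ]
        basis = extract_basis(trajs)
        c0 = expand_in_basis(trajs, basis)
        c1 = expand_in_basis(rotated, basis)
        assert np.allclose(c1, np.exp(1j * theta) * c0, atol=1e-10)
        b1 = extract_basis(rotated)
        assert np.allclose(b1.mean_moduli, basis.mean_moduli, atol=1e-10)

    def test_expand_defining_set_matches(self, rng):
        trajs = _random_set(rng)
        basis = extract_basis(trajs)
        assert np.allclose(expand_in_basis(trajs, basis), basis.coefficients, atol=1e-10)

    def test_orthogonal_trajectory_has_zero_coefficients(self, rng):
        t = 10
        raw = rng.normal(size=(t, 5)) + 1j * rng.normal(size=(t, 5))
        raw[0] = 0
        q, _ = np.linalg.qr(raw)
        span, extra = q[:, :3], q[:, 4]
        coeff = rng.normal(size=(8, 3)) + 1j * rng.normal(size=(8, 3))
        z = coeff @ span.T
        trajs = [
            _traj(np.column_stack([zz.real, zz.imag]), cell_id=i) for i, zz in enumerate(z)
        ]
        basis = extract_basis(trajs, n_components=3)
        orth = _traj(np.column_stack([extra.real, extra.imag]))
        assert np.abs(expand_in_basis([orth], basis)).max() < 1e-8

    def test_spectrum_matches_brute_force(self, rng):
        trajs = _random_set(rng)
        basis = extract_basis(trajs)
        z = np.stack([t.positions[:, 0] + 1j * t.positions[:, 1] for t in trajs])
        z -= z[:, :1]
        # np.vdot conjugates its first argument, i.e. <b_j, z>
        brute = np.mean(
            [[abs(np.vdot(b, zz)) for b in basis.basis_functions] for zz in z],
            axis=0,
        )
        assert np.allclose(coefficient_spectrum(basis), brute, atol=1e-10)

    def test_basis_optimality_vs_random_bases(self, rng):
        """Rank-k SVD reconstruction beats random orthonormal bases."""
        trajs = _random_set(rng, n=15)
        basis = extract_basis(trajs)
        z = np.stack([t.positions[:, 0] + 1j * t.positions[:, 1] for t in trajs])
        z -= z[:, :1]
        k = 3
        err_svd = np.linalg.norm(reconstruct(basis, basis.coefficients, k) - z)
        for _ in range(5):
            raw = rng.normal(size=(z.shape[1], k)) + 1j * rng.normal(size=(z.shape[1], k))
            q, _ = np.linalg.qr(raw)
            err = np.linalg.norm((z @ q.conj()) @ q.T - z)
            assert err_svd <= err + 1e-9

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            extract_basis([_traj([(0, 0), (1, 1)]), _traj([(0, 0), (1, 1), (2, 2)])])


def _oracle_crossings(trajectories, window_steps, tol=1e-6):
    """Exhaustive O(n^2 T^2) shapely-based crossing count (independent route)."""
    total = 0
    for ta, tb in itertools.combinations(trajectories, 2):
        pts = []
        pa, pb = ta.positions, tb.positions
        for i in range(len(pa) - 1):
            for j in range(len(pb) - 1):
                if abs(i - j) > window_steps:
                    continue
                sa = (
                    LineString([pa[i], pa[i + 1]])
                    if np.linalg.norm(pa[i + 1] - pa[i]) > 1e-9
                    else Point(pa[i])
                )
                sb = (
                    LineString([pb[j], pb[j + 1]])
                    if np.linalg.norm(pb[j + 1] - pb[j]) > 1e-9
                    else Point(pb[j])
                )
                inter = sa.intersection(sb)
                if inter.is_empty:
                    continue
                c = inter.centroid
                pts.append((c.x, c.y))
        if not pts:
            continue
        pts = np.asarray(pts)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(tol, output_type="ndarray")
        parent = np.arange(len(pts))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        total += len({find(i) for i in range(len(pts))})
    return total


class TestCrossings:
    def test_x_crossing(self):
        a = _traj([(0, 0), (2, 2)], cell_id=0)
        b = _traj([(0, 2), (2, 0)], cell_id=1)
        assert count_crossings([a, b], window_steps=1) == 1

    def test_parallel_no_crossing(self):
        a = _traj([(0, 0), (2, 0)], cell_id=0)
        b = _traj([(0, 1), (2, 1)], cell_id=1)
        assert count_crossings([a, b], window_steps=1) == 0

    def test_window_excludes_late_crossings(self):
        a = _traj([(0, 0), (1, 0), (1.01, 0), (1.02, 0)], cell_id=0)
        b = _traj([(0.5, -1), (0.5, -0.9), (0.5, -0.8), (0.5, 1)], cell_id=1)
        # b crosses a's first segment only with its last segment (|0-3| > 1)
        assert count_crossings([a, b], window_steps=1) == 0
        assert count_crossings([a, b], window_steps=3) == 1

    def test_touching_at_shared_node_counts_once(self):
        a = _traj([(0, 0), (1, 0), (2, 0)], cell_id=0)
        b = _traj([(1, 1), (1, 0), (1, -1)], cell_id=1)
        assert count_crossings([a, b], window_steps=2) == 1

    def test_symmetric_in_pair_order(self, rng):
        trajs = _random_set(rng, n=6, t=8)
        assert count_crossings(trajs, 3) == count_crossings(trajs[::-1], 3)

    def test_invariant_under_rigid_motion(self, rng):
        trajs = _random_set(rng, n=8, t=8)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = [
            _traj(t.positions @ rot.T + np.array([5.0, -3.0]), cell_id=t.cell_id)
            for t in trajs
        ]
        assert count_crossings(trajs, 3) == count_crossings(moved, 3)

    @pytest.mark.parametrize("window", [1, 3, 10])
    def test_matches_exhaustive_oracle(self, rng, window):
        trajs = _random_set(rng, n=20, t=10, scale=2.0)
        assert count_crossings(trajs, window) == _oracle_crossings(trajs, window)

    def test_matches_oracle_with_stationary_segments(self, rng):
        trajs = _random_set(rng, n=10, t=8)
        for tr in trajs[:4]:  # freeze a few cells part of the time
            tr.positions[2:5] = tr.positions[2]
        assert count_crossings(trajs, 4) == _oracle_crossings(trajs, 4)


def _mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), n1):
        r = sum(sorted_rank + 1 for sorted_rank in comb)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    mu = us.mean()
    extreme = np.sum(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return extreme / len(us)


class TestCompare:
    def test_mannwhitney_matches_enumeration(self):
        x = np.array([1.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 9.0])
        assert _mannwhitney_p(x, y) == pytest.approx(_mw_enumeration_oracle(x, y))
        x2 = np.array([1.0, 2.0, 3.0])
        y2 = np.array([10.0, 11.0, 12.0])
        assert _mannwhitney_p(x2, y2) == pytest.approx(_mw_enumeration_oracle(x2, y2))

    def test_degenerate_ties_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert _mannwhitney_p(np.ones(5), np.ones(5)) == 1.0

    def test_set_vs_itself(self, rng):
        trajs = _random_set(rng, n=20)
        report = compare_sets(trajs, trajs)
        for metric in report["metrics"].values():
            assert metric["p_value"] > 0.99
        assert report["crossings"]["set_a"] == report["crossings"]["set_b"]

    def test_disjoint_supports_give_tiny_p(self, rng):
        slow = [_traj(np.cumsum(rng.normal(0, 0.1, (10, 2)), 0), cell_id=i) for i in range(20)]
        fast = [
            _traj(np.cumsum(rng.normal(0, 5.0, (10, 2)), 0), cell_id=i) for i in range(20)
        ]
        report = compare_sets(slow, fast)
        assert report["metrics"]["mean_speed"]["p_value"] < 1e-6

    def test_spectrum_slope_orders_random_vs_smooth(self, rng):
        smooth = [
            _traj([(i * 1.0, i * 0.5 + k) for i in range(10)], cell_id=k) for k in range(15)
        ]
        noisy = _random_set(rng, n=15, t=10, scale=1.0)
        b_smooth = extract_basis(smooth)
        b_noisy = extract_basis(noisy)
        s_smooth = spectrum_slope(coefficient_spectrum(b_smooth))
        s_noisy = spectrum_slope(coefficient_spectrum(b_noisy))
        assert s_noisy > s_smooth  # noise decays more slowly
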