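"""Trajectory-set analysis: migration metrics, complex shape basis, crossings.

Three complementary views of a set of cell trajectories:

* classical migration metrics — total path length, Euclidean start-end
  distance, directionality (their ratio) and mean speed;
* a shape decomposition: writing each start-anchored path as the complex
  sequence z_t = x_t + i*y_t and extracting an orthonormal basis of "basic
  trajectories" by complex SVD (a PCA-like, least-squares-optimal
  construction); multiplying a basic trajectory by a complex coefficient
  rotates and dilates it, so the per-index mean coefficient moduli form a
  spectrum whose decay rate separates smooth paths (fast decay) from
  random-walk-like paths (slow decay);
* a trajectory-crossing count: the number of distinct points where two
  different cells' path segments intersect within a bounded simultaneity
  window (~1 h), the statistic that reveals the repulsion-trail memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulator import Trajectory

__all__ = [
    "TrajectoryMetrics",
    "TrajectoryBasis",
    "compute_metrics",
    "extract_basis",
    "expand_in_basis",
    "coefficient_spectrum",
    "spectrum_slope",
    "reconstruct",
    "count_crossings",
    "compare_sets",
]


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Classical per-cell migration statistics."""

    total_distance: float       # um
    euclidean_distance: float   # um
    directionality: float       # euclidean / total, in [0, 1]; nan if total = 0
    mean_speed: float           # um / min


def compute_metrics(traj: Trajectory) -> TrajectoryMetrics:
    """Total/Euclidean distance, directionality and mean speed of one path."""
    p = traj.positions
    if len(p) < 2:
        raise ValueError("trajectory needs at least 2 positions")
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = float(seg.sum())
    euclid = float(np.linalg.norm(p[-1] - p[0]))
    direc = euclid / total if total > 0 else float("nan")
    elapsed = traj.dt * (len(p) - 1)
    return TrajectoryMetrics(
        total_distance=total,
        euclidean_distance=euclid,
        directionality=direc,
        mean_speed=total / elapsed,
    )


# ---------------------------------------------------------------------------
# complex shape basis
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryBasis:
    """Orthonormal complex basic trajectories and the expansion of the set
    they were extracted from.

    ``basis_functions[j]`` is a length-T complex sequence; each centered
    trajectory equals ``sum_j coefficients[i, j] * basis_functions[j]``.
    Components are ordered by decreasing mean coefficient modulus.
    """

    basis_functions: np.ndarray  # (k, T) complex, orthonormal rows
    coefficients: np.ndarray     # (n_traj, k) complex
    mean_moduli: np.ndarray      # (k,)


def _as_complex(trajectories: list[Trajectory]) -> np.ndarray:
    """Stack start-anchored paths as rows of a complex matrix."""
    lengths = {len(t.positions) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError("all trajectories must have the same length; resample first")
    z = np.stack(
        [(t.positions[:, 0] + 1j * t.positions[:, 1]) for t in trajectories]
    )
    return z - z[:, :1]


def extract_basis(trajectories: list[Trajectory], n_components: int | None = None) -> TrajectoryBasis:
    """Least-squares-optimal orthonormal basis of a trajectory set (complex SVD)."""
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    z = _as_complex(trajectories)
    t_len = z.shape[1]
    if n_components is None:
        n_components = min(z.shape)
    if n_components > t_len:
        raise ValueError("n_components cannot exceed the trajectory length")
    _, s, vh = np.linalg.svd(z, full_matrices=True)
    vh = vh[:n_components]
    coeff = z @ vh.conj().T
    moduli = np.abs(coeff).mean(axis=0)
    order = np.argsort(-moduli, kind="stable")
    return TrajectoryBasis(
        basis_functions=vh[order],
        coefficients=coeff[:, order],
        mean_moduli=moduli[order],
    )


def expand_in_basis(trajectories: list[Trajectory], basis: TrajectoryBasis) -> np.ndarray:
    """Complex projections of centered trajectories onto a (possibly foreign)
    orthonormal basis, e.g. simulated paths in an experimental basis."""
    z = _as_complex(trajectories)
    if z.shape[1] != basis.basis_functions.shape[1]:
        raise ValueError("trajectory length does not match the basis length")
    return z @ basis.basis_functions.conj().T


def coefficient_spectrum(basis: TrajectoryBasis) -> np.ndarray:
    """Per-index mean coefficient modulus across the set (plot on log scale)."""
    return basis.mean_moduli.copy()


def spectrum_slope(spectrum: np.ndarray, n_components: int = 8, floor: float = 1e-12) -> float:
    """Slope of log(mean modulus) vs component index over the leading
    components; closer to 0 means a slower decay (more random paths)."""
    m = np.asarray(spectrum, dtype=float)[:n_components]
    idx = np.arange(len(m))
    return float(stats.linregress(idx, np.log(np.maximum(m, floor))).slope)


def reconstruct(basis: TrajectoryBasis, coefficients: np.ndarray, k: int | None = None) -> np.ndarray:
    """Rank-k reconstruction of the centered complex trajectories."""
    if k is None:
        k = basis.basis_functions.shape[0]
    return coefficients[:, :k] @ basis.basis_functions[:k]


# ---------------------------------------------------------------------------
# trajectory crossings
# ---------------------------------------------------------------------------

_CLUSTER_TOL = 1e-6  # um; merge coincident intersection points


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2-D vectors (broadcasts)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _segment_intersection_points(
    a0, a1, b0, b1
) -> np.ndarray:
    """Representative intersection points for batches of segment pairs.

    Inputs are (m, 2) arrays: segment A from a0 to a1, B from b0 to b1.
    Returns an (h, 2) array with one representative point per intersecting
    pair — the crossing point for proper intersections, the touch point for
    endpoint contacts, and the overlap midpoint for collinear overlaps.
    """
    da = a1 - a0
    db = b1 - b0
    denom = _cross2(da, db)
    dab = b0 - a0
    points = []

    with np.errstate(divide="ignore", invalid="ignore"):
        t = _cross2(dab, db) / denom
        u = _cross2(dab, da) / denom
    eps = 1e-12
    proper = (np.abs(denom) > eps) & (t >= -eps) & (t <= 1 + eps) & (u >= -eps) & (u <= 1 + eps)
    if proper.any():
        points.append(a0[proper] + np.clip(t[proper], 0, 1)[:, None] * da[proper])

    # parallel or degenerate pairs: handle collinear overlap / point contacts
    par = ~(np.abs(denom) > eps)
    if par.any():
        for i in np.flatnonzero(par):
            pt = _parallel_pair_point(a0[i], a1[i], b0[i], b1[i])
            if pt is not None:
                points.append(pt[None, :])
    if not points:
        return np.empty((0, 2))
    return np.vstack(points)


def _parallel_pair_point(a0, a1, b0, b1, eps: float = 1e-9):
    """Intersection representative for parallel/degenerate segment pairs."""
    da = a1 - a0
    la = np.linalg.norm(da)
    if la < eps:  # A degenerated to a point
        return a0 if _point_on_segment(a0, b0, b1, eps) else None
    lb = np.linalg.norm(b1 - b0)
    if lb < eps:  # B degenerated to a point
        return b0 if _point_on_segment(b0, a0, a1, eps) else None
    # both real and parallel: intersect only if collinear with overlapping spans
    if abs(_cross2(b0 - a0, da)) / la > eps or abs(_cross2(b1 - a0, da)) / la > eps:
        return None
    u = da / la
    tb0 = float((b0 - a0) @ u)
    tb1 = float((b1 - a0) @ u)
    lo = max(0.0, min(tb0, tb1))
    hi = min(la, max(tb0, tb1))
    if lo > hi + eps:
        return None
    return a0 + 0.5 * (lo + hi) * u


def _point_on_segment(p, s0, s1, eps: float = 1e-9) -> bool:
    d = s1 - s0
    l = np.linalg.norm(d)
    if l < eps:
        return bool(np.linalg.norm(p - s0) < eps)
    t = float((p - s0) @ d) / (l * l)
    if t < -eps or t > 1 + eps:
        return False
    return bool(abs(_cross2(p - s0, d)) / l < eps)


def _cluster_count(points: np.ndarray, tol: float = _CLUSTER_TOL) -> int:
    """Number of clusters of points under single-linkage at `tol`."""
    if len(points) == 0:
        return 0
    if len(points) == 1:
        return 1
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return len({find(i) for i in range(len(points))})


def count_crossings(trajectories: list[Trajectory], window_steps: int) -> int:
    """Count trajectory crossings between distinct cells.

    A crossing is a geometric intersection of two segments whose time indices
    differ by at most ``window_steps`` (the second cell traverses where the
    first passed within the simultaneity window, ~1 h).  Per cell pair,
    coincident intersection points (e.g. several segment pairs touching the
    same vertex) are counted once.
    """
    paths = [np.asarray(t.positions, dtype=float) for t in trajectories]
    n = len(paths)
    total = 0
    bboxes = [
        (p[:, 0].min(), p[:, 0].max(), p[:, 1].min(), p[:, 1].max()) for p in paths
    ]
    t_count = len(paths[0]) - 1
    ii, jj = np.meshgrid(np.arange(t_count), np.arange(t_count), indexing="ij")
    in_window = np.abs(ii - jj) <= window_steps
    si = ii[in_window]
    sj = jj[in_window]
    for a in range(n):
        pa = paths[a]
        for b in range(a + 1, n):
            xa0, xa1, ya0, ya1 = bboxes[a]
            xb0, xb1, yb0, yb1 = bboxes[b]
            if xa1 < xb0 or xb1 < xa0 or ya1 < yb0 or yb1 < ya0:
                continue
            pb = paths[b]
            pts = _segment_intersection_points(
                pa[si], pa[si + 1], pb[sj], pb[sj + 1]
            )
            total += _cluster_count(pts)
    return total


# ---------------------------------------------------------------------------
# two-sample comparison
# ---------------------------------------------------------------------------


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; degenerate all-tied samples -> 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all observations tied; Mann-Whitney p reported as 1")
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _metric_table(trajectories: list[Trajectory]) -> dict[str, np.ndarray]:
    metrics = [compute_metrics(t) for t in trajectories]
    table = {
        "mean_speed": np.array([m.mean_speed for m in metrics]),
        "euclidean_distance": np.array([m.euclidean_distance for m in metrics]),
        "total_distance": np.array([m.total_distance for m in metrics]),
        "directionality": np.array([m.directionality for m in metrics]),
    }
    table["directionality"] = table["directionality"][~np.isnan(table["directionality"])]
    return table


def compare_sets(
    set_a: list[Trajectory],
    set_b: list[Trajectory],
    window_steps: int | None = None,
    n_spectrum: int = 8,
) -> dict:
    """Compare two trajectory sets the way experiments are compared to runs.

    Reports per-metric descriptive statistics and two-sided Mann-Whitney U
    p-values, the coefficient spectra of both sets expanded in the basis of
    ``set_a``, and crossing counts of each set.
    """
    if not set_a or not set_b:
        raise ValueError("both trajectory sets must be nonempty")
    ta = _metric_table(set_a)
    tb = _metric_table(set_b)
    report: dict = {"metrics": {}}
    for name in ("mean_speed", "euclidean_distance", "total_distance", "directionality"):
        xa, xb = ta[name], tb[name]
        report["metrics"][name] = {
            "mean_a": float(xa.mean()),
            "sd_a": float(xa.std(ddof=1)) if len(xa) > 1 else 0.0,
            "mean_b": float(xb.mean()),
            "sd_b": float(xb.std(ddof=1)) if len(xb) > 1 else 0.0,
            "p_value": _mannwhitney_p(xa, xb),
        }
    basis = extract_basis(set_a)
    coeff_b = expand_in_basis(set_b, basis)
    spec_a = coefficient_spectrum(basis)
    spec_b = np.abs(coeff_b).mean(axis=0)
    k = min(n_spectrum, len(spec_a))
    report["spectrum"] = {
        "basis": "set_a",
        "mean_moduli_a": spec_a.tolist(),
        "mean_moduli_b": spec_b.tolist(),
        "log_slope_a": spectrum_slope(spec_a, k),
        "log_slope_b": spectrum_slope(spec_b, k),
    }
    if window_steps is None:
        dt = set_a[0].dt
        window_steps = max(1, int(round(60.0 / dt)))
    report["crossings"] = {
        "window_steps": window_steps,
        "set_a": count_crossings(set_a, window_steps),
        "set_b": count_crossings(set_b, window_steps),
    }
    return report
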