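"""Melanoblast agents hopping on the keratinocyte vertex graph.

A population of melanoblasts (Mbs) occupies distinct polygon vertices and,
once per time step, each Mb either stays put or hops to an adjacent vertex.
Three move rules are supported:

* ``deterministic`` — hop to the free neighbor with the highest total
  potential phi_n (attraction - trail repulsion + anisotropy), or stay if
  the current node's sensed attraction beats every candidate;
* ``partially_random`` — with probability ``random_p`` hop to a uniformly
  chosen free neighbor, otherwise apply the deterministic rule;
* ``totally_random`` — always the uniform choice among free neighbors.

Every rule is gated by a per-cell move probability P in [p_min, 1] drawn at
seeding time, which produces the natural spread of cell speeds.  A run
follows the four-phase protocol: build the tiling, seed the Mbs at random
distinct vertices, advance 10 unrecorded warm-up steps so the potential
field reaches its stationary regime, then record 20 steps of positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DomainSpec, Tissue, build_tissue, mean_edge_length
from .potentials import (
    KcState,
    PotentialWeights,
    TrailField,
    anisotropy_value,
    node_attraction_all,
    sensed_potential_all,
    step_kc_potentials,
)

__all__ = [
    "Melanoblast",
    "SimulationConfig",
    "Trajectory",
    "SimulationResult",
    "CalibrationResult",
    "seed_melanoblasts",
    "SimulationState",
    "step",
    "run",
    "calibrate",
    "step_minutes_for",
]

MODELS = ("deterministic", "partially_random", "totally_random")


@dataclass
class Melanoblast:
    """A point agent: current vertex, per-step move probability, protrusion reach."""

    id: int
    node: int
    p_move: float
    sensing_depth: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run.

    Defaults mirror the wild-type setting: a 635 um square with ~4000 Kcs,
    157 Mbs, 9-minute steps (3 h over 20 recorded steps), sensing depth 2,
    and a 60-minute repulsion-trail memory.
    """

    domain: DomainSpec = field(default_factory=lambda: DomainSpec(635.0, 4000, seed=0))
    n_mbs: int = 157
    model: str = "deterministic"
    random_p: float = 0.0
    warmup_steps: int = 10
    recorded_steps: int = 20
    step_minutes: float = 9.0
    # Kc potential dynamics
    psi_base: float = 1.0
    alpha: float = 0.01
    c_f: float = 0.1
    c_b: float = 0.16
    # total-potential weights
    w_r: float = 0.5
    w_d: float = 0.0
    direction: tuple[float, float] | None = None
    # repulsion-trail memory; when disabled, repulsion acts only on currently
    # occupied nodes (inert under hard exclusion), with no memory of vacated ones
    trail_enabled: bool = True
    rho: float = 0.65
    trail_horizon: int | None = None  # None -> round(60 / step_minutes)
    # agents
    sensing_depth: int = 2
    gamma: float = 0.5
    p_min: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0.0 <= self.random_p <= 1.0:
            raise ValueError("random_p must lie in [0, 1]")
        if self.warmup_steps < 0 or self.recorded_steps < 0:
            raise ValueError("step counts must be >= 0")
        if not 0.0 <= self.p_min <= 1.0:
            raise ValueError("p_min must lie in [0, 1]")
        if self.sensing_depth not in (1, 2):
            raise ValueError("sensing_depth must be 1 or 2")
        if self.step_minutes <= 0:
            raise ValueError("step_minutes must be positive")

    @property
    def effective_trail_horizon(self) -> int:
        """Trail memory span in steps: ~60 min of steps, or 0 (occupancy-only
        repulsion, i.e. only just-vacated/occupied nodes repel) when the
        trail memory is disabled."""
        if not self.trail_enabled:
            return 0
        if self.trail_horizon is not None:
            return self.trail_horizon
        return int(round(60.0 / self.step_minutes))

    def to_dict(self) -> dict:
        d = {
            "domain": {
                "side_length": self.domain.side_length,
                "n_kcs": self.domain.n_kcs,
                "seed": self.domain.seed,
                "lloyd_iterations": self.domain.lloyd_iterations,
            }
        }
        for k in (
            "n_mbs", "model", "random_p", "warmup_steps", "recorded_steps",
            "step_minutes", "psi_base", "alpha", "c_f", "c_b", "w_r", "w_d",
            "direction", "trail_enabled", "rho", "trail_horizon",
            "sensing_depth", "gamma", "p_min", "seed",
        ):
            d[k] = getattr(self, k)
        if d["direction"] is not None:
            d["direction"] = list(d["direction"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        dom = d.pop("domain", {})
        domain = DomainSpec(
            side_length=float(dom.get("side_length", 635.0)),
            n_kcs=int(dom.get("n_kcs", 4000)),
            seed=int(dom.get("seed", 0)),
            lloyd_iterations=int(dom.get("lloyd_iterations", 0)),
        )
        if d.get("direction") is not None:
            d["direction"] = tuple(d["direction"])
        return cls(domain=domain, **d)


@dataclass
class Trajectory:
    """One cell's recorded path: positions in um at a fixed sampling interval."""

    cell_id: int
    positions: np.ndarray  # (n_samples, 2)
    dt: float              # minutes between samples

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")


def seed_melanoblasts(
    tissue: Tissue,
    n_mbs: int,
    p_min: float,
    seed: int | np.random.Generator,
    sensing_depth: int = 2,
) -> list[Melanoblast]:
    """Place Mbs on distinct vertices chosen uniformly at random, with move
    probabilities drawn uniformly in [p_min, 1]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mbs > tissue.n_nodes:
        raise ValueError("more melanoblasts than graph nodes")
    nodes = rng.choice(tissue.n_nodes, size=n_mbs, replace=False)
    p = rng.uniform(p_min, 1.0, size=n_mbs)
    return [
        Melanoblast(id=i, node=int(nodes[i]), p_move=float(p[i]), sensing_depth=sensing_depth)
        for i in range(n_mbs)
    ]


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`step`."""

    tissue: Tissue
    kc: KcState
    trail: TrailField
    weights: PotentialWeights
    mbs: list[Melanoblast]
    occupied: np.ndarray  # bool per node
    rng: np.random.Generator
    model: str = "deterministic"
    random_p: float = 0.0
    gamma: float = 0.5
    trail_memory: bool = True

    @classmethod
    def initialize(cls, config: SimulationConfig, tissue: Tissue | None = None) -> "SimulationState":
        tissue = tissue if tissue is not None else build_tissue(config.domain)
        rng = np.random.default_rng(config.seed)
        kc = KcState.from_tissue(
            tissue, psi_base=config.psi_base, alpha=config.alpha,
            c_f=config.c_f, c_b=config.c_b,
        )
        trail = TrailField.empty(
            tissue.n_nodes, rho=config.rho, horizon=config.effective_trail_horizon
        )
        direction = None if config.direction is None else np.asarray(config.direction, float)
        weights = PotentialWeights(w_r=config.w_r, w_d=config.w_d, direction=direction)
        mbs = seed_melanoblasts(
            tissue, config.n_mbs, config.p_min, rng, sensing_depth=config.sensing_depth
        )
        occupied = np.zeros(tissue.n_nodes, dtype=bool)
        occupied[[m.node for m in mbs]] = True
        state = cls(
            tissue=tissue, kc=kc, trail=trail, weights=weights, mbs=mbs,
            occupied=occupied, rng=rng, model=config.model,
            random_p=config.random_p, gamma=config.gamma,
            trail_memory=config.trail_enabled,
        )
        state._refresh_bound()
        # seeded nodes carry a fresh trail stamp
        trail.stamp(np.array([m.node for m in mbs]))
        return state

    def _refresh_bound(self) -> None:
        """A Kc is bound exactly while >= 1 Mb sits on one of its vertices."""
        bound = np.zeros(self.tissue.n_kcs, dtype=bool)
        for m in self.mbs:
            bound[self.tissue.node_kcs[m.node]] = True
        self.kc.bound = bound

    def positions(self) -> np.ndarray:
        return self.tissue.node_coords[[m.node for m in self.mbs]]


def _deterministic_choice(
    state: SimulationState, mb: Melanoblast, sensed: np.ndarray, trail_vals: np.ndarray
) -> int:
    """Argmax of phi_n over free neighbors; stay if the current node's sensed
    attraction beats every candidate.  Ties broken uniformly at random."""
    cur = mb.node
    cands = [int(v) for v in state.tissue.node_adjacency[cur] if not state.occupied[v]]
    if not cands:
        return cur
    w = state.weights
    scores = np.array([sensed[c] - w.w_r * trail_vals[c] for c in cands])
    if w.direction is not None:
        scores += w.w_d * np.array(
            [anisotropy_value(state.tissue, cur, c, w.direction) for c in cands]
        )
    best = scores.max()
    if sensed[cur] > best:
        return cur
    ties = np.flatnonzero(scores >= best - 1e-12)
    pick = ties[0] if len(ties) == 1 else state.rng.choice(ties)
    return cands[int(pick)]


def step(state: SimulationState) -> SimulationState:
    """Advance the population by one time step (in place; returns `state`).

    Mbs move sequentially in a fresh random order so node exclusion can never
    be violated.  Afterwards bound flags are refreshed, Kc potentials are
    stepped, and the trail field is aged and stamped at every node vacated or
    occupied this step.
    """
    tissue = state.tissue
    sensed_cache: dict[int, np.ndarray] = {}
    trail_vals = state.trail.values()
    prev_nodes = np.array([m.node for m in state.mbs])

    for i in state.rng.permutation(len(state.mbs)):
        mb = state.mbs[i]
        if state.rng.random() > mb.p_move:
            continue
        # totally_random is partially_random with random_p = 1 (same RNG stream,
        # so the variant reduction is exact)
        if state.model == "deterministic":
            go_random = False
        else:
            p_rand = 1.0 if state.model == "totally_random" else state.random_p
            go_random = state.rng.random() < p_rand
        if go_random:
            free = [int(v) for v in tissue.node_adjacency[mb.node] if not state.occupied[v]]
            if not free:
                continue
            new = int(state.rng.choice(free)) if len(free) > 1 else free[0]
        else:
            depth = mb.sensing_depth
            if depth not in sensed_cache:
                sensed_cache[depth] = sensed_potential_all(tissue, state.kc, depth, state.gamma)
            new = _deterministic_choice(state, mb, sensed_cache[depth], trail_vals)
        if new != mb.node:
            state.occupied[mb.node] = False
            state.occupied[new] = True
            mb.node = new

    cur_nodes = np.array([m.node for m in state.mbs])
    assert len(np.unique(cur_nodes)) == len(cur_nodes), "node exclusion violated"

    state._refresh_bound()
    state.kc = step_kc_potentials(state.kc)
    state.trail.advance()
    if state.trail_memory:
        vacated = prev_nodes[prev_nodes != cur_nodes]
        state.trail.stamp(np.concatenate([vacated, cur_nodes]))
    else:
        # memoryless repulsion: only nodes a Mb currently sits on repel
        state.trail.age[:] = np.where(state.occupied, 0, -1)
    return state


@dataclass
class SimulationResult:
    """Trajectories plus the tissue, config and a structured run log."""

    trajectories: list[Trajectory]
    tissue: Tissue
    config: SimulationConfig
    log: dict
    potential_snapshots: pd.DataFrame | None = None


def run(
    config: SimulationConfig,
    tissue: Tissue | None = None,
    record_potentials: bool = False,
) -> SimulationResult:
    """Execute the four-phase protocol and return recorded trajectories.

    Fully reproducible: the tissue derives from ``config.domain.seed`` and
    all dynamics randomness from ``config.seed``.
    """
    state = SimulationState.initialize(config, tissue=tissue)
    tissue = state.tissue
    if config.n_mbs >= tissue.n_nodes:
        raise ValueError("n_mbs must be smaller than the node count")

    for _ in range(config.warmup_steps):
        step(state)

    recorded = [state.positions()]
    snap_rows = []
    bound_counts = [int(state.kc.bound.sum())]
    if record_potentials:
        snap_rows.append(_snapshot(tissue, state.kc, 0))
    for t in range(1, config.recorded_steps + 1):
        step(state)
        recorded.append(state.positions())
        bound_counts.append(int(state.kc.bound.sum()))
        if record_potentials:
            snap_rows.append(_snapshot(tissue, state.kc, t))

    stack = np.stack(recorded)  # (T+1, n_mbs, 2)
    trajectories = [
        Trajectory(cell_id=i, positions=stack[:, i, :], dt=config.step_minutes)
        for i in range(config.n_mbs)
    ]
    log = {
        "seed": config.seed,
        "n_nodes": tissue.n_nodes,
        "n_kcs": tissue.n_kcs,
        "mean_edge_length_um": mean_edge_length(tissue),
        "occupancy_per_step": config.n_mbs,
        "bound_kcs_per_step": bound_counts,
        "trail_horizon_steps": config.effective_trail_horizon,
    }
    snapshots = pd.concat(snap_rows, ignore_index=True) if record_potentials else None
    return SimulationResult(
        trajectories=trajectories, tissue=tissue, config=config, log=log,
        potential_snapshots=snapshots,
    )


def _snapshot(tissue: Tissue, kc: KcState, step_idx: int) -> pd.DataFrame:
    phi = node_attraction_all(tissue, kc)
    return pd.DataFrame(
        {
            "step": step_idx,
            "node": np.arange(tissue.n_nodes),
            "x": tissue.node_coords[:, 0],
            "y": tissue.node_coords[:, 1],
            "phi": phi,
        }
    )


def step_minutes_for(total_minutes: float = 180.0, steps: int = 20) -> float:
    """Physical step duration so that `steps` recorded steps span the imaging
    window (3 h over 20 steps -> 9 min)."""
    if steps <= 0:
        raise ValueError("steps must be positive")
    return total_minutes / steps


@dataclass
class CalibrationResult:
    config: SimulationConfig
    achieved_mean_speed: float
    achieved_speed_sd: float
    attained: bool


def _speed_stats(config: SimulationConfig, tissue: Tissue, n_seeds: int) -> tuple[float, float]:
    """Mean and s.d. (across cells, pooled over seeds) of per-cell mean speed,
    in um per *step* (step_minutes factored out)."""
    speeds = []
    for s in range(n_seeds):
        cfg = replace(config, seed=config.seed + 1000 + s)
        res = run(cfg, tissue=tissue)
        for tr in res.trajectories:
            total = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1).sum()
            speeds.append(total / (len(tr.positions) - 1))
    arr = np.asarray(speeds)
    return float(arr.mean()), float(arr.std(ddof=1))


def calibrate(
    config: SimulationConfig,
    target_mean_speed: float,
    target_speed_sd: float,
    n_seeds: int = 5,
    tissue: Tissue | None = None,
    max_iter: int = 7,
) -> CalibrationResult:
    """Choose p_min and the physical step duration to match target speed stats.

    The spread of cell speeds depends only on the move-probability
    distribution, so p_min is bisected until the simulated coefficient of
    variation matches ``target_speed_sd / target_mean_speed``; the step
    duration is then fixed so the simulated mean speed equals
    ``target_mean_speed`` (for p_min = 1 this reduces to mean edge length /
    target speed).  If the target spread is outside the attainable range the
    closest endpoint is returned with ``attained=False``.
    """
    if target_mean_speed <= 0 or target_speed_sd < 0:
        raise ValueError("targets must be positive")
    tissue = tissue if tissue is not None else build_tissue(config.domain)
    target_cv = target_speed_sd / target_mean_speed

    def cv_at(p_min: float) -> tuple[float, float]:
        m, s = _speed_stats(replace(config, p_min=p_min), tissue, n_seeds)
        return (s / m if m > 0 else np.inf), m

    evals: list[tuple[float, float]] = []  # (p_min, cv)
    lo, hi = 0.0, 1.0
    cv_hi, m_hi = cv_at(hi)   # smallest attainable spread
    cv_lo, m_lo = cv_at(lo)   # largest attainable spread
    evals += [(hi, cv_hi), (lo, cv_lo)]
    attained = True
    if target_cv <= cv_hi:
        p_best, cv_best = hi, cv_hi
        attained = target_cv >= cv_hi * 0.9
    elif target_cv >= cv_lo:
        p_best, cv_best = lo, cv_lo
        attained = False
    else:
        p_best, cv_best = hi, cv_hi
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            cv_mid, _ = cv_at(mid)
            evals.append((mid, cv_mid))
            if abs(cv_mid - target_cv) < abs(cv_best - target_cv):
                p_best, cv_best = mid, cv_mid
            if cv_mid > target_cv:
                lo = mid
            else:
                hi = mid
            if abs(cv_best - target_cv) / target_cv < 0.015:
                break
    # refine with more replicates; if still off, take one secant step through
    # the sampled (p_min, cv) curve (cv is close to linear in p_min)
    m_best, s_best = _speed_stats(replace(config, p_min=p_best), tissue, 3 * n_seeds)
    cv_best = s_best / m_best
    if attained and abs(cv_best - target_cv) / target_cv > 0.01 and 0.0 < p_best < 1.0:
        ps = np.array([e[0] for e in evals] + [p_best])
        cvs = np.array([e[1] for e in evals] + [cv_best])
        slope, intercept = np.polyfit(ps, cvs, 1)
        if slope < 0:
            p_new = float(np.clip((target_cv - intercept) / slope, 0.0, 1.0))
            m_new, s_new = _speed_stats(replace(config, p_min=p_new), tissue, 3 * n_seeds)
            if abs(s_new / m_new - target_cv) < abs(cv_best - target_cv):
                p_best, m_best, s_best = p_new, m_new, s_new
                cv_best = s_best / m_best
    step_minutes = m_best / target_mean_speed
    cfg = replace(config, p_min=p_best, step_minutes=step_minutes)
    return CalibrationResult(
        config=cfg,
        achieved_mean_speed=m_best / step_minutes,
        achieved_speed_sd=s_best / step_minutes,
        attained=attained,
    )
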