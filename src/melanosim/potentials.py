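"""Keratinocyte attraction potentials and the total node potential.

Each Kc carries a scalar attraction potential psi, read as the local density
of secreted soluble attractant (Kit ligand / endothelins): psi ramps up
linearly while the Kc is free and decays while a melanoblast is bound to it,
saturating at a per-cell threshold psi_max that grows with the polygon
perimeter (larger Kcs, later in the cell cycle, attract more).

Melanoblast moves are driven by a per-node total potential

    phi_n = phi_A - w_r * phi_R + w_d * phi_D

where phi_A is the protrusion-sensed attraction (distance-discounted average
of nodal Kc-potential means), phi_R in [0, 1] is the decaying repulsion
trail rho**k left at nodes a melanoblast occupied k steps ago, and phi_D in
[0, 1] = (1 + cos(theta)) / 2 rewards displacement along a favored
anisotropy direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Tissue

__all__ = [
    "KcState",
    "TrailField",
    "PotentialWeights",
    "step_kc_potentials",
    "node_attraction",
    "node_attraction_all",
    "sensed_potential",
    "sensed_potential_all",
    "trail_value",
    "total_potential",
]

NEVER = -1  # trail age sentinel: node never occupied


@dataclass
class KcState:
    """Per-keratinocyte attraction potentials and their rise/decay rates.

    psi is dimensionless and confined to [0, psi_max]; c_f and c_b are the
    per-step rise (free Kc) and decay (bound Kc) increments.
    """

    psi: np.ndarray
    bound: np.ndarray
    psi_max: np.ndarray
    c_f: float
    c_b: float

    def __post_init__(self) -> None:
        if np.any(self.psi_max <= 0):
            raise ValueError("psi_max must be positive for every Kc")
        if np.any(self.psi < 0) or np.any(self.psi > self.psi_max):
            raise ValueError("psi must lie in [0, psi_max]")

    @classmethod
    def from_tissue(
        cls,
        tissue: Tissue,
        psi_base: float = 1.0,
        alpha: float = 0.01,
        c_f: float = 0.1,
        c_b: float = 0.16,
        psi0: float = 0.0,
    ) -> "KcState":
        """Initialize all-free Kcs with perimeter-modulated thresholds.

        psi_max[k] = psi_base + alpha * (perimeter[k] - mean perimeter),
        clipped to stay positive; constant for the whole run.
        """
        per = tissue.kc_perimeter
        psi_max = psi_base + alpha * (per - per.mean())
        psi_max = np.clip(psi_max, 0.1 * psi_base, None)
        psi = np.full(tissue.n_kcs, psi0, dtype=float)
        psi = np.minimum(psi, psi_max)
        return cls(
            psi=psi,
            bound=np.zeros(tissue.n_kcs, dtype=bool),
            psi_max=psi_max,
            c_f=c_f,
            c_b=c_b,
        )


@dataclass
class TrailField:
    """Per-node repulsion-trail memory.

    age[n] is the number of steps since a melanoblast last occupied node n
    (NEVER if none ever did); the trail potential is rho**age for ages up to
    `horizon`, after which the trail is dropped.
    """

    age: np.ndarray
    rho: float
    horizon: int

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    @classmethod
    def empty(cls, n_nodes: int, rho: float = 0.65, horizon: int = 7) -> "TrailField":
        return cls(age=np.full(n_nodes, NEVER, dtype=np.int64), rho=rho, horizon=horizon)

    def advance(self) -> None:
        self.age[self.age != NEVER] += 1

    def stamp(self, nodes: np.ndarray) -> None:
        self.age[nodes] = 0

    def values(self) -> np.ndarray:
        """Vector of trail potentials rho**k over all nodes."""
        v = np.zeros_like(self.age, dtype=float)
        live = (self.age != NEVER) & (self.age <= self.horizon)
        v[live] = self.rho ** self.age[live]
        return v


@dataclass
class PotentialWeights:
    """Weights of the repulsion-trail and anisotropy terms of phi_n."""

    w_r: float = 0.0
    w_d: float = 0.0
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_r) and np.isfinite(self.w_d)):
            raise ValueError("weights must be finite")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            norm = np.linalg.norm(d)
            if norm == 0:
                raise ValueError("anisotropy direction must be nonzero")
            self.direction = d / norm


def step_kc_potentials(kc: KcState) -> KcState:
    """Advance psi by one step: linear rise toward psi_max while free, linear
    decay toward 0 while bound.  Bound flags are untouched."""
    psi = kc.psi.copy()
    free = ~kc.bound
    psi[free] = np.minimum(psi[free] + kc.c_f, kc.psi_max[free])
    psi[kc.bound] = np.maximum(psi[kc.bound] - kc.c_b, 0.0)
    return replace(kc, psi=psi, bound=kc.bound.copy())


def node_attraction_all(tissue: Tissue, kc: KcState) -> np.ndarray:
    """phi per node: mean psi of the Kcs incident to each node."""
    return tissue.node_kc_matrix @ kc.psi


def node_attraction(tissue: Tissue, kc: KcState, node: int) -> float:
    kcs = tissue.node_kcs[node]
    assert len(kcs) > 0, "every node is a vertex of at least one Kc"
    return float(kc.psi[kcs].mean())


def sensed_potential_all(
    tissue: Tissue, kc: KcState, depth: int, gamma: float = 0.5
) -> np.ndarray:
    """Vector of protrusion-sensed attractions phi_A at every candidate node.

    depth=1: the nodal attraction itself.  depth=2: distance-discounted
    average with weight 1 for the candidate and weight gamma spread over its
    graph neighbors (one extra Kc away).
    """
    phi = node_attraction_all(tissue, kc)
    if depth == 1:
        return phi
    if depth == 2:
        return (phi + gamma * (tissue.adjacency_mean_matrix @ phi)) / (1.0 + gamma)
    raise ValueError("sensing depth must be 1 or 2")


def sensed_potential(
    tissue: Tissue, kc: KcState, candidate: int, depth: int, gamma: float = 0.5
) -> float:
    """phi_A sensed from `candidate` with protrusions reaching `depth` Kcs."""
    if depth == 1:
        return node_attraction(tissue, kc, candidate)
    if depth == 2:
        nbrs = tissue.node_adjacency[candidate]
        own = node_attraction(tissue, kc, candidate)
        around = float(np.mean([node_attraction(tissue, kc, int(m)) for m in nbrs]))
        return (own + gamma * around) / (1.0 + gamma)
    raise ValueError("sensing depth must be 1 or 2")


def trail_value(trail: TrailField, node: int) -> float:
    """Repulsion-trail potential rho**k at a node (0 if never occupied or
    older than the horizon; 1 if occupied this step)."""
    k = int(trail.age[node])
    if k == NEVER or k > trail.horizon:
        return 0.0
    return float(trail.rho**k)


def anisotropy_value(
    tissue: Tissue, mb_position: int, candidate: int, direction: np.ndarray
) -> float:
    """phi_D = (1 + cos theta)/2 between the hop displacement and the favored
    direction; 0.5 for a zero displacement."""
    disp = tissue.node_coords[candidate] - tissue.node_coords[mb_position]
    norm = np.linalg.norm(disp)
    if norm == 0:
        return 0.5
    return float((1.0 + disp @ direction / norm) / 2.0)


def total_potential(
    tissue: Tissue,
    kc: KcState,
    trail: TrailField,
    weights: PotentialWeights,
    mb_position: int,
    candidate: int,
    depth: int,
    gamma: float = 0.5,
) -> float:
    """Total node potential phi_n = phi_A - w_r*phi_R + w_d*phi_D at `candidate`
    for a melanoblast currently sitting at `mb_position`."""
    phi = sensed_potential(tissue, kc, candidate, depth, gamma)
    phi -= weights.w_r * trail_value(trail, candidate)
    if weights.direction is not None:
        phi += weights.w_d * anisotropy_value(tissue, mb_position, candidate, weights.direction)
    return phi
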