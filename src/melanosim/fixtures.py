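"""Synthetic "experimental-like" trajectory tables and end-to-end demos.

The fixture generator stands in for manual-tracking exports of time-lapse
movies: per-cell, per-frame positions sampled every 5 minutes for 3 hours
(36 frames) inside a 635 um field.  Motion models range from idealized
(straight, random walk, biased walk) to the full simulator resampled onto
the experimental frame grid.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import compare_sets, count_crossings
from .geometry import DomainSpec
from .io import COLUMNS, frame_to_trajectories, trajectories_to_frame
from .simulator import SimulationConfig, Trajectory, run

__all__ = ["FixtureSpec", "generate_fixture", "end_to_end"]

MOTION_MODELS = ("straight", "random_walk", "biased_walk", "from_simulator")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic tracked-trajectory table.

    Defaults emulate the imaging protocol: 36 frames at 5-minute intervals
    (3 h) in a 635 um square, ~155 tracked cells moving at a realistic
    embryonic-melanoblast pace (a few tenths of um/min).
    """

    n_cells: int = 155
    n_frames: int = 36
    frame_minutes: float = 5.0
    field_side: float = 635.0
    motion_model: str = "random_walk"
    speed_um_min: float = 0.45
    speed_sd: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motion_model not in MOTION_MODELS:
            raise ValueError(f"motion_model must be one of {MOTION_MODELS}")


def _reflect(pos: np.ndarray, side: float) -> np.ndarray:
    """Fold positions back into [0, side] by reflection at the walls."""
    pos = np.mod(pos, 2 * side)
    over = pos > side
    pos[over] = 2 * side - pos[over]
    return pos


def generate_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Generate a tidy trajectory table (cell_id, step, t_min, x_um, y_um)."""
    rng = np.random.default_rng(spec.seed)
    n, T, dt, side = spec.n_cells, spec.n_frames, spec.frame_minutes, spec.field_side

    if spec.motion_model == "from_simulator":
        n_kcs = max(4, int(round(4000 * (side / 635.0) ** 2)))
        cfg = SimulationConfig(
            domain=DomainSpec(side, n_kcs, seed=spec.seed),
            n_mbs=spec.n_cells,
            seed=spec.seed,
        )
        trajs = run(cfg).trajectories
        pos = np.stack([t.positions for t in trajs], axis=1)  # (steps+1, n, 2)
        t_sim = np.arange(pos.shape[0]) * cfg.step_minutes
        t_frames = np.arange(T) * dt
        t_frames = np.clip(t_frames, 0, t_sim[-1])
        resampled = np.empty((T, n, 2))
        for axis in (0, 1):
            for c in range(n):
                resampled[:, c, axis] = np.interp(t_frames, t_sim, pos[:, c, axis])
        xy = resampled
    else:
        speeds = np.clip(
            rng.normal(spec.speed_um_min, spec.speed_sd, size=n), 0.05, None
        )
        step_len = speeds * dt
        start = rng.uniform(0.05 * side, 0.95 * side, size=(n, 2))
        xy = np.empty((T, n, 2))
        xy[0] = start
        if spec.motion_model == "straight":
            theta = rng.uniform(0, 2 * np.pi, size=n)
            vel = np.stack([np.cos(theta), np.sin(theta)], axis=1) * step_len[:, None]
            # shrink runs that would leave the field so paths stay straight
            for c in range(n):
                for axis in (0, 1):
                    end = start[c, axis] + vel[c, axis] * (T - 1)
                    if end < 0 or end > side:
                        room = (start[c, axis] if vel[c, axis] < 0 else side - start[c, axis])
                        vel[c] *= room / (abs(vel[c, axis]) * (T - 1)) * 0.99
            for t in range(1, T):
                xy[t] = xy[t - 1] + vel
        elif spec.motion_model == "random_walk":
            for t in range(1, T):
                theta = rng.uniform(0, 2 * np.pi, size=n)
                stepv = np.stack([np.cos(theta), np.sin(theta)], axis=1) * step_len[:, None]
                xy[t] = _reflect(xy[t - 1] + stepv, side)
        else:  # biased_walk
            bias_theta = rng.uniform(0, 2 * np.pi)
            drift = np.array([np.cos(bias_theta), np.sin(bias_theta)])
            for t in range(1, T):
                theta = rng.uniform(0, 2 * np.pi, size=n)
                noise = np.stack([np.cos(theta), np.sin(theta)], axis=1)
                stepv = (0.7 * drift[None, :] + 0.3 * noise) * step_len[:, None]
                xy[t] = _reflect(xy[t - 1] + stepv, side)

    if spec.noise_sd > 0:
        xy = xy + rng.normal(0, spec.noise_sd, size=xy.shape)
        xy = _reflect(xy, side)

    trajs = [
        Trajectory(cell_id=c, positions=xy[:, c, :], dt=dt) for c in range(n)
    ]
    return trajectories_to_frame(trajs)


def end_to_end(
    config: SimulationConfig,
    reference: pd.DataFrame | None = None,
    n_seeds: int = 20,
) -> dict:
    """Simulate with and without the repulsion-trail memory over paired seeds,
    compare against a reference trajectory table, and report crossing counts.

    This reproduces the memory-effect comparison: the trail term should
    roughly halve the number of trajectory crossings while leaving the
    classical metrics and coefficient spectra close to the reference.
    """
    if reference is None:
        reference = generate_fixture(
            FixtureSpec(
                n_cells=config.n_mbs,
                n_frames=config.recorded_steps + 1,
                frame_minutes=config.step_minutes,
                field_side=config.domain.side_length,
                motion_model="from_simulator",
                seed=config.seed + 7919,
            )
        )
    ref_trajs = frame_to_trajectories(reference)
    window = max(1, int(round(60.0 / config.step_minutes)))

    crossings = {"with_trail": [], "without_trail": []}
    last = {}
    for s in range(n_seeds):
        seed = config.seed + s
        for label, trail in (("with_trail", True), ("without_trail", False)):
            cfg = replace(
                config,
                seed=seed,
                trail_enabled=trail,
                domain=replace(config.domain, seed=seed),
            )
            trajs = run(cfg).trajectories
            crossings[label].append(count_crossings(trajs, window))
            last[label] = trajs

    report = {
        "config": config.to_dict(),
        "n_seeds": n_seeds,
        "crossings": {
            k: {"mean": float(np.mean(v)), "per_seed": v} for k, v in crossings.items()
        },
        "comparison_vs_reference": {
            k: compare_sets(ref_trajs, trajs, window_steps=window)
            for k, trajs in last.items()
        },
    }
    report["crossings"]["reduction_factor"] = (
        report["crossings"]["without_trail"]["mean"]
        / max(report["crossings"]["with_trail"]["mean"], 1e-9)
    )
    return report
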