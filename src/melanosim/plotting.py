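"""Figure helpers: trajectory overlays, coefficient spectra, potential maps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .simulator import Trajectory

__all__ = ["plot_trajectories", "plot_spectra", "plot_potential_snapshot"]


def plot_trajectories(trajectories: list[Trajectory], ax=None, side: float | None = None):
    """Overlay all trajectories with open dots at their start positions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for tr in trajectories:
        p = tr.positions
        ax.plot(p[:, 0], p[:, 1], lw=0.7)
        ax.plot(p[0, 0], p[0, 1], "o", mfc="none", ms=3, color="tab:blue")
    if side is not None:
        ax.set_xlim(0, side)
        ax.set_ylim(0, side)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    return ax


def plot_spectra(spectra: dict[str, np.ndarray], ax=None, n_components: int = 10):
    """Mean coefficient moduli vs component index on a log scale."""
    if ax is None:
        _, ax = plt.subplots()
    for label, spec in spectra.items():
        m = np.asarray(spec)[:n_components]
        ax.semilogy(np.arange(1, len(m) + 1), m, marker="o", label=label)
    ax.set_xlabel("component index")
    ax.set_ylabel("mean |coefficient|")
    ax.legend()
    return ax


def plot_potential_snapshot(snapshot, ax=None):
    """Scatter map of the nodal attraction potential (one recorded step)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(snapshot["x"], snapshot["y"], c=snapshot["phi"], s=4, cmap="jet")
    plt.colorbar(sc, ax=ax, label="Φ_A")
    ax.set_aspect("equal")
    return ax
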