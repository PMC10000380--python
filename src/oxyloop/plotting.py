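"""Time-series and control-surface plots (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fuzzy import FuzzyGainSystem, control_surface
from .simulate import SimulationResult

__all__ = ["plot_run", "plot_surface"]


def plot_run(res: SimulationResult, out_dir: str | Path, name: str = "run") -> list[Path]:
    """Write tracking (y/ym/r) and control-signal (u/theta/m) figures.

    File names are deterministic: ``<name>_tracking.png`` and
    ``<name>_control.png`` under ``out_dir``.
    """
    if len(res.t) == 0:
        raise ValueError("cannot plot an empty simulation result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(res.t, res.r, "k--", lw=1, label="set-point r")
    ax.plot(res.t, res.ym, lw=1, label="reference y_m")
    ax.plot(res.t, res.y, lw=1.5, label="patient y")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("SpO2 (%)")
    ax.legend(loc="lower right")
    ax.grid(alpha=0.3)
    p = out_dir / f"{name}_tracking.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(3, 1, figsize=(8, 7), sharex=True)
    axes[0].plot(res.t, res.u, lw=1)
    axes[0].set_ylabel("u (% supply)")
    axes[1].plot(res.t, res.theta, lw=1)
    axes[1].set_ylabel("theta")
    axes[2].plot(res.t, res.m, lw=1)
    axes[2].set_ylabel("m")
    axes[2].set_xlabel("time (s)")
    for ax in axes:
        ax.grid(alpha=0.3)
    p = out_dir / f"{name}_control.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def plot_surface(sys: FuzzyGainSystem, out: str | Path, grid_n: int = 101) -> Path:
    """Heatmap of the fuzzy control surface m(e, de)."""
    e_grid, de_grid, M = control_surface(sys, grid_n)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(de_grid, e_grid, M, cmap="RdBu_r", vmin=-1, vmax=1, shading="auto")
    fig.colorbar(im, ax=ax, label="adaptation gain m")
    ax.set_xlabel("error increment de")
    ax.set_ylabel("model-following error e")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
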