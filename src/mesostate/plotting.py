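"""Figure helpers for the pipeline report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_state_maps(maps: np.ndarray, mask: np.ndarray,
                    names: list[str] | None = None,
                    path: str | Path | None = None):
    """Mean DF/F z-score map per consensus state."""
    n = maps.shape[0]
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.6))
    vmax = np.abs(maps).max() or 1.0
    for i, ax in enumerate(np.atleast_1d(axes)):
        shown = np.where(mask, maps[i], np.nan)
        ax.imshow(shown, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        title = f"state {i}"
        if names is not None:
            title += f"\n{names[i]}"
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_tdistance_curves(curves: dict[int, dict[int, float]],
                          path: str | Path | None = None):
    """Cumulative t-distance vs candidate state count, one line per mouse."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for mouse, curve in curves.items():
        ks = sorted(curve)
        ax.plot(ks, [curve[k] for k in ks], marker="o", label=f"mouse {mouse}")
        ax.axvline(max(curve, key=lambda k: (curve[k], -k)), ls=":", lw=0.8)
    ax.set_xlabel("number of states k")
    ax.set_ylabel("t-distance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_peri_event(offsets: np.ndarray, p_obs: np.ndarray,
                    significant: np.ndarray | None = None,
                    fps: float = 15.0, path: str | Path | None = None):
    """Peri-event state probability histogram (one panel per state)."""
    n = p_obs.shape[0]
    fig, axes = plt.subplots(n, 1, figsize=(5, 1.1 * n), sharex=True)
    t = offsets / fps
    for s, ax in enumerate(np.atleast_1d(axes)):
        ax.plot(t, p_obs[s], lw=1.0)
        if significant is not None and significant[s].any():
            ax.plot(t[significant[s]], p_obs[s][significant[s]], ".",
                    color="k", ms=3)
        ax.axvline(0.0, color="gray", lw=0.6)
        ax.set_ylabel(f"P{s}", fontsize=8)
        ax.set_ylim(0, 1)
    np.atleast_1d(axes)[-1].set_xlabel("time from event (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
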