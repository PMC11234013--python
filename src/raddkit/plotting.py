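"""Optional matplotlib views of traces, fits, and screening windows."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .models import SequentialParams, sequential_species
from .screening import ScreenStats

__all__ = ["plot_traces", "plot_species", "plot_screen_bands"]

_ROLE_COLORS = {
    "sample": "tab:blue",
    "inhibited_sample": "tab:purple",
    "endoq_tdu_control": "tab:green",
    "negative_tc": "tab:red",
    "buffer_blank": "tab:gray",
}


def plot_traces(traces, ax=None, ylabel: str = "RFU"):
    """Kinetic traces coloured by well role."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    seen = set()
    for tr in traces:
        label = tr.role if tr.role not in seen else None
        seen.add(tr.role)
        ax.plot(tr.times / 60.0, tr.values, color=_ROLE_COLORS.get(tr.role, "k"),
                alpha=0.7, label=label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_species(p: SequentialParams, t_max: float = 3600.0, ax=None):
    """Theoretical substrate / intermediate / product curves of S -> I -> P."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.linspace(0.0, t_max, 400)
    s, i, prod = sequential_species(t, p)
    ax.plot(t / 60.0, s, label="intact reporter")
    ax.plot(t / 60.0, i, label="deaminated intermediate")
    ax.plot(t / 60.0, prod, label="cleaved product")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (uM)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_screen_bands(stats: ScreenStats, pos, neg, ax=None):
    """Endpoint scatter with mean and mean +/- 3 SD bands per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    ax.scatter(np.arange(pos.size), pos, color="tab:blue", label="positive")
    ax.scatter(np.arange(neg.size), neg, color="tab:red", label="negative")
    for mu, band, color in (
        (stats.mu_pos, stats.pos_band, "tab:blue"),
        (stats.mu_neg, stats.neg_band, "tab:red"),
    ):
        ax.axhline(mu, color=color, lw=1.5)
        for y in band:
            ax.axhline(y, color=color, lw=1.0, ls="--")
    ax.set_xlabel("well index")
    ax.set_ylabel("endpoint RFU")
    ax.set_title(f"Z' = {stats.z_prime:.2f}  S:N = {stats.snr:.1f}  S:B = {stats.sbr:.1f}")
    ax.legend(frameon=False, fontsize=8)
    return ax
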