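"""Plots of NPS, MTF and profile curves for experiment reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_COLORS = {"HIR": "tab:blue", "DLR": "tab:orange", "SR-DLR": "tab:green"}


def _color(name: str):
    return _COLORS.get(name)


def plot_nps(result, path: str | Path) -> Path:
    """Radial noise power spectra of every preset."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, r in result.presets.items():
        keep = r.nps.freq >= r.nps.low_freq_cutoff
        ax.plot(r.nps.freq[keep], r.nps.nps[keep], label=name, color=_color(name))
    ax.set_xlabel("spatial frequency (cycle/mm)")
    ax.set_ylabel(r"NPS (HU$^2$ mm$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_mtf(result, path: str | Path) -> Path:
    """Task-based MTF in-plane (left) and through-plane (right)."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, attr, title in (
        (axes[0], "mtf_xy", "XY plane"),
        (axes[1], "mtf_z", "Z direction"),
    ):
        for name, r in result.presets.items():
            m = getattr(r, attr)
            ax.plot(m.freq, m.mtf, label=name, color=_color(name))
        m = getattr(result, f"model_{attr}")
        ax.plot(m.freq, m.mtf, "k--", label="model")
        ax.axhline(0.1, color="gray", lw=0.5)
        ax.set_xlim(0, 2.0)
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("spatial frequency (cycle/mm)")
        ax.set_title(title)
    axes[0].set_ylabel("T-MTF")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_profiles(result, path: str | Path) -> Path:
    """Orthogonal profile curves at every measurement site."""
    sites = list(result.model_profiles)
    fig, axes = plt.subplots(1, len(sites), figsize=(4 * len(sites), 4), sharey=True)
    if len(sites) == 1:
        axes = [axes]
    for ax, label in zip(axes, sites):
        for name, r in result.presets.items():
            prof = r.profiles[label]
            ax.plot(prof.positions, prof.values, label=name, color=_color(name))
        mp = result.model_profiles[label]
        ax.plot(mp.positions, mp.values, "k--", label="model")
        ax.set_title(label)
        ax.set_xlabel("offset (mm)")
    axes[0].set_ylabel("CT number (HU)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
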