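"""Figures: amplitude-frequency scatters, tunability bars, ratio curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tunability import TunabilityReport

__all__ = [
    "plot_amp_freq_scatter",
    "plot_tunability_bars",
    "plot_extra_domain_curve",
]

_CONFIG_COLORS = {
    "positive_only": "tab:red",
    "negative_only": "tab:blue",
    "hybrid": "tab:purple",
    "none": "0.4",
}


def plot_amp_freq_scatter(point_sets: dict, path: str | Path, title: str = ""):
    """Scatter of (frequency, amplitude) per feedback configuration."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cfg, pts in point_sets.items():
        pts = np.asarray(pts)
        if len(pts) == 0:
            continue
        ax.scatter(
            pts[:, 0], pts[:, 1], s=12, alpha=0.6,
            label=cfg, color=_CONFIG_COLORS.get(cfg),
        )
    ax.set_xlabel("frequency (cycles / time unit)")
    ax.set_ylabel("amplitude (signal units)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_tunability_bars(report: TunabilityReport, path: str | Path):
    """Paired bars: normalized frequency and amplitude tunability per config."""
    configs = list(report.entries)
    freq = [report.entries[c].tunability_freq for c in configs]
    amp = [report.entries[c].tunability_amp for c in configs]
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharey=False)
    for ax, values, label in zip(axes, (freq, amp), ("frequency", "amplitude")):
        ax.bar(
            configs, values,
            color=[_CONFIG_COLORS.get(c, "0.5") for c in configs],
        )
        ax.set_ylabel(f"normalized {label} tunability")
        ax.tick_params(axis="x", rotation=20)
    fig.suptitle(f"{report.model_name} / {report.observable}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_extra_domain_curve(curve, path: str | Path, title: str = ""):
    """Extra-domain percentage vs dominant-to-recessive feedback ratio."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["ratio"], curve["extra_domain_pct"], "o-")
    ax.set_xscale("log")
    ax.set_xlabel("dominant / recessive feedback strength ratio")
    ax.set_ylabel("extra accessible states (%)")
    ax.set_ylim(bottom=min(0.0, float(curve["extra_domain_pct"].min())))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
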