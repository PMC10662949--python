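"""Matplotlib figures for the pipeline outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .chip import MetageneProfile
from .foci import MitoticProfile
from .hic import ContactMatrix, PairSubmatrixStack

__all__ = [
    "plot_contact_map",
    "plot_decay_curves",
    "plot_metagene",
    "plot_aggregate",
    "plot_foci_profile",
]


def _chrom_boundaries(m: ContactMatrix) -> list[int]:
    edges, offset = [], 0
    for nb in m.bins_per_chrom[:-1]:
        offset += nb
        edges.append(offset)
    return edges


def plot_contact_map(m: ContactMatrix, path: str | Path, log: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    data = m.matrix
    if log:
        with np.errstate(divide="ignore"):
            data = np.log10(np.where(data > 0, data, np.nan))
    im = ax.imshow(data, cmap="Reds", interpolation="nearest")
    for edge in _chrom_boundaries(m):
        ax.axhline(edge - 0.5, color="grey", lw=0.5)
        ax.axvline(edge - 0.5, color="grey", lw=0.5)
    ax.set_title(f"{m.condition or ''} ({m.state})".strip())
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_decay_curves(curves: dict, path: str | Path) -> None:
    """``curves``: condition label -> decay DataFrame."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.loglog(curve["distance_bp"], curve["probability"], label=label)
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("median contact probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metagene(profile: MetageneProfile, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(profile.mean.size)
    ax.plot(x, profile.mean, label=label or None)
    ax.fill_between(
        x, profile.mean - profile.sd, profile.mean + profile.sd, alpha=0.25
    )
    for edge in (profile.flank_bins, profile.flank_bins + profile.body_bins):
        ax.axvline(edge - 0.5, color="grey", lw=0.5, ls="--")
    ax.set_xticks(
        [profile.flank_bins, profile.flank_bins + profile.body_bins],
        ["TSS", "TES"],
    )
    ax.set_ylabel("mean calibrated ratio")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_aggregate(stack: PairSubmatrixStack, path: str | Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, data, title in (
        (axes[0], stack.aggregate(), "raw"),
        (axes[1], stack.aggregate_quantized(), "rank-quantized"),
    ):
        im = ax.imshow(data, cmap="Reds", interpolation="nearest")
        ax.set_title(f"{stack.pair_class} ({title})")
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_foci_profile(profile: MitoticProfile, path: str | Path) -> None:
    """Foci-count vs spindle-length scatter with stage shading."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t1, t2 = profile.summary.get("thresholds", (4.0, 5.0))
    ax.axvspan(0, t1, color="tab:blue", alpha=0.08, label="metaphase")
    ax.axvspan(t1, t2, color="tab:orange", alpha=0.08, label="anaphase")
    xmax = max(profile.per_cell.spindle_length.max() * 1.05, t2 + 1)
    ax.axvspan(t2, xmax, color="tab:red", alpha=0.08, label="late anaphase")
    ax.scatter(
        profile.per_cell.spindle_length,
        profile.per_cell.focus_count,
        s=12,
        color="k",
        alpha=0.6,
    )
    ax.set_xlim(0, xmax)
    ax.set_xlabel("SPB-SPB distance (um)")
    ax.set_ylabel("telomere foci")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
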