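"""Optional figure analogs (length histogram, strand-bias curves, profiles).

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_length_distribution(counts: Mapping[int, int], path: str | Path) -> None:
    plt = _plt()
    lengths = sorted(counts)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(lengths, [counts[k] for k in lengths], color="steelblue")
    ax.set_xlabel("sRNA length (nt)")
    ax.set_ylabel("redundant reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_first_base_composition(comp: Mapping[str, float], path: str | Path) -> None:
    plt = _plt()
    bases = ["A", "C", "G", "U"]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.bar(bases, [comp.get(b, 0.0) for b in bases], color="darkseagreen")
    ax.set_ylabel("fraction of unique sRNAs")
    ax.set_xlabel("5' nucleotide")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_strand_bias_curves(records: Sequence, path: str | Path) -> None:
    """Two percentage curves (sense/antisense) over rank order."""
    plt = _plt()
    ranks = np.arange(1, len(records) + 1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(ranks, [r.pct_sense for r in records], color="tab:blue",
            label="sense")
    ax.plot(ranks, [r.pct_antisense for r in records], color="tab:red",
            label="antisense")
    ax.set_xlabel("reference rank (by % sense)")
    ax.set_ylabel("% of sRNAs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stop_distance_profile(profile: np.ndarray, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(np.arange(len(profile)), profile, color="black", lw=0.8)
    ax.set_xlabel("distance from stop codon (nt)")
    ax.set_ylabel("mean relative tag frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_peak_factor_histogram(hist: Mapping[int, int], path: str | Path) -> None:
    plt = _plt()
    bins = sorted(hist)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar([str(b) if b < max(bins) else f"{b}+" for b in bins],
           [hist[b] for b in bins], color="indianred")
    ax.set_xlabel("peak factor (x mean)")
    ax.set_ylabel("peaks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
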