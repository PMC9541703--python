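"""Convenience plots: conditional QQ, conjFDR Manhattan, overlap summary.

Rendering is environment-dependent; plots are not part of the deterministic
output contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_conditional_qq(curves: dict, path: str | Path, title: str = "Conditional QQ") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for thr, curve in sorted(curves.items(), reverse=True):
        ax.plot(curve["expected"], curve["observed"], label=f"p ≤ {thr:g} (n={curve['n']})")
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_conjfdr_manhattan(table, path: str | Path, threshold: float = 0.05) -> None:
    """Per-variant -log10 conjFDR against genomic position, colored by chromosome."""
    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0
    ticks, labels = [], []
    for chrom, sub in table.groupby("CHR"):
        x = sub["BP"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["conjFDR"]), s=2, rasterized=True)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + 1_000_000
    ax.axhline(-np.log10(threshold), color="k", ls=":", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}$ conjFDR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overlap_summary(derived: dict, path: str | Path) -> None:
    """Venn-style bar summary of unique/shared trait-influencing variant counts."""
    fig, ax = plt.subplots(figsize=(5, 3))
    keys = ["n1_unique", "n_shared", "n2_unique"]
    vals = [derived.get(k, 0) / 1e3 for k in keys]
    ax.bar(["trait1 unique", "shared", "trait2 unique"], vals)
    ax.set_ylabel("variants (thousands)")
    ax.set_title(f"rg = {derived.get('rg', float('nan')):.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
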