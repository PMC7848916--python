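"""Karyotype plots: per-chromosome allele frequency and scaled depth.

Mirrors the standard hybrid-genome overview figure: one panel per
chromosome with per-site alternate allele frequencies (points) and the
scaled (0-1) binned depth, plus guide lines at the canonical allele
ratios 0.25, 0.33, 0.5, 0.66 and 0.75.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .variants import alt_allele_frequency

GUIDE_LINES = (0.25, 1 / 3, 0.5, 2 / 3, 0.75)


def plot_genome_overview(results, path, max_cols: int = 4) -> None:
    """Write a multi-panel AF/depth overview for a fitted strain."""
    track = results.scaled_depth_track()
    chroms = list(dict.fromkeys(track["chrom"]))
    by_chrom: dict[str, list] = {c: [] for c in chroms}
    for site in results.model.sites:
        if site.chrom in by_chrom and sum(site.ad) > 0 and site.is_snp:
            by_chrom[site.chrom].append((site.pos, alt_allele_frequency(site)))

    n = len(chroms)
    ncols = min(max_cols, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.2 * nrows), squeeze=False, sharey=True
    )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, chrom in zip(axes.flat, chroms):
        bins = track[track["chrom"] == chrom]
        mid = (bins["start"] + bins["end"]) / 2
        ax.plot(mid, bins["scaled"], color="tab:blue", lw=1.2, label="scaled depth")
        pts = by_chrom[chrom]
        if pts:
            pos, af = zip(*pts)
            ax.plot(pos, af, ".", color="tab:red", ms=2, alpha=0.5, label="alt AF")
        for g in GUIDE_LINES:
            ax.axhline(g, color="grey", lw=0.4, ls=":")
        call = results.karyotype.call_for(chrom)
        ax.set_title(f"{chrom} (c={call.copies})", fontsize=8)
        ax.set_ylim(-0.05, 1.05)
        ax.tick_params(labelsize=6)
    fig.suptitle(f"{results.sample}: AF (red) and scaled depth (blue)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_parental_frequencies(results, path) -> None:
    """Per-chromosome median parental allele frequencies with guide lines."""
    df = results.contributions_frame()
    parents = sorted(df["parent"].unique())
    fig, ax = plt.subplots(figsize=(8, 3.2))
    x = np.arange(df["chrom"].nunique())
    chroms = list(dict.fromkeys(df["chrom"]))
    offsets = {p: d for p, d in zip(parents, (-0.15, 0.15))}
    colors = {p: c for p, c in zip(parents, ("tab:orange", "tab:green"))}
    for parent in parents:
        sel = df[df["parent"] == parent].set_index("chrom").reindex(chroms)
        ax.bar(
            x + offsets[parent], sel["median_af"], width=0.3,
            color=colors[parent], label=parent,
        )
    for g in GUIDE_LINES:
        ax.axhline(g, color="grey", lw=0.5, ls=":")
    ax.set_xticks(x)
    ax.set_xticklabels(chroms, rotation=90, fontsize=6)
    ax.set_ylabel("median parental AF")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
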