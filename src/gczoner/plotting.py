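"""Figure exports: zone-dominance dot plot, composition pies, gene panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def zone_dot_plot(zones: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """Effect size vs -log10 adjusted p per (group, substage).

    Reference lines: significance at -log10(alpha) (1.3 for alpha 0.05),
    medium effect at |d| = 0.3, large at |d| = 0.5.  Flagged-dominant
    zones are drawn in red.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = np.where(zones["dominant_flag"], "crimson", "grey")
    ax.scatter(zones["cohens_d"], zones["neglog10_adj_p"], c=colors, s=30)
    for _, row in zones[zones["dominant_flag"]].iterrows():
        ax.annotate(f"{row['group']}:{row['substage']}",
                    (row["cohens_d"], row["neglog10_adj_p"]), fontsize=7)
    ax.axhline(-np.log10(alpha), ls="--", color="red", lw=1)
    ax.axvline(0.3, ls="--", color="blue", lw=1)
    ax.axvline(0.5, ls="--", color="green", lw=1)
    ax.set_xlabel("Cohen's d (in-group vs out-of-group differential score)")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def composition_pies(comp: pd.DataFrame, path: str | Path) -> None:
    """One pie of dominant-substage percentages per group."""
    groups = list(dict.fromkeys(comp["group"]))
    fig, axes = plt.subplots(1, len(groups), figsize=(3 * len(groups), 3.2))
    if len(groups) == 1:
        axes = [axes]
    for ax, g in zip(axes, groups):
        sub = comp[(comp["group"] == g) & (comp["count"] > 0)]
        ax.pie(sub["percent"], labels=sub["substage"],
               textprops={"fontsize": 7})
        ax.set_title(g, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gene_panel(
    expr: pd.DataFrame, meta: pd.DataFrame, genes: list[str], path: str | Path
) -> None:
    """Per-group log-CPM dot panels for a named gene list."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    groups = list(dict.fromkeys(meta.loc[list(expr.columns), "group"]))
    genes = [g for g in genes if g in expr.index]
    fig, axes = plt.subplots(1, max(len(genes), 1), figsize=(2.2 * max(len(genes), 1), 3))
    if len(genes) <= 1:
        axes = [axes]
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for ax, gene in zip(axes, genes):
        for i, g in enumerate(groups):
            ids = [s for s in expr.columns if meta.loc[s, "group"] == g]
            y = expr.loc[gene, ids]
            ax.scatter(i + rng.uniform(-0.15, 0.15, len(y)), y, s=12)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups, rotation=60, fontsize=7)
        ax.set_title(gene, fontsize=9)
        ax.set_ylabel("log-CPM", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
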