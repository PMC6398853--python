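"""Simple bar-chart views of cluster profiles.

Charts mirror the tabular output of :func:`crpclust.profile_clusters`: one
stacked bar per survey item showing the within-cluster response-option
proportions, and an optional side panel with outcome-category proportions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import ClusterProfile


def plot_cluster_profile(
    profile: ClusterProfile,
    path: str | Path | None = None,
    title: str | None = None,
) -> plt.Figure:
    """Stacked response-proportion bars per item, plus outcome bars if present."""
    has_outcome = profile.outcome_frequencies is not None
    fig, axes = plt.subplots(
        1, 2 if has_outcome else 1,
        figsize=(11 if has_outcome else 7, 4),
        gridspec_kw={"width_ratios": [2, 1]} if has_outcome else None,
    )
    ax0 = axes[0] if has_outcome else axes
    labels = list(profile.item_frequencies)
    vmax = max(len(f) for f in profile.item_frequencies.values())
    bottoms = np.zeros(len(labels))
    cmap = plt.get_cmap("viridis", vmax)
    for v in range(vmax):
        heights = np.array(
            [f[v] if v < len(f) else 0.0 for f in profile.item_frequencies.values()]
        )
        ax0.bar(range(len(labels)), heights, bottom=bottoms,
                color=cmap(v), label=f"option {v}")
        bottoms += heights
    ax0.set_xticks(range(len(labels)))
    ax0.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
    ax0.set_ylabel("proportion")
    ax0.legend(fontsize=7)
    ax0.set_title(title or f"cluster {profile.cluster} (n={profile.size})")
    if has_outcome:
        cats = list(profile.outcome_frequencies)
        axes[1].bar(range(len(cats)), [profile.outcome_frequencies[c] for c in cats],
                    color="tab:gray")
        axes[1].set_xticks(range(len(cats)))
        axes[1].set_xticklabels(cats, rotation=60, ha="right", fontsize=7)
        axes[1].set_title("outcome")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
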