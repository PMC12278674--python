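"""Small plotting helpers for the standard figures of a run: occupancy
distributions per condition group and the site-by-lipid-subclass
correlation heatmap.  These are descriptive views; all numbers come from
the quantification modules."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import OccupancyTable
from .enrich import CorrelationResult

__all__ = ["plot_occupancy_distributions", "plot_correlation_heatmap"]


def plot_occupancy_distributions(occ: OccupancyTable, path=None):
    """Histogram of % thiol oxidation per condition, mean annotated."""
    conds = sorted(occ.rows["condition"].unique())
    fig, axes = plt.subplots(2, max(1, (len(conds) + 1) // 2),
                             figsize=(3 * ((len(conds) + 1) // 2), 5), squeeze=False)
    for ax, cond in zip(axes.ravel(), conds):
        vals = occ.rows.loc[occ.rows["condition"] == cond, "mean_percent_oxidation"]
        ax.hist(vals, bins=40, color="#4477aa")
        ax.axvline(vals.mean(), color="k", ls="--")
        ax.set_title(f"{cond}\nmean {vals.mean():.1f}%", fontsize=9)
        ax.set_xlabel("% occupancy")
    for ax in axes.ravel()[len(conds):]:
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(corr: CorrelationResult, path=None, max_sites: int = 60):
    """Pearson r heatmap of cysteine sites vs lipid subclass trajectories."""
    piv = corr.pivot()
    if len(piv) > max_sites:
        spread = piv.abs().max(axis=1)
        piv = piv.loc[spread.nlargest(max_sites).index]
    fig, ax = plt.subplots(figsize=(0.45 * piv.shape[1] + 2, 0.12 * piv.shape[0] + 2))
    im = ax.imshow(piv.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(np.arange(piv.shape[1]), labels=piv.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(piv.shape[0]), labels=piv.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
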