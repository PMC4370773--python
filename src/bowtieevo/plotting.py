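"""Summary figures for evolved ensembles: layer-width histograms and medians."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import EnsembleSummary

__all__ = ["plot_layer_histograms", "plot_layer_medians"]


def plot_layer_histograms(summary: EnsembleSummary, title: str | None = None):
    """One histogram panel of active-node counts per node layer."""
    n_layers = summary.layer_histograms.shape[0]
    fig, axes = plt.subplots(
        1, n_layers, figsize=(2.2 * n_layers, 2.4), sharey=True
    )
    widths = np.arange(summary.layer_histograms.shape[1])
    for layer, ax in enumerate(np.atleast_1d(axes)):
        ax.bar(widths, summary.layer_histograms[layer], color="steelblue")
        ax.axvline(summary.goal_rank, color="firebrick", ls="--", lw=1)
        ax.set_xlabel("active nodes")
        ax.set_title(f"layer {layer + 1}", fontsize=9)
    np.atleast_1d(axes)[0].set_ylabel("runs")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_layer_medians(summaries: dict[str, EnsembleSummary]):
    """Median active nodes per layer, one curve per ensemble (e.g. per rank)."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    for label, summary in summaries.items():
        layers = np.arange(1, len(summary.layer_medians) + 1)
        ax.plot(layers, summary.layer_medians, "o-", label=label)
    ax.set_xlabel("node layer")
    ax.set_ylabel("median active nodes")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
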