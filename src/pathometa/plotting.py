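"""Benchmark figures: cross-validated AUC as a function of forest size."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import GridSearchResult


def plot_grid_search(result: GridSearchResult, path=None):
    """AUC-vs-trees curves, one line per (encoding, mtry) combination."""
    series: dict[tuple, list[tuple[int, float]]] = {}
    for e in result.entries:
        key = (e.encoding_kind, tuple(sorted(e.encoder_params.items())), e.rf_config.mtry)
        series.setdefault(key, []).append((e.rf_config.n_trees, e.evaluation.auc))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (kind, params, mtry), pts in sorted(series.items()):
        pts.sort()
        label = f"{kind}, mtry={mtry}"
        if params:
            label += " (" + ", ".join(f"{k}={v}" for k, v in params) + ")"
        ax.plot(*zip(*pts), marker="o", label=label)
    ax.set_xlabel("number of trees")
    ax.set_ylabel("10-fold CV AUC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
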