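"""Convenience heatmaps of sweep tables (the tables are the primary output)."""

from __future__ import annotations

import pandas as pd

__all__ = ["heatmap"]


def heatmap(table: pd.DataFrame, metric: str, ax=None):
    """Ensemble-mean heatmap of a sweep metric over the (rho, sigma) grid."""
    import matplotlib.pyplot as plt

    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    pivot = table.pivot_table(index="rho", columns="sigma", values=metric, aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        pivot.to_numpy(),
        origin="lower",
        aspect="auto",
        extent=(
            float(pivot.columns.min()),
            float(pivot.columns.max()),
            float(pivot.index.min()),
            float(pivot.index.max()),
        ),
    )
    ax.set_xlabel(r"spatial scale $\sigma$")
    ax.set_ylabel(r"density scale $\rho$")
    ax.set_title(metric)
    ax.figure.colorbar(im, ax=ax)
    return ax
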