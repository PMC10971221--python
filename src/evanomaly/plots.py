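"""Optional diagnostic plots (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .descriptives import QuadraticFit
from .distance import AnomalySet

__all__ = ["sorted_distance_bars", "logfc_distance_scatter"]


def sorted_distance_bars(anomalies: AnomalySet, path: str | Path) -> None:
    """Bar plot of distances sorted descending with the threshold line."""
    d = [r.d for r in anomalies.records]
    fig, ax = plt.subplots(figsize=(max(4, len(d) * 0.12), 3.2))
    ax.bar(range(len(d)), d, color="steelblue")
    ax.axhline(anomalies.tau, color="red", linestyle="--",
               label=f"mean + {anomalies.k:g} SD")
    ax.set_xlabel("proteins (sorted by distance)")
    ax.set_ylabel("Euclidean distance (log units)")
    ax.set_title(anomalies.comparison.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def logfc_distance_scatter(anomalies: AnomalySet, fit: QuadraticFit | None,
                           path: str | Path) -> None:
    """Scatter of distance against log fold change with the quadratic curve."""
    x = np.array([r.logFC for r in anomalies.records])
    y = np.array([r.d for r in anomalies.records])
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, s=18, color="dimgray")
    ax.axvline(0.0, color="green", linewidth=1)
    if fit is not None and len(x) >= 3:
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(grid, fit.a * grid ** 2 + fit.b * grid + fit.c,
                color="tab:blue", label=f"quadratic fit (R²={fit.r_squared:.2f})")
        ax.legend(frameon=False)
    ax.set_xlabel("log fold change")
    ax.set_ylabel("Euclidean distance (log units)")
    ax.set_title(anomalies.comparison.label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
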