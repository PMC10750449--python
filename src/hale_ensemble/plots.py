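"""Simple diagnostic plots: posterior distributions and rank heatmaps."""

from __future__ import annotations

import numpy as np

from .summaries import RankTable


def posterior_distribution_plot(country_draws, year_label: str = "", ax=None):
    """Horizontal posterior spreads of HLE at birth per country.

    ``country_draws`` maps country -> 1-D array of pooled draws.  Countries
    are ordered by posterior median, the dot marking the median.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * max(len(country_draws), 4) + 1))
    order = sorted(country_draws, key=lambda c: np.median(country_draws[c]))
    for i, c in enumerate(order):
        d = np.asarray(country_draws[c], dtype=float)
        lo, hi = np.percentile(d, [2.5, 97.5])
        ax.plot([lo, hi], [i, i], color="steelblue", lw=2, alpha=0.7)
        ax.plot(np.median(d), i, "o", color="crimson", ms=4)
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel(f"HLE at birth (years) {year_label}".strip())
    return ax


def rank_heatmap(table: RankTable, ax=None):
    """Country-by-rank probability heatmap (rank 1 = highest HLE)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(table.countries) + 1))
    im = ax.imshow(table.probabilities, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(table.countries)), table.countries)
    ax.set_xticks(range(len(table.countries)),
                  [str(r + 1) for r in range(len(table.countries))])
    ax.set_xlabel("rank (1 = highest HLE)")
    ax.figure.colorbar(im, ax=ax, label="probability")
    return ax
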