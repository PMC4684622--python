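"""Minimal plot helpers for per-probe within-pair differences."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_pair_deltas"]


def plot_pair_deltas(delta: pd.DataFrame, probes: list[str],
                     path: str | Path | None = None):
    """Per-pair delta-beta dots with the cohort mean ± SD per probe.

    One panel per probe: each dot is one twin pair's within-pair
    difference, the horizontal line is the mean across pairs with an
    error bar of one standard deviation.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(probes)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 3), sharey=True,
                             squeeze=False)
    for ax, probe in zip(axes[0], probes):
        d = delta.loc[probe].to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        x = np.arange(1, len(d) + 1)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.scatter(x, d, s=12, color="black")
        ax.errorbar([len(d) + 1], [d.mean()], yerr=[d.std(ddof=1)],
                    fmt="o", color="red", capsize=3)
        ax.set_title(probe, fontsize=8)
        ax.set_xticks([])
    axes[0][0].set_ylabel(r"within-pair $\Delta\beta$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
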