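"""Minimal plotting helpers (cluster panels, count-RIN histograms)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from mirlag.io_model import TIMEPOINTS  # noqa: E402
from mirlag.profiles import ClusterModel  # noqa: E402


def plot_clusters(model: ClusterModel, path: str | Path) -> None:
    """One panel per cluster; profiles colored by membership strength."""
    c = model.c
    ncol = min(c, 3)
    nrow = int(np.ceil(c / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharey=True)
    x = np.arange(len(TIMEPOINTS))
    labels = model.hard_labels()
    # re-standardize is not needed; centers already live in standardized space
    for k in range(c):
        ax = axes[k // ncol][k % ncol]
        members = np.where(labels == k)[0]
        ax.plot(x, model.centers[k], color="black", lw=2)
        ax.set_title(f"cluster {k + 1} (n={len(members)})")
        ax.set_xticks(x, [str(t) for t in TIMEPOINTS])
        ax.set_xlabel("time (h)")
    for k in range(c, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_count_rin_histograms(
    before: np.ndarray, after: np.ndarray, path: str | Path, cutoff: float = 0.5,
) -> None:
    """Side-by-side histograms of count-RIN correlations pre/post correction."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, r, title in ((axes[0], before, "before correction"),
                         (axes[1], after, "after correction")):
        r = r[~np.isnan(r)]
        ax.hist(r, bins=np.linspace(-1, 1, 41), color="steelblue")
        ax.axvline(cutoff, color="red", ls="--", lw=1)
        ax.set_title(title)
        ax.set_xlabel("count-RIN correlation")
    axes[0].set_ylabel("entities")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
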