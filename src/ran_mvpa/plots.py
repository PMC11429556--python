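"""Optional matplotlib views of the report bundle.

Figures mirror the analysis artifacts: the threshold-sweep accuracy curve,
per-visit cluster-averaged group distributions, and orthogonal slices of a
thresholded weight map.  All functions return the figure and never call
``show``; import of this module is the only place matplotlib is required.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_sweep(sweep_summary: pd.DataFrame):
    """Mean LOO accuracy against the Fisher-score threshold grid."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sweep_summary["threshold"], sweep_summary["mean_loo_accuracy"],
            marker="o")
    chosen = sweep_summary.loc[sweep_summary["chosen"]]
    if not chosen.empty:
        ax.axvline(float(chosen["threshold"].iloc[0]), ls="--", color="gray")
    ax.set_xlabel("Fisher score threshold")
    ax.set_ylabel("mean LOO accuracy")
    fig.tight_layout()
    return fig


def plot_group_stats(group_stats: pd.DataFrame, side: str = "selected"):
    """Cluster-averaged contrast by group and visit (mean +/- SD bars)."""
    plt = _mpl()
    df = group_stats[group_stats["side"] == side]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(df))
    w = 0.35
    ax.bar(x - w / 2, df["mean_survivor"], w, yerr=df["sd_survivor"],
           label="survivors", color="firebrick", capsize=3)
    ax.bar(x + w / 2, df["mean_control"], w, yerr=df["sd_control"],
           label="controls", color="steelblue", capsize=3)
    for i, p in enumerate(df["p_value"]):
        if p < 0.05:
            ax.annotate("*", (x[i], ax.get_ylim()[1] * 0.9),
                        ha="center", fontsize=14)
    ax.set_xticks(x, df["visit"])
    ax.set_ylabel("cluster-averaged Letter > Color")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_weight_map(weight_map: np.ndarray, min_abs_weight: float = 0.02):
    """Mid-volume orthogonal slices of a magnitude-thresholded weight map."""
    plt = _mpl()
    shown = np.where(np.abs(weight_map) >= min_abs_weight, weight_map, np.nan)
    centers = [s // 2 for s in weight_map.shape]
    vmax = np.nanmax(np.abs(shown)) if np.isfinite(shown).any() else 1.0
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    slices = [shown[centers[0], :, :], shown[:, centers[1], :],
              shown[:, :, centers[2]]]
    for ax, sl, title in zip(axes, slices, ("sagittal", "coronal", "axial")):
        im = ax.imshow(sl.T, origin="lower", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_title(title)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8, label="SVM weight")
    return fig
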