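"""Plotting conveniences: parametric-map quicklooks, ROC/PR curves,
and z-scored feature box plots.

All functions return the matplotlib figure so callers can save or show
it; nothing here is needed by the computational pipeline.
"""

from __future__ import annotations

import numpy as np

from .metrics import roc_curve_points
from .spectral import CHANNEL_DISPLAY_RANGE, QUSMaps


def plot_parametric_maps(maps: QUSMaps, figsize=(15, 3)):
    """One panel per channel, masked to the ROI, display ranges centered
    on the in-ROI median."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(maps.channels), figsize=figsize)
    extent = [
        maps.lat_center_mm[0],
        maps.lat_center_mm[-1],
        maps.ax_center_mm[-1],
        maps.ax_center_mm[0],
    ]
    for ax, (name, channel) in zip(np.atleast_1d(axes), maps.channels.items()):
        data = np.where(maps.valid_mask, channel, np.nan)
        mid = np.nanmedian(data)
        half = CHANNEL_DISPLAY_RANGE.get(name, np.nanstd(data) * 4) / 2
        im = ax.imshow(
            data, extent=extent, cmap="viridis", vmin=mid - half, vmax=mid + half
        )
        ax.set_title(name)
        ax.set_xlabel("lateral (mm)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    np.atleast_1d(axes)[0].set_ylabel("depth (mm)")
    fig.tight_layout()
    return fig


def plot_roc(results, ax=None):
    """ROC curve of the aggregated leave-one-out test scores."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr = roc_curve_points(results.y_true, results.scores)
    ax.plot(fpr, tpr, marker="o", ms=3, label=f"AUROC = {results.metrics.auroc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{results.classifier}: LOO test ROC")
    ax.legend()
    return ax.figure


def plot_feature_groups(X, y, feature_names, ax=None):
    """Box plots of z-scored features split by recurrence-risk group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(feature_names) + 2, 4))
    y = np.asarray(y).astype(int)
    positions, data, labels = [], [], []
    for i, name in enumerate(feature_names):
        vals = np.asarray(X[name], dtype=float)
        z = (vals - vals.mean()) / (vals.std() or 1.0)
        data += [z[y == 0], z[y == 1]]
        positions += [3 * i, 3 * i + 1]
        labels.append(name)
    box = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, pos in zip(box["boxes"], positions):
        patch.set_facecolor("#6699cc" if pos % 3 == 0 else "#cc6666")
    ax.set_xticks([3 * i + 0.5 for i in range(len(labels))])
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=7)
    ax.set_ylabel("z-scored value")
    return ax.figure
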