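"""Matplotlib views of connectivity matrices and cohort metrics."""

from __future__ import annotations

import numpy as np


def plot_sl_matrix(values: np.ndarray, ax=None, title: str = "",
                   cmap: str = "viridis"):
    """Heat map of an SL or SL_MAD matrix (channels ordered as recorded)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(values, cmap=cmap, vmin=0.0)
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="SL")
    return ax


def plot_group_metrics(metrics, measure: str = "SL_MEAN", ax=None):
    """Group means with SD bars, one line per condition."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    groups = sorted(metrics["group"].unique())
    x = np.arange(len(groups))
    for offset, condition in ((-0.05, "rest"), (0.05, "prehension")):
        sub = metrics[metrics["condition"] == condition]
        means = [sub.loc[sub["group"] == g, measure].mean() for g in groups]
        sds = [sub.loc[sub["group"] == g, measure].std() for g in groups]
        ax.errorbar(x + offset, means, yerr=sds, marker="o", capsize=3,
                    label=condition)
    ax.set_xticks(x, groups)
    ax.set_ylabel(measure)
    ax.set_xlabel("group")
    ax.legend()
    return ax


def plot_sensor_layout(arr, ax=None):
    """Top view of the sensor cap (x/y positions, mm)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(arr.position[:, 0], arr.position[:, 1], s=20)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax
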