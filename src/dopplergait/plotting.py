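"""Accuracy-vs-threshold plots for sweep results."""

from __future__ import annotations

import pandas as pd

_RATES = {"apathy_c": "Apathy-C", "apathy_m": "Apathy-M", "nonapathy_c": "Non-Apathy-C", "nonapathy_m": "Non-Apathy-M"}


def plot_sweep(df: pd.DataFrame, model: str, channel: str, ax=None):
    """Plot the four per-class rates against the binarization threshold for
    one model on one channel, mirroring the standard threshold-sweep figure.
    """
    import matplotlib.pyplot as plt

    sub = df[(df["model"] == model) & (df["channel"] == channel)].sort_values("threshold")
    if sub.empty:
        raise ValueError(f"no sweep rows for model={model!r}, channel={channel!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col, label in _RATES.items():
        ax.plot(sub["threshold"], sub[col], marker="o", markersize=3, label=label)
    ax.plot(sub["threshold"], sub["total_accuracy"], color="black", lw=2, label="total accuracy")
    ax.set_xlabel("binarization threshold")
    ax.set_ylabel("rate (fraction of test set)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"{model} — {channel} channel")
    ax.legend(fontsize=8)
    return ax
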