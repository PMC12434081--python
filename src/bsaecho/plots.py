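"""Basic figures: Bland–Altman agreement plots and violin summaries."""

from __future__ import annotations

import numpy as np

from .comparison import bland_altman


def bland_altman_plot(pred, ref, ax=None, label: str | None = None):
    """Difference-vs-mean scatter with mean difference and 1.96·SD limits."""
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ba = bland_altman(pred, ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((pred + ref) / 2, pred - ref, s=12, alpha=0.6)
    ax.axhline(ba.mean_diff, color="k", lw=1.2)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of methods (m²)")
    ax.set_ylabel("difference (m²)")
    if label:
        ax.set_title(label)
    return ax


def violin_summary(values_by_method: dict, ax=None, ylabel: str = "BSA (m²)"):
    """Violin plot of per-method value distributions, in registry order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = list(values_by_method)
    ax.violinplot([np.asarray(values_by_method[m]) for m in labels], showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    return ax
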