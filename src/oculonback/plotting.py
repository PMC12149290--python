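"""Figure helpers for encoding fits, population activity and decoding curves."""

from __future__ import annotations

import numpy as np


def plot_population_heatmap(pop: dict, centers=None, ax=None, cmap="viridis"):
    """Heatmap of sorted per-neuron activity with the population mean below.

    ``pop`` is the dict returned by
    :func:`~oculonback.spikes.population_average`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, height_ratios=[3, 1])
    hm, mean, sem = pop["heatmap"], pop["mean"], pop["sem"]
    x = centers if centers is not None else np.arange(hm.shape[1])
    ax[0].imshow(hm, aspect="auto", cmap=cmap,
                 extent=[x[0], x[-1], hm.shape[0], 0])
    ax[0].set_ylabel("neuron (sorted by peak)")
    ax[1].plot(x, mean, color="k")
    ax[1].fill_between(x, mean - sem, mean + sem, alpha=0.3, color="k")
    if "baseline" in pop:
        ax[1].axhline(pop["baseline"], ls="--", color="gray", lw=0.8)
    ax[1].set_xlabel("time from alignment (ms)")
    ax[1].set_ylabel("z")
    return ax


def plot_accuracy_curve(curve, ax=None, label=None, chance=0.5):
    """Decoding accuracy (mean +/- SEM) against population size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = curve["n_neurons"]
    m = curve["accuracy_mean"]
    s = curve["accuracy_sem"]
    ax.plot(n, m, marker="o", label=label)
    ax.fill_between(n, m - s, m + s, alpha=0.3)
    ax.axhline(chance, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("number of neurons")
    ax.set_ylabel("decoding accuracy")
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax


def plot_betas(results, ax=None):
    """Bar plot of the 18 encoding-model coefficients with Wald SEs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    params = results.params
    ax.bar(range(len(params)), params.to_numpy(), yerr=results.bse.to_numpy(),
           color="steelblue")
    ax.set_xticks(range(len(params)))
    ax.set_xticklabels(params.index, rotation=90, fontsize=7)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("beta")
    return ax
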