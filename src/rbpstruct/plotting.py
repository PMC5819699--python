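"""Diagnostic plots for the pipeline's main distributions and contrasts."""

from __future__ import annotations

import numpy as np

from .kmers import KmerOccurrenceStats


def plot_sd_distribution(kstats: KmerOccurrenceStats, ax=None, bins: int = 40,
                         label: str | None = None):
    """Histogram of per-k-mer occurrence SDs of mean pairing probability,
    with the median marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sds = kstats.defined_sds()
    ax.hist(sds, bins=bins, density=True, alpha=0.6, label=label)
    ax.axvline(np.median(sds), linestyle="--", color="k")
    ax.set_xlabel(f"SD of mean {kstats.k}-mer pairing probability")
    ax.set_ylabel("density")
    if label:
        ax.legend()
    return ax


def plot_paired_metrics(metrics_a, metrics_b, label_a: str = "sequence only",
                        label_b: str = "sequence + structure", ax=None):
    """Per-experiment scatter of one metric against another (e.g. Pearson r
    or AUC), with the diagonal for reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    ax.scatter(a, b, s=12, alpha=0.7)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=0.8)
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    return ax


def plot_context_profile(profile, ax=None):
    """Stacked per-position context probabilities (S, H, I, M, E)."""
    import matplotlib.pyplot as plt

    from .structure import CONTEXTS

    if ax is None:
        _, ax = plt.subplots()
    profile = np.asarray(profile, dtype=float)
    x = np.arange(1, len(profile) + 1)
    bottom = np.zeros(len(profile))
    for i, name in enumerate(CONTEXTS):
        ax.bar(x, profile[:, i], bottom=bottom, width=1.0, label=name)
        bottom += profile[:, i]
    ax.set_xlabel("position")
    ax.set_ylabel("context probability")
    ax.legend(ncol=5, fontsize="small")
    return ax
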