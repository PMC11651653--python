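"""Plotting helpers (all optional to the analysis path)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_psychometric", "plot_cluster_profiles", "plot_decoding_timecourse", "tsne_pairs"]


def plot_psychometric(summary, ax=None):
    """d' vs sound-level bin for one session."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    pb = summary.per_bin
    centers = 0.5 * (pb["bin_lo"] + pb["bin_hi"])
    ax.plot(centers, pb["dprime"], "o-")
    ax.axhline(1.5, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("sound level (dB SPL)")
    ax.set_ylabel("d'")
    return ax


def plot_cluster_profiles(model, averages_hit, averages_miss, L=193, axes=None):
    """Mean hit (red) and miss (blue) trace per cluster."""
    import matplotlib.pyplot as plt

    clusters = np.unique(model.labels)
    if axes is None:
        _, axes = plt.subplots(1, clusters.size, figsize=(3 * clusters.size, 2.5), squeeze=False)
        axes = axes[0]
    t = np.linspace(-2, 5, L)
    for ax, c in zip(axes, clusters):
        in_c = model.labels == c
        ax.plot(t, averages_hit[in_c].mean(axis=0), c="crimson", label="hit")
        ax.plot(t, averages_miss[in_c].mean(axis=0), c="steelblue", label="miss")
        ax.axvline(0, ls=":", c="k", lw=0.6)
        ax.set_title(f"cluster {c} (n={in_c.sum()})")
    axes[0].legend(frameon=False)
    return axes


def plot_decoding_timecourse(results, comparison=None, ax=None):
    """Mean trained and dummy accuracy across sessions, with significance dots."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    trained = np.vstack([r.trained for r in results])
    dummy = np.vstack([r.dummy for r in results])
    t = results[0].frame_times
    ax.plot(t, trained.mean(axis=0), label="trained")
    ax.plot(t, dummy.mean(axis=0), label="dummy", c="grey")
    if comparison is not None:
        sig = comparison.significant_times
        ax.plot(sig, np.full(sig.size, trained.max() + 0.02), ".", c="k", ms=3)
    ax.axvline(0, ls=":", c="k", lw=0.6)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("balanced accuracy")
    ax.legend(frameon=False)
    return ax


def tsne_pairs(scores, labels, perplexity=30.0, seed=0, ax=None):
    """t-SNE embedding of the PCA scores coloured by cluster (inspection only)."""
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    emb = TSNE(
        n_components=2, perplexity=min(perplexity, (scores.shape[0] - 1) / 3), random_state=seed
    ).fit_transform(scores)
    ax = ax or plt.gca()
    ax.scatter(emb[:, 0], emb[:, 1], c=labels, cmap="tab10", s=8)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
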