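"""Diagnostic plots: feature densities, templates, detection overlays."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from selsort.features import FeatureMatrix, feature_pdf
from selsort.overlap import TemplateSet


def plot_feature_densities(fm: FeatureMatrix, path) -> None:
    """One panel per selected feature: kernel density with mode count.

    Multimodal densities visually confirm that a feature separates spike
    classes."""
    curves = feature_pdf(fm)
    n = len(curves)
    ncol = min(5, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False)
    for k, c in enumerate(curves):
        ax = axes[k // ncol][k % ncol]
        ax.plot(c.grid, c.density, lw=1)
        ax.set_title(
            f"coeff {fm.coeff_ids[k]} (KS {fm.ks_scores[k]:.2f}, "
            f"{c.n_modes} mode{'s' if c.n_modes != 1 else ''})",
            fontsize=8,
        )
        ax.tick_params(labelsize=7)
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_templates(tset: TemplateSet, path) -> None:
    """Putative templates on the lag axis, one line per neuron."""
    fig, ax = plt.subplots(figsize=(5, 3))
    lags = np.arange(-tset.lag, tset.lag + 1)
    for n, w in enumerate(tset.templates):
        ax.plot(lags, w, lw=1.2, label=f"neuron {n + 1}")
    ax.set_xlabel("lag (samples)")
    ax.set_ylabel("amplitude")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_detection(rec_samples, events, path, span=24000) -> None:
    """First ``span`` samples of the trace with detected events marked."""
    x = np.asarray(rec_samples)[:span]
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(x, lw=0.5, color="0.3")
    ev = np.asarray(events)
    ev = ev[ev < span]
    ax.plot(ev, x[ev], "r*", ms=6)
    ax.set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
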