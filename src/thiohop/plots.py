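"""Figure output: population kinetics, manifold decay, hop-geometry
statistics and coherence heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_populations(series, fit=None, path=None):
    """State populations vs time, optionally overlaid with a kinetic fit."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lb in series.labels:
        ax.plot(series.times, series.data[lb], lw=2.5, alpha=0.5, label=lb)
    if fit is not None and fit.model_populations is not None:
        mp = fit.model_populations
        for lb in mp.labels:
            ax.plot(mp.times, mp.data[lb], lw=1.0)
    ax.set_xlabel("time (fs)")
    ax.set_ylabel("population")
    ax.set_ylim(0, 1)
    ax.legend(ncol=3, fontsize=8)
    return _finish(fig, path)


def plot_manifold_fit(series, manifolds, exp_fit=None, kin_fit=None, path=None):
    """Summed manifold populations with exponential / kinetic-model fits."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = series.times
    for name, labels in manifolds.items():
        ax.plot(t, series.manifold_sum(labels), lw=2.5, alpha=0.5, label=name)
    if exp_fit is not None and exp_fit.converged:
        ax.plot(t, np.exp(-t / exp_fit.tau), "k--", lw=1.2,
                label=f"exp fit, tau={exp_fit.tau:.0f} fs")
    if kin_fit is not None and kin_fit.model_populations is not None:
        mp = kin_fit.model_populations
        for name, labels in manifolds.items():
            present = [lb for lb in labels if lb in mp.labels]
            ax.plot(mp.times, mp.data[present].sum(axis=1), lw=1.0)
    ax.set_xlabel("time (fs)")
    ax.set_ylabel("manifold population")
    ax.legend(fontsize=8)
    return _finish(fig, path)


def plot_hop_stats(stats_list, path=None):
    """Per-mode mu +/- sigma dot plots, one panel per transition."""
    stats_list = [s for s in stats_list if not s.empty]
    n = max(len(stats_list), 1)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.6), squeeze=False)
    for ax, st in zip(axes[0], stats_list):
        ax.errorbar(st.mode_indices, st.mu, yerr=st.sigma, fmt="o", ms=4,
                    capsize=3)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_title(f"{st.transition[0]}->{st.transition[1]} (n={st.n_hops})",
                     fontsize=9)
        ax.set_xlabel("mode")
        ax.set_ylabel(r"projection $p_i$ ($\AA$)")
    return _finish(fig, path)


def plot_coherence(cs, mode_pos, path=None):
    """Binned trajectory density vs time with signed/unsigned mean overlays."""
    fig, ax = plt.subplots(figsize=(7, 3.6))
    if cs.density is not None:
        extent = [cs.times[0], cs.times[-1], cs.bin_edges[0], cs.bin_edges[-1]]
        ax.imshow(cs.density[mode_pos].T, origin="lower", aspect="auto",
                  extent=extent, cmap="Blues")
    ax.plot(cs.times, cs.signed_mean[:, mode_pos], color="orange", lw=1.5,
            label="signed mean")
    ax.plot(cs.times, cs.unsigned_mean[:, mode_pos], color="black", lw=1.5,
            label="unsigned mean")
    ax.set_xlabel("time (fs)")
    ax.set_ylabel(rf"$p_{{{cs.mode_indices[mode_pos]}}}$ ($\AA$)")
    ax.legend(fontsize=8)
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
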