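"""Static figure export (no interactive GUI).

Matplotlib renderings of the pipeline artefacts: an epoch's IMF stack,
the Hilbert spectrogram, per-phase HHT_IF trend dots with IQR bars, and
the BIS ~ HHT_IF regression with its 68% credible band.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import gpr_model

__all__ = [
    "plot_imfs",
    "plot_spectrogram",
    "plot_trends",
    "plot_gpr",
    "save_report_figures",
]


def plot_imfs(epoch, imfset, path=None):
    """Stacked plot: the epoch on top, each IMF below, residual last."""
    n = imfset.n_imfs
    fig, axes = plt.subplots(n + 2, 1, figsize=(8, 1.2 * (n + 2)),
                             sharex=True)
    t = epoch.times - epoch.t0
    axes[0].plot(t, epoch.samples, lw=0.5, color="k")
    axes[0].set_ylabel("EEG")
    for k, imf in enumerate(imfset.imfs):
        axes[k + 1].plot(t, imf, lw=0.5)
        axes[k + 1].set_ylabel(f"IMF{k + 1}")
    axes[-1].plot(t, imfset.residual, lw=0.8, color="gray")
    axes[-1].set_ylabel("res.")
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_spectrogram(spectrum, path=None, f_max=40.0):
    fig, ax = plt.subplots(figsize=(6, 4))
    sel = spectrum.freq_centers <= f_max
    pw = spectrum.power[sel]
    ax.pcolormesh(spectrum.time_edges, spectrum.freq_edges[:len(pw) + 1],
                  np.log10(pw + 1e-12), shading="auto", cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trends(summaries, path=None, variables=None):
    """Per-phase median +/- IQR of each IMF's HHT_IF over epoch time."""
    variables = variables or [f"hht_if{k}" for k in range(1, 7)]
    phases = ("induction", "maintenance", "emergence")
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, phase in zip(axes, phases):
        sub = summaries[summaries["phase"] == phase]
        for var in variables:
            g = sub.groupby("epoch_start_s")[var]
            med = g.median()
            q1, q3 = g.quantile(0.25), g.quantile(0.75)
            t = med.index - med.index.min()
            ax.errorbar(t, med, yerr=[med - q1, q3 - med], fmt="o", ms=2,
                        lw=0.5, label=var)
        ax.axhspan(8, 12, color="lightblue", alpha=0.4)
        ax.set_title(phase)
        ax.set_xlabel("time in phase (s)")
    axes[0].set_ylabel("HHT_IF (Hz)")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gpr(fit, path=None, test_sets=None):
    """Training cloud, posterior mean and 68% band; optional test panels."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(fit.x_train, fit.y_train, ".", ms=2, alpha=0.3, color="gray")
    grid = np.linspace(fit.x_train.min(), fit.x_train.max(), 300)
    mean, sd, lo, hi = gpr_model.predict(fit, grid)
    ax.plot(grid, mean, color="C0")
    ax.fill_between(grid, lo, hi, color="C0", alpha=0.3)
    ax.set_xlabel("HHT_IF (Hz)")
    ax.set_ylabel("BIS")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def save_report_figures(report, out_dir):
    out_dir = Path(out_dir)
    plot_trends(report.summaries, out_dir / "hht_if_trends.png")
    if report.gpr_fit is not None:
        plot_gpr(report.gpr_fit, out_dir / "gpr_fit.png")
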