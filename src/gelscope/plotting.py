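"""Minimal matplotlib views of the pipeline outputs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_anchor_profile(profile, quantities=None, ax=None):
    """Mean +/- 95% CI per step for the chosen quantities."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    means = profile.matrix("mean")
    lo = profile.matrix("ci_low")
    hi = profile.matrix("ci_high")
    for q in quantities or means.columns:
        ax.plot(means.index, means[q], label=str(q))
        ax.fill_between(means.index, lo[q], hi[q], alpha=0.25)
    ax.axvline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("step (px from object boundary)")
    ax.set_ylabel(f"mean counts ({profile.transform})")
    ax.legend(fontsize=7)
    return ax


def plot_peak_heatmap(peaks, ax=None):
    """Z-normalised step x channel heatmap with peak markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    z = peaks.z
    im = ax.imshow(
        z.T.to_numpy(),
        aspect="auto",
        extent=(z.index.min(), z.index.max(), len(z.columns), 0),
        cmap="viridis",
    )
    for i, q in enumerate(z.columns):
        ax.plot([peaks.peaks[q]], [i + 0.5], "w|", markersize=10)
    ax.set_yticks(np.arange(len(z.columns)) + 0.5)
    ax.set_yticklabels(z.columns, fontsize=7)
    ax.set_xlabel("step (px)")
    plt.colorbar(im, ax=ax, label="z-score")
    return ax


def plot_distortion_curve(curve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = curve.bin_centers_um
    ax.plot(x, curve.rms_um, color="k")
    if curve.sd_um is not None:
        ax.fill_between(
            x,
            curve.rms_um - curve.sd_um,
            curve.rms_um + curve.sd_um,
            color="gray",
            alpha=0.4,
        )
    ax.set_xlabel("measurement length (um)")
    ax.set_ylabel("RMS distance change (um)")
    return ax


def plot_window_profile(windows, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in windows.table["channel"].unique():
        sub = windows.channel(c)
        ax.plot(sub["center_px"], sub["mean"], label=str(c))
        ax.fill_between(sub["center_px"], sub["ci_low"], sub["ci_high"], alpha=0.25)
    ax.set_xlabel("position along long axis (px)")
    ax.set_ylabel("normalized mean")
    ax.legend(fontsize=7)
    return ax
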