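"""Matplotlib figure writers for the command-line tools.

Every figure written by the CLI has a CSV twin produced alongside it; these
functions only render, they never compute results.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import scipy.cluster.hierarchy as sch

from .intensity import AggregateStats, WilsonFit, rolling_average
from .orientation import AXIS_LABELS

__all__ = [
    "plot_dendrograms",
    "plot_orientation_maps",
    "plot_intensity_stats",
    "plot_frame_intensity",
    "plot_overview",
]


def _draw_dendrogram(ax, dend, threshold, log_axis=False):
    n = dend.n_leaves
    sch.dendrogram(
        dend.merges,
        ax=ax,
        color_threshold=threshold,
        no_labels=n > 40,
        labels=[str(x) for x in dend.leaves] if n <= 40 else None,
    )
    ax.axhline(threshold, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("distance ($\\mathrm{\\AA}^2$)")
    if log_axis:
        ax.set_yscale("symlog", linthresh=1.0)
    ax.set_xlabel("frames")


def plot_dendrograms(dend, threshold, path_linear, path_log):
    """Dendrogram with linear and symlog height axes (two files)."""
    for path, log_axis in ((path_linear, False), (path_log, True)):
        fig, ax = plt.subplots(figsize=(10, 4))
        _draw_dendrogram(ax, dend, threshold, log_axis=log_axis)
        ax.set_title(
            f"single-linkage unit-cell clustering (cut at {threshold:g} $\\mathrm{{\\AA}}^2$)"
        )
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def plot_orientation_maps(projections, densities, path):
    """Three-panel equirectangular map (a top, b middle, c bottom): vMF
    density color map with the projected axis directions overlaid.

    ``densities`` maps axis label -> (lat, lon, density).
    """
    fig, axes = plt.subplots(3, 1, figsize=(9, 10), sharex=True)
    for ax, label in zip(axes, AXIS_LABELS):
        lat, lon, dens = densities[label]
        mesh = ax.pcolormesh(lon, lat, dens, shading="nearest", cmap="viridis")
        pts = [p for p in projections if p.axis == label]
        ax.plot(
            [p.longitude for p in pts],
            [p.latitude for p in pts],
            ".", color="yellow", markersize=3, alpha=0.7,
        )
        ax.set_ylabel(f"{label} axis\nlatitude (deg)")
        ax.set_xlim(-180, 180)
        ax.set_ylim(-90, 90)
        fig.colorbar(mesh, ax=ax, label="density (sr$^{-1}$)")
    axes[-1].set_xlabel("longitude (deg)  [(0, 0) = along the beam]")
    fig.suptitle("lab-frame real-axis orientations")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_intensity_stats(agg: AggregateStats, path, window: int = 50):
    """Pseudo-Wilson super-plot with per-frame fit marginals: pooled
    (s^2, ln I) cloud + rolling average + pooled OLS line, slope/intercept
    scatter, and gradient / standard-error histograms."""
    fig = plt.figure(figsize=(12, 8))
    gs = fig.add_gridspec(2, 3, width_ratios=[1, 1, 2.2])
    ax_scatter = fig.add_subplot(gs[0, 0])
    ax_hist_g = fig.add_subplot(gs[0, 1])
    ax_hist_se = fig.add_subplot(gs[1, 0])
    ax_hist_sei = fig.add_subplot(gs[1, 1])
    ax_main = fig.add_subplot(gs[:, 2])

    ax_scatter.plot(agg.fits["slope"], agg.fits["intercept"], ".", markersize=3)
    ax_scatter.set_xlabel("gradient $-2B$ ($\\mathrm{\\AA}^2$)")
    ax_scatter.set_ylabel("intercept $\\ln G$")

    for ax, key, label in (
        (ax_hist_g, "gradient", "gradient $-2B$ ($\\mathrm{\\AA}^2$)"),
        (ax_hist_se, "se_slope", "SE(gradient)"),
        (ax_hist_sei, "se_intercept", "SE(intercept)"),
    ):
        counts, edges = agg.histograms[key]
        ax.stairs(counts, edges, fill=True)
        ax.set_xlabel(label)
        ax.set_ylabel("frames")

    x = agg.pooled["s2"].to_numpy()
    y = agg.pooled["log_i"].to_numpy()
    ax_main.plot(x, y, ".", markersize=1, alpha=0.25, label="partial reflections")
    if x.size >= window:
        rx, ry = rolling_average(x, y, window=window)
        ax_main.plot(rx, ry, "-", color="orange", linewidth=2, label=f"rolling mean ({window})")
    xx = np.linspace(x.min(), x.max(), 50)
    ax_main.plot(
        xx, agg.pooled_intercept + agg.pooled_slope * xx, "r-", linewidth=1.5,
        label=f"pooled fit (slope {agg.pooled_slope:.1f})",
    )
    ax_main.set_xlabel("$(\\sin\\theta/\\lambda)^2$ ($\\mathrm{\\AA}^{-2}$)")
    ax_main.set_ylabel("$\\ln I_\\mathrm{partial}$")
    ax_main.legend(loc="upper right", fontsize=8)
    fig.suptitle("pseudo-Wilson intensity statistics")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_frame_intensity(x, y, fit: WilsonFit, path, window: int = 50):
    """Per-frame pseudo-Wilson plot: points, fitted line, rolling average."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(x, y, ".", markersize=3, label="reflections")
    if x.size >= window:
        rx, ry = rolling_average(x, y, window=window)
        ax.plot(rx, ry, "-", color="orange", label=f"rolling mean ({window})")
    xx = np.linspace(x.min(), x.max(), 50)
    ax.plot(xx, fit.intercept + fit.slope * xx, "r-", label=f"fit: B={fit.b_factor:.1f}")
    ax.set_xlabel("$(\\sin\\theta/\\lambda)^2$ ($\\mathrm{\\AA}^{-2}$)")
    ax.set_ylabel("$\\ln I_\\mathrm{partial}$")
    ax.set_title(f"frame {fit.frame_id}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overview(dend, threshold, projections, densities, agg, path):
    """One-figure dataset overview: dendrogram, orientation maps, intensity
    histograms."""
    fig = plt.figure(figsize=(14, 10))
    gs = fig.add_gridspec(3, 3)
    ax_dend = fig.add_subplot(gs[0, :])
    _draw_dendrogram(ax_dend, dend, threshold)
    axes_orient = [fig.add_subplot(gs[1, i]) for i in range(3)]
    for ax, label in zip(axes_orient, AXIS_LABELS):
        lat, lon, dens = densities[label]
        ax.pcolormesh(lon, lat, dens, shading="nearest", cmap="viridis")
        pts = [p for p in projections if p.axis == label]
        ax.plot(
            [p.longitude for p in pts], [p.latitude for p in pts],
            ".", color="yellow", markersize=2, alpha=0.6,
        )
        ax.set_title(f"{label} axis")
        ax.set_xlim(-180, 180)
        ax.set_ylim(-90, 90)
    ax_b = fig.add_subplot(gs[2, 0])
    counts, edges = agg.histograms["gradient"]
    ax_b.stairs(counts, edges, fill=True)
    ax_b.set_xlabel("gradient $-2B$ ($\\mathrm{\\AA}^2$)")
    ax_b.set_ylabel("frames")
    ax_se = fig.add_subplot(gs[2, 1])
    counts, edges = agg.histograms["se_slope"]
    ax_se.stairs(counts, edges, fill=True)
    ax_se.set_xlabel("SE(gradient)")
    ax_g = fig.add_subplot(gs[2, 2])
    ax_g.plot(agg.fits["slope"], agg.fits["intercept"], ".", markersize=3)
    ax_g.set_xlabel("gradient $-2B$ ($\\mathrm{\\AA}^2$)")
    ax_g.set_ylabel("intercept $\\ln G$")
    fig.suptitle("dataset overview: unit cells / orientations / intensities")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
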