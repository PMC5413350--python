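"""Diagnostic plots: window curves with learned thresholds, MA-style
dotplots of fold change vs mean expression with significant genes
highlighted, and GC-content histograms by organism."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_window_curve(detection, ax=None, log: bool = True):
    """Scatter of window companion statistic vs reference median, with the
    learned threshold as a dashed vertical line."""
    curve = detection.curve
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = curve.ref_median
    y = curve.companion
    ax.scatter(x, y, s=4, alpha=0.5, color="0.3")
    if np.isfinite(detection.value):
        ax.axvline(detection.value, color="red", linestyle="--")
    if log and (x > 0).any():
        ax.set_xscale("log")
        if curve.mode == "median" and (y > 0).any():
            ax.set_yscale("log")
    ax.set_xlabel("reference window median FPKM")
    ax.set_ylabel(
        "companion window median FPKM"
        if curve.mode == "median"
        else "detected proportion"
    )
    return ax


def plot_ma(results, alpha: float = 0.05, fc_lines=(1.0,), ax=None):
    """log2FC vs rank of mean abundance; FDR-significant genes in red."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    tab = results.table
    x = np.arange(len(tab))
    sig = tab["fdr"] < alpha
    ax.scatter(x[~sig], tab["log2_fold_change"][~sig], s=4, color="0.6")
    ax.scatter(x[sig], tab["log2_fold_change"][sig], s=6, color="red")
    for fc in fc_lines:
        ax.axhline(fc, color="blue", linestyle=":", linewidth=0.8)
        ax.axhline(-fc, color="blue", linestyle=":", linewidth=0.8)
    ax.set_xlabel("gene index")
    ax.set_ylabel("log2 fold change")
    return ax


def plot_gc_distributions(catalog, ax=None):
    """Overlaid GC histograms per organism with median markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for organism, grp in catalog.groupby("organism"):
        gc = grp["gc_fraction"]
        ax.hist(gc, bins=40, alpha=0.45, label=f"{organism} (median {gc.median():.2f})")
        ax.axvline(gc.median(), linestyle="--", linewidth=0.8)
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("transcripts")
    ax.legend(fontsize=7)
    return ax
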