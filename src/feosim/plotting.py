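"""Raster actograms and smoothed activity waveforms (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .analysis import ActivityRecord, ActogramRaster

__all__ = ["plot_actogram", "plot_waveform"]


def plot_actogram(raster: ActogramRaster, ax=None, title: str = ""):
    """Render a raster actogram: days stacked vertically, one vertical bar
    per time bin, bar height proportional to the quintile rank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.18 * raster.rows.shape[0])))
    n_days, n_bins = raster.rows.shape
    bw_h = raster.bin_width / 60.0
    t = np.arange(n_bins) * bw_h
    for d in range(n_days):
        heights = raster.rows[d] / 5.0 * 0.9
        nz = heights > 0
        ax.bar(
            t[nz],
            heights[nz],
            width=bw_h,
            bottom=n_days - 1 - d,
            align="edge",
            color="black",
            linewidth=0,
        )
    span = raster.day_length * (2 if raster.double_plotted else 1)
    ax.set_xlim(0, span)
    ax.set_ylim(0, n_days)
    ax.set_xlabel(f"Time (h, modulo {raster.day_length:g} h)")
    ax.set_ylabel("Day")
    ax.set_yticks(np.arange(0, n_days, max(1, n_days // 10)) + 0.5)
    ax.set_yticklabels(n_days - np.arange(0, n_days, max(1, n_days // 10)))
    if title:
        ax.set_title(title)
    return ax


def plot_waveform(record: ActivityRecord, ax=None, mealtimes=None, title: str = ""):
    """Line plot of a (typically smoothed or folded) activity record, with
    optional vertical mealtime markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(record.centers, record.counts, color="black", lw=1)
    if mealtimes is not None:
        for m in mealtimes:
            ax.axvline(m, color="green", lw=2, alpha=0.5)
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Activity / bin")
    if title:
        ax.set_title(title)
    return ax
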