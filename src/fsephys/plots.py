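"""Minimal summary figures for study outputs (not publication replicas)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_ppr_curves", "plot_bootstrap_means", "plot_sweep"]


def plot_sweep(sweep, ax=None):
    """Voltage or current trace against time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(sweep.time_ms(), sweep.samples, lw=0.6, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("mV" if sweep.modality == "current_clamp" else "pA")
    ax.set_title(sweep.sweep_id)
    return ax


def plot_ppr_curves(ppr_table: pd.DataFrame, units: str = "current", ax=None):
    """Group mean +/- SEM paired-pulse ratio against interstimulus
    interval (log axis), one line per genotype."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    sub = ppr_table[ppr_table.units == units]
    for geno, d in sub.groupby("genotype"):
        g = d.groupby("delta_t_ms")["ppr"]
        m, s = g.mean(), g.sem()
        ax.errorbar(m.index, m, yerr=s, marker="o", capsize=3, label=geno)
    ax.set_xscale("log")
    ax.set_xlabel(r"$\Delta t$ (ms)")
    ax.set_ylabel(f"PPR ({units})")
    ax.axhline(1.0, color="0.7", lw=0.8, ls="--")
    ax.legend(frameon=False)
    return ax


def plot_bootstrap_means(boot: dict, metric: str, ax=None, bins=30):
    """Overlaid histograms of bootstrapped group means for one metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    for geno, values in boot[metric].items():
        ax.hist(np.asarray(values), bins=bins, alpha=0.5, density=True,
                label=geno)
    ax.set_xlabel(metric)
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    return ax
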