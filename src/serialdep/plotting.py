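"""Diagnostic figures: moving-average curves with DoG overlays and
model-free bias summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .serial import ConditionedSeries, dog_value, fit_dog, moving_average

__all__ = ["plot_transition_curves", "plot_bias_summary"]

_TRANSITIONS = ("LL", "HH", "LH", "HL")


def plot_transition_curves(
    series_stimulus: ConditionedSeries,
    series_response: ConditionedSeries,
    window_deg: int,
    path,
) -> None:
    """4×2 grid of pooled moving averages (black) with DoG fits (red):
    one column of transitions per conditioning mode."""
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharex=True, sharey=True)
    for row, series in enumerate((series_stimulus, series_response)):
        for col, trans in enumerate(_TRANSITIONS):
            ax = axes[row, col]
            curve = moving_average(series.for_transition(trans), window_deg)
            fit = fit_dog(curve)
            ax.axhline(0, color="0.8", lw=0.8)
            ax.plot(curve["delta_deg"], curve["mean_error_deg"], "k-", lw=1)
            x = np.linspace(-89, 89, 300)
            ax.plot(x, dog_value(x, fit.a, fit.w, fit.b), "r-", lw=1.2)
            ax.set_title(f"{trans}  a={fit.a:.2f}°", fontsize=9)
            if col == 0:
                ax.set_ylabel(
                    ("stimulus" if row == 0 else "response") + "-contingent\nerror (°)"
                )
            if row == 1:
                ax.set_xlabel("difference from previous (°)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bias_summary(bias: pd.DataFrame, path) -> None:
    """Mean model-free bias per transition cell with 95% CIs, one panel
    per conditioning mode."""
    modes = list(bias["mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(5 * len(modes), 4), squeeze=False)
    order = [("low", "low"), ("high", "high"), ("low", "high"), ("high", "low")]
    labels = ["L→L", "H→H", "L→H", "H→L"]
    for ax, mode in zip(axes[0], modes):
        sub = bias[bias["mode"] == mode]
        means, cis = [], []
        for prev, cur in order:
            vals = sub.loc[
                (sub["previous_noise"] == prev) & (sub["current_noise"] == cur),
                "bias_deg",
            ].dropna()
            means.append(vals.mean())
            cis.append(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0)
        ax.bar(labels, means, yerr=cis, capsize=4, color="0.6")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_title(mode.replace("_", "-"))
        ax.set_ylabel("bias (°)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
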