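"""Figure-analogue plots for the bias and diagnostics tables.

Each function takes the tidy data frame produced by the corresponding
experiment and returns a matplotlib figure; nothing is shown or saved
here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_bias", "plot_profiles", "plot_exclusion"]


def plot_bias(df: pd.DataFrame) -> "plt.Figure":
    """Realized vs. fitted learning rates (top) and fitted inverse
    temperatures (bottom), one column per task."""
    tasks = list(dict.fromkeys(df["task"]))
    fig, axes = plt.subplots(2, len(tasks), figsize=(5 * len(tasks), 7), squeeze=False)
    for j, task in enumerate(tasks):
        sub = df[df["task"] == task]
        beta0 = sorted(sub["beta_gen"].unique())[0]
        fx = sub[(sub["model"] == "fixed_lr") & (sub["beta_gen"] == beta0)]
        ax = axes[0][j]
        ax.errorbar(
            fx["lam"],
            fx["median_realized_alpha"],
            yerr=[
                fx["median_realized_alpha"] - fx["iqr_lo"],
                fx["iqr_hi"] - fx["median_realized_alpha"],
            ],
            fmt="ko-",
            label="realized (median, IQR)",
        )
        ax.plot(fx["lam"], fx["alpha_hat"], "o--", color="gray", label="fixed-LR fit")
        ax.set_xlabel("adaptiveness")
        ax.set_ylabel("learning rate")
        ax.set_title(task)
        ax.legend(fontsize=8)

        ax = axes[1][j]
        for beta, mark in zip(sorted(sub["beta_gen"].unique()), ("o", "s")):
            for model, color in (("fixed_lr", "0.2"), ("bayes_lr", "0.6")):
                m = sub[(sub["model"] == model) & (sub["beta_gen"] == beta)]
                ax.errorbar(
                    m["lam"],
                    m["beta_hat"],
                    yerr=m["beta_se"],
                    fmt=f"{mark}-",
                    color=color,
                    label=f"{model} (beta={beta:g})",
                )
            ax.axhline(beta, color="k", lw=0.5, ls=":")
        ax.set_xlabel("adaptiveness")
        ax.set_ylabel("fitted inverse temperature")
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_profiles(profiles: pd.DataFrame) -> "plt.Figure":
    """Change-point-aligned mean log-likelihood, one panel per task;
    lighter gray = higher adaptiveness; dashed line = steady-state bin."""
    tasks = list(dict.fromkeys(profiles["task"]))
    fig, axes = plt.subplots(1, len(tasks), figsize=(5 * len(tasks), 3.5), squeeze=False)
    for j, task in enumerate(tasks):
        ax = axes[0][j]
        sub = profiles[profiles["task"] == task]
        lams = sorted(sub["lam"].unique())
        for i, lam in enumerate(lams):
            m = sub[(sub["lam"] == lam) & (sub["offset"] >= 0)]
            term = sub[(sub["lam"] == lam) & (sub["offset"] == -1)]["mean_loglik"]
            shade = str(0.7 * i / max(len(lams) - 1, 1))
            ax.errorbar(
                m["offset"], m["mean_loglik"], yerr=m["se_loglik"],
                color=shade, marker="o", ms=3, label=f"lam={lam:g}",
            )
            if len(term):
                ax.axhline(float(term.iloc[0]), color=shade, ls="--", lw=0.7)
        ax.set_xlabel("trials after change-point")
        ax.set_ylabel("mean log-likelihood")
        ax.set_title(task)
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_exclusion(exclusion: pd.DataFrame) -> "plt.Figure":
    """Fitted learning rate and inverse temperature vs. exclusion window."""
    tasks = list(dict.fromkeys(exclusion["task"]))
    fig, axes = plt.subplots(2, len(tasks), figsize=(5 * len(tasks), 6), squeeze=False)
    for j, task in enumerate(tasks):
        sub = exclusion[exclusion["task"] == task]
        lams = sorted(sub["lam"].unique())
        for row, col in ((0, "alpha_hat"), (1, "beta_hat")):
            ax = axes[row][j]
            for i, lam in enumerate(lams):
                m = sub[sub["lam"] == lam]
                shade = str(0.7 * i / max(len(lams) - 1, 1))
                ax.plot(m["window"], m[col], "o-", ms=3, color=shade, label=f"lam={lam:g}")
            ax.set_xlabel("exclusion window (trials after change-point)")
            ax.set_ylabel(col)
            if row == 0:
                ax.set_title(task)
            ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
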