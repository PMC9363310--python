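"""Diagnostic plots: scatter with fitted lines, forest, funnel, leave-one-out.

Plots are optional artifacts of the pipeline; no analysis result depends on
them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .estimators import wald_ratios

__all__ = ["scatter_plot", "forest_plot", "funnel_plot", "loo_plot", "epoch_panel"]


def scatter_plot(ax, instr, estimates) -> None:
    bx, sx, by, sy = instr.beta_exp, instr.se_exp, instr.beta_out, instr.se_out
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=4, lw=0.8, color="0.3")
    xs = np.linspace(0, bx.max() * 1.05, 50)
    for e in estimates:
        if e.method in ("ivw_mre", "egger", "weighted_median"):
            ax.plot(xs, e.beta * xs, label=e.method)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("SNP effect on exposure (SD/allele)")
    ax.set_ylabel("SNP effect on outcome (log OR/allele)")
    ax.legend(fontsize=7)


def forest_plot(ax, instr, estimates) -> None:
    r, se = wald_ratios(instr, variance="first_order")
    labels = list(instr.snp_ids)
    y = np.arange(len(r))
    ax.errorbar(r, y, xerr=1.96 * se, fmt="o", ms=3, lw=0.8, color="0.3")
    offset = len(r)
    for k, e in enumerate(e for e in estimates if e.method in ("ivw_mre", "egger")):
        ax.errorbar([e.beta], [offset + k], xerr=[1.96 * e.se], fmt="s", ms=4)
        labels.append(e.method)
    ax.set_yticks(np.arange(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("causal estimate (log OR per SD)")


def funnel_plot(ax, instr, estimates) -> None:
    r, se = wald_ratios(instr, variance="first_order")
    ax.plot(r, 1.0 / se, "o", ms=4, color="0.3")
    for e in estimates:
        if e.method == "ivw_mre":
            ax.axvline(e.beta, color="C0", lw=1, label="IVW")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    ax.legend(fontsize=7)


def loo_plot(ax, loo) -> None:
    labels = [sid for sid, _ in loo]
    betas = np.array([e.beta for _, e in loo])
    ses = np.array([e.se for _, e in loo])
    y = np.arange(len(labels))
    ax.errorbar(betas, y, xerr=1.96 * ses, fmt="o", ms=3, lw=0.8, color="0.3")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=6)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("IVW estimate omitting each SNP")


def epoch_panel(epoch_result, path) -> None:
    """2×2 diagnostic panel for one epoch, written to ``path``."""
    instr = epoch_result.instruments
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    scatter_plot(axes[0, 0], instr, epoch_result.estimates)
    forest_plot(axes[0, 1], instr, epoch_result.estimates)
    funnel_plot(axes[1, 0], instr, epoch_result.estimates)
    if epoch_result.loo:
        loo_plot(axes[1, 1], epoch_result.loo)
    else:
        axes[1, 1].axis("off")
    fig.suptitle(epoch_result.label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
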