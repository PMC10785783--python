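"""Diagnostic plots: correction-factor regression and Bland-Altman."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bias import MethodComparison, RegressionEstimate
from .speciation import CorrectionRecord


def plot_correction_regression(
    records: Sequence[CorrectionRecord],
    estimates: Sequence[RegressionEstimate],
    path: Optional[str] = None,
):
    """Correction factor vs log eps with fitted curves and 95% bands."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"O_methyl": "tab:blue", "amide": "tab:orange", "S_methyl": "tab:green"}
    for mt in sorted({r.model_type for r in records}):
        sel = [r for r in records if r.model_type == mt]
        ax.scatter(
            [r.log_eps.value for r in sel],
            [r.correction for r in sel],
            s=22,
            color=colors.get(mt, "gray"),
            label=mt.replace("_", "-"),
        )
    for est in estimates:
        xs = np.linspace(0.05, 3.6, 200)
        fit, lo, hi = est.prediction_band(xs)
        c = colors.get(est.model_type, "gray")
        ax.plot(xs, fit, color=c)
        ax.fill_between(xs, lo, hi, color=c, alpha=0.15)
    ax.axhline(0.0, color="k", lw=0.6, ls=":")
    ax.set_xlabel(r"interactivity parameter log $\varepsilon$")
    ax.set_ylabel("correction factor (log units)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bland_altman(
    comparison: MethodComparison, path: Optional[str] = None
):
    """Difference (NMR - potentiometry) vs mean log K with bias and LoA."""
    df = comparison.pairs
    mean = (df["logK_nmr"] + df["logK_pot"]) / 2
    diff = df["logK_nmr"] - df["logK_pot"]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(mean, diff, s=24, color="tab:blue")
    ax.axhline(comparison.bland_altman_bias, color="k", lw=1, label="bias")
    for y in comparison.loa:
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean log K (NMR, potentiometry)")
    ax.set_ylabel("difference in log K (NMR - potentiometry)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
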