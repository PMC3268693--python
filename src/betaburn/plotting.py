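"""Decay plots: B-factor (solid) and normalized relative scale (dashed) vs dose."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .betafit import DecayResult, DecaySeries

__all__ = ["plot_decay"]


def plot_decay(
    series: DecaySeries,
    fit: DecayResult | None = None,
    path: str | Path | None = None,
    title: str | None = None,
) -> "plt.Figure":
    """Plot B-factors and relative scales against nominal dose.

    Full line with markers: per-wedge B (A^2, left axis); dashed line:
    overall scale normalized to its maximum (right axis).  If a fit is
    given, the fitted line and beta are drawn on top.
    """
    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    ax.plot(series.doses, series.B, "o-", color="tab:blue", label="B-factor")
    if fit is not None:
        d = np.linspace(series.doses.min(), series.doses.max(), 50)
        ax.plot(
            d,
            fit.intercept + fit.beta * d,
            color="tab:blue",
            alpha=0.5,
            label=rf"fit: $\beta$ = {fit.beta:.2f} $\mathrm{{\AA^2\,MGy^{{-1}}}}$",
        )
    ax.set_xlabel("nominal dose (MGy)")
    ax.set_ylabel(r"relative B-factor ($\mathrm{\AA^2}$)")
    ax2 = ax.twinx()
    kmax = series.k.max() if series.k.size else 1.0
    ax2.plot(series.doses, series.k / kmax, "s--", color="tab:orange", label="relative scale")
    ax2.set_ylabel("relative scale (max = 1)")
    ax2.set_ylim(0, 1.05)
    lines, labels = ax.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax.legend(lines + l2, labels + lab2, loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
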