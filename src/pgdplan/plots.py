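"""Figure helpers for evaluation outputs (thin matplotlib wrappers)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluate import RepresentationCurves

__all__ = ["plot_representation_curves", "plot_pgd_representation"]


def plot_representation_curves(
    curves: RepresentationCurves,
    path: str | Path,
    highlight: Optional[list[str]] = None,
    max_background: int = 200,
) -> None:
    """Retained proportion vs top landscape fraction, one line per feature."""
    fig, ax = plt.subplots(figsize=(6, 4))
    shown = 0
    for fid, row in zip(curves.feature_ids, curves.proportions):
        if fid in curves.undefined:
            continue
        if highlight and fid in highlight:
            ax.plot(curves.fractions, row, lw=1.8, label=fid)
        elif shown < max_background:
            ax.plot(curves.fractions, row, lw=0.5, alpha=0.3, color="gray")
            shown += 1
    ax.set_xlabel("top landscape fraction")
    ax.set_ylabel("retained proportion of feature")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if highlight:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pgd_representation(
    rep: pd.DataFrame, path: str | Path, fraction: float = 0.2
) -> None:
    """Bar chart of per-proxy retained proportion at an area threshold."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    order = rep.sort_values("pgd_id")
    ax.bar(order["pgd_id"].astype(str), order["proportion"], color="#3b7a57")
    ax.axhline(fraction, ls="--", lw=0.8, color="k",
               label=f"area threshold {fraction:.0%}")
    ax.set_xlabel("proxy of genetic differentiation")
    ax.set_ylabel("retained share of range overlap")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", labelsize=6, rotation=90)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
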