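"""Static plots of ensemble results (roles vs connectivity, ascendancy peak)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ensembles import PeakEstimate, locate_ascendancy_peak
from .indices import DEFAULT_WOV, WOVPolygon

__all__ = ["plot_roles_vs_connectivity", "plot_ascendancy_vs_connectivity"]


def _by_size(df: pd.DataFrame):
    for size, group in df.dropna(subset=["mean_connectivity"]).groupby("size"):
        yield int(size), group


def plot_roles_vs_connectivity(
    df: pd.DataFrame,
    wov: WOVPolygon | None = None,
    path: str | Path | None = None,
):
    """Scatter of realized roles vs mean connectivity by size group.

    Optionally overlays the window-of-vitality rectangle (the region of
    connectivity/roles space occupied by real ecological flow networks).
    """
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for size, group in _by_size(df):
        ax.scatter(
            group["mean_connectivity"],
            group["realized_roles"],
            s=12,
            alpha=0.6,
            label=f"n={size}",
        )
    if wov is not None:
        rect = plt.Rectangle(
            (wov.c_min, wov.r_min),
            wov.c_max - wov.c_min,
            wov.r_max - wov.r_min,
            fill=False,
            edgecolor="black",
            linewidth=1.5,
            label=(
                f"Window of Vitality (C {wov.c_min}–{wov.c_max}, "
                f"R {wov.r_min}–{wov.r_max})"
            ),
        )
        ax.add_patch(rect)
    ax.set_xlabel("mean connectivity C (weighted links per node)")
    ax.set_ylabel("realized roles R")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ascendancy_vs_connectivity(
    df: pd.DataFrame,
    fit_peak: bool = True,
    path: str | Path | None = None,
):
    """Scatter of ascendancy vs mean connectivity with optional parabola fit."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for size, group in _by_size(df):
        ax.scatter(
            group["mean_connectivity"],
            group["ascendancy"],
            s=12,
            alpha=0.6,
            label=f"n={size}",
        )
    if fit_peak:
        clean = df.dropna(subset=["mean_connectivity", "ascendancy"])
        for size, group in clean.groupby("size"):
            if len(group) < 10:
                continue
            try:
                peak: PeakEstimate = locate_ascendancy_peak(
                    group["mean_connectivity"], group["ascendancy"]
                )
            except ValueError:
                continue
            ax.axvline(peak.c_at_max, linestyle="--", linewidth=0.8, color="grey")
            ax.annotate(
                f"peak n={int(size)}: C={peak.c_at_max:.1f}",
                (peak.c_at_max, group["ascendancy"].max()),
                fontsize=7,
                rotation=90,
                va="top",
            )
    ax.set_xlabel("mean connectivity C (weighted links per node)")
    ax.set_ylabel("ascendancy A (influence·bits)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
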