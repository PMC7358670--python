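"""Plotting helpers mirroring the package's two summary figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .smear import log10_pct_with_floor

__all__ = ["two_axis_plot", "band_plot"]


def two_axis_plot(scores: pd.DataFrame, path: str | Path) -> Path:
    """Scatter of %-vacuolated (log10, floored zeros) vs vacuoles per cell."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in scores.groupby("severity_class"):
        log_pct, _ = log10_pct_with_floor(grp["pct_vacuolated"])
        ax.scatter(log_pct, grp["vacuoles_per_cell_median"], label=cls, s=18)
    ax.set_xlabel("log10 % vacuolated lymphocytes")
    ax.set_ylabel("vacuoles per affected lymphocyte (median)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def band_plot(bands: pd.DataFrame, path: str | Path) -> Path:
    """Sliding-threshold percentile bands per class (long-format table)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in bands.groupby("class"):
        ax.fill_between(grp["level"], grp["p2_5"], grp["p97_5"], alpha=0.15)
        ax.fill_between(grp["level"], grp["q25"], grp["q75"], alpha=0.3)
        ax.plot(grp["level"], grp["median"], label=str(cls))
    ax.set_xlabel("intensity threshold level (0-255)")
    ax.set_ylabel("% of cell area >= level")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
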