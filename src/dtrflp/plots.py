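"""Figure rendering: mirror plot, cross-correlation curve, density histogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .comparison import CrossCorrelationResult
from .metrics import DensityReport


def mirror_plot(data: pd.DataFrame, path: str | Path, clip: float = 5.0) -> None:
    """Experimental profile up, shifted digital profile down, shared axis.

    Peaks taller than *clip* percent are truncated and annotated with their
    true abundance.
    """
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(data["size_bp"], data["etrf_display"], width=1.0, color="tab:blue")
    ax.bar(data["size_bp"], -data["dtrf_display"], width=1.0, color="tab:red")
    for _, row in data.iterrows():
        if row["etrf_abundance"] > clip:
            ax.annotate(
                f"{row['etrf_abundance']:.1f}",
                (row["size_bp"], clip),
                fontsize=6,
                ha="center",
                va="bottom",
            )
        if row["dtrf_abundance"] > clip:
            ax.annotate(
                f"{row['dtrf_abundance']:.1f}",
                (row["size_bp"], -clip),
                fontsize=6,
                ha="center",
                va="top",
            )
    ax.axhline(0.0, color="black", linewidth=0.6)
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("relative abundance (%)\n eT-RFLP up / dT-RFLP down")
    ax.set_ylim(-clip * 1.3, clip * 1.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cross_correlation_plot(result: CrossCorrelationResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(result.lags, result.coefficients, marker="o", markersize=3)
    ax.axvline(result.optimal_lag, color="tab:red", linestyle="--",
               label=f"optimal lag {result.optimal_lag:+d} bp")
    ax.set_xlabel("lag (bp)")
    ax.set_ylabel("cross-correlation coefficient")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_plot(report: DensityReport, path: str | Path) -> None:
    frame = report.to_frame()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    centers = (frame["class_start_bp"] + frame["class_end_bp"]) / 2
    ax.bar(centers, frame["trf_count"], width=45, color="tab:gray")
    ax2 = ax.twinx()
    ax2.plot(centers, frame["cumulative_trf_count"], color="black", linewidth=1.5)
    ax.set_xlabel("fragment size class (bp)")
    ax.set_ylabel("T-RFs per 50-bp class")
    ax2.set_ylabel("cumulative T-RFs")
    ax.set_title(
        f"{report.enzyme}: richness {report.indices.richness}, "
        f"H' {report.indices.shannon:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
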