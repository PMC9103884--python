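"""Plot helpers mirroring the analysis outputs: concordance transition
curves per tissue/family and quality (SNR, sharpness) curves per tissue."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_transition_curves", "plot_quality"]


def _pair_labels(df: pd.DataFrame) -> list[str]:
    return [f"{lo}→{hi}" for lo, hi in zip(df["pair_lo"], df["pair_hi"])]


def plot_transition_curves(tidy_report: pd.DataFrame, family: str = "ALL"):
    """Average Lin's ρc per matrix transition, one line per
    (tissue, normalization); ``tidy_report`` comes from
    PipelineResult.tidy_report()."""
    sub = tidy_report[tidy_report["family"] == family]
    fig, axes = plt.subplots(
        1, sub["mode"].nunique(), figsize=(6 * sub["mode"].nunique(), 4), squeeze=False
    )
    for ax, (mode, mgrp) in zip(axes[0], sub.groupby("mode")):
        for (tissue, norm), grp in mgrp.groupby(["tissue", "normalization"]):
            grp = grp.sort_values(["pair_lo", "pair_hi"])
            ax.plot(
                _pair_labels(grp),
                grp["mean_ccc"],
                marker="o",
                linestyle="-" if norm == "raw" else "--",
                label=f"{tissue} ({norm})",
            )
        ax.set_title(f"{mode}: mean Lin's ρc per transition ({family})")
        ax.set_xlabel("matrix transition")
        ax.set_ylabel("mean ρc")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_quality(quality_df: pd.DataFrame):
    """SNR and sharpness versus matrix size, one line per tissue."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for tissue, grp in quality_df.groupby("tissue"):
        grp = grp.sort_values("matrix_size")
        ax1.plot(grp["matrix_size"], grp["snr_mean"], marker="o", label=tissue)
        ax2.plot(grp["matrix_size"], grp["sharpness_mean"], marker="o", label=tissue)
    ax1.set_xlabel("matrix size")
    ax1.set_ylabel("mean SNR")
    ax1.set_title("ROI SNR")
    ax2.set_xlabel("matrix size")
    ax2.set_ylabel("mean |∇| per mm")
    ax2.set_title("ROI sharpness")
    ax1.legend()
    ax2.legend()
    fig.tight_layout()
    return fig
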