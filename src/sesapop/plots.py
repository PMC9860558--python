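"""Simple Manhattan / QQ / LD-decay figures from the pipeline's tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan(results: pd.DataFrame, out_path, threshold: float = 6.0) -> None:
    """Manhattan plot of -log10 p by position, one panel color per chromosome."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for i, (chrom, sub) in enumerate(results.groupby("chrom", sort=False)):
        ax.scatter(sub.pos + offset, sub.minus_log10_p, s=4,
                   color=f"C{i % 2}", rasterized=True)
        ticks.append((chrom, offset + sub.pos.median()))
        offset += sub.pos.max() + 1
    ax.axhline(threshold, ls="--", lw=0.8, color="steelblue")
    ax.set_xticks([t for _, t in ticks], [c for c, _ in ticks], rotation=45)
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def qq(qq_data: pd.DataFrame, out_path) -> None:
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot(qq_data.expected_minus_log10_p, qq_data.observed_minus_log10_p,
            ".", ms=3)
    lim = float(qq_data.expected_minus_log10_p.max())
    ax.plot([0, lim], [0, lim], "r-", lw=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def ld_decay(curve_frame: pd.DataFrame, out_path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3))
    mid = (curve_frame.bin_start_bp + curve_frame.bin_end_bp) / 2e3
    ax.plot(mid, curve_frame.mean_r2, ".", ms=2, alpha=0.4, label="binned")
    ax.plot(mid, curve_frame.smoothed_r2, "-", lw=1.2, label="smoothed")
    half = np.nanmax(curve_frame.smoothed_r2) / 2
    ax.axhline(half, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
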