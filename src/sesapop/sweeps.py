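"""Joint FST / pi-ratio selective-sweep calling and trait-extreme group splits.

A window is called swept for a focal group against a background group when
both its Weir-Cockerham FST and its log2(pi_background / pi_focal) exceed the
adopted thresholds (FST > 0.45, log2 ratio > 2.5 by default); an empirical
top-5%-of-both mode is available. Flagged windows are merged into regions,
which are then intersected with gene models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GeneModel

FST_MIN = 0.45
LOG2_RATIO_MIN = 2.5
RATIO_CAP = 10.0  # log2 ratio assigned when the focal group has zero diversity


@dataclass
class SweepRegion:
    chrom: str
    start: int      # 0-based inclusive, merged window span
    end: int        # exclusive
    n_windows: int
    peak_fst: float
    peak_log2_ratio: float
    focal: str
    background: str
    gene_ids: list[str] = field(default_factory=list)


def window_contrast(stats: pd.DataFrame, focal: str, background: str,
                    ratio_cap: float = RATIO_CAP) -> pd.DataFrame:
    """Per-window (fst, log2_pi_ratio) for a focal group against a background.

    log2_pi_ratio = log2(pi_background / pi_focal), so a sweep in the focal
    group scores positive. Windows with zero background diversity are
    excluded; zero focal diversity with positive background gets the cap.
    """
    for g in (focal, background):
        if f"pi_{g}" not in stats.columns:
            raise ValueError(f"unknown group {g!r} in window stats")
    fst_col = (f"fst_{focal}_{background}"
               if f"fst_{focal}_{background}" in stats.columns
               else f"fst_{background}_{focal}")
    if fst_col not in stats.columns:
        raise ValueError(f"no FST column for pair ({focal}, {background})")
    pi_f = stats[f"pi_{focal}"].to_numpy(dtype=float)
    pi_b = stats[f"pi_{background}"].to_numpy(dtype=float)
    out = stats[["chrom", "start", "end", "n_snps"]].copy()
    out["fst"] = stats[fst_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pi_b / pi_f)
    ratio[(pi_f == 0) & (pi_b > 0)] = ratio_cap
    capped = (pi_f == 0) & (pi_b > 0)
    out["log2_pi_ratio"] = ratio
    out["ratio_capped"] = capped
    out = out[pi_b > 0].reset_index(drop=True)
    out.attrs["focal"], out.attrs["background"] = focal, background
    return out


def call_sweep_regions(contrasts: pd.DataFrame, fst_min: float = FST_MIN,
                       ratio_min: float = LOG2_RATIO_MIN, mode: str = "fixed",
                       quantile: float = 0.05, merge_gap: int = 1,
                       window_size: int = 10_000) -> list[SweepRegion]:
    """Flag windows passing both criteria and merge them into regions.

    ``mode="fixed"`` uses the numeric thresholds; ``mode="quantile"`` flags
    windows in the top ``quantile`` of BOTH statistics. Flagged windows within
    ``merge_gap`` windows of each other on the same chromosome are merged.
    """
    fst = contrasts["fst"].to_numpy(dtype=float)
    ratio = contrasts["log2_pi_ratio"].to_numpy(dtype=float)
    if mode == "fixed":
        flag = (fst > fst_min) & (ratio > ratio_min)
    elif mode == "quantile":
        flag = ((fst >= np.nanquantile(fst, 1 - quantile))
                & (ratio >= np.nanquantile(ratio, 1 - quantile)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flag &= np.isfinite(fst) & np.isfinite(ratio)
    flagged = contrasts[flag]
    focal = contrasts.attrs.get("focal", "")
    background = contrasts.attrs.get("background", "")
    regions: list[SweepRegion] = []
    gap_bp = merge_gap * window_size
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, row in sub.iterrows():
            w_start, w_end = int(row.start) - 1, int(row.end)  # back to 0-based
            if cur is not None and w_start - cur.end <= gap_bp:
                cur.end = w_end
                cur.n_windows += 1
                cur.peak_fst = max(cur.peak_fst, float(row.fst))
                cur.peak_log2_ratio = max(cur.peak_log2_ratio, float(row.log2_pi_ratio))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = SweepRegion(chrom, w_start, w_end, 1, float(row.fst),
                                  float(row.log2_pi_ratio), focal, background)
        if cur is not None:
            regions.append(cur)
    return regions


def genes_in_regions(regions: list[SweepRegion], genes: list[GeneModel],
                     ) -> tuple[list[SweepRegion], set[str]]:
    """Attach overlapping genes (>= 1 bp) to each region; return the union too."""
    union: set[str] = set()
    for reg in regions:
        hits = [g.gene_id for g in genes
                if g.chrom == reg.chrom and g.start < reg.end and reg.start < g.end]
        reg.gene_ids = sorted(hits)
        union.update(hits)
    return regions, union


def common_selected_genes(*gene_sets: set[str]) -> list[str]:
    """Sorted intersection of two or more selected-gene sets (Venn core)."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    common = set(gene_sets[0])
    for s in gene_sets[1:]:
        common &= set(s)
    return sorted(common)


def trait_group_split(values: pd.Series, high_min: float = 6.0,
                      low_max: float = 1.0, min_group: int = 10,
                      ) -> tuple[list[str], list[str]]:
    """Split accessions into high / low trait groups by strict thresholds.

    ``values`` is one value per accession (a BLUP or single-environment
    measurement, mg/g). Accessions with value > high_min go high, < low_max go
    low, the rest are unassigned. Groups smaller than ``min_group`` trigger a
    warning: downstream scans should refuse them.
    """
    high = sorted(values.index[values > high_min].astype(str))
    low = sorted(values.index[values < low_max].astype(str))
    for name, grp in (("high", high), ("low", low)):
        if len(grp) < min_group:
            warnings.warn(f"{name}-trait group has only {len(grp)} accessions",
                          stacklevel=2)
    return high, low


def regions_table(regions: list[SweepRegion]) -> pd.DataFrame:
    """TSV-ready region table (1-based inclusive coordinates)."""
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start + 1, "end": r.end,
        "n_windows": r.n_windows, "peak_fst": r.peak_fst,
        "peak_log2_ratio": r.peak_log2_ratio, "focal": r.focal,
        "background": r.background, "genes": ";".join(r.gene_ids),
    } for r in regions])
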