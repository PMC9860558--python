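"""Pairwise genotype r^2, binned LD-decay curves, and the half-decay distance.

Unphased input means genotype (dosage) r^2, i.e. the squared Pearson
correlation of ALT-dosage vectors -- the PopLDdecay-style default for
resequencing panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix

SMOOTH_BINS = 5  # rolling-median window (bins) applied before feature extraction


def pair_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation over shared non-missing samples.

    NaN when fewer than 2 shared calls or either site is monomorphic in the
    shared set. Symmetric and invariant to allele relabeling (d -> 2-d).
    """
    ok = (dosage_a != MISSING) & (dosage_b != MISSING)
    a = dosage_a[ok].astype(float)
    b = dosage_b[ok].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdCurve:
    """Binned LD-decay curve: mean r^2 per distance bin plus a smoothed track."""

    bin_start: np.ndarray   # bp, inclusive
    bin_end: np.ndarray     # bp, exclusive
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        return (self.bin_start + self.bin_end) / 2.0

    @property
    def max_r2(self) -> float:
        track = self.smoothed if self.smoothed is not None else self.mean_r2
        return float(np.nanmax(track))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_bp": self.bin_start, "bin_end_bp": self.bin_end,
            "n_pairs": self.n_pairs, "mean_r2": self.mean_r2,
            "smoothed_r2": (self.smoothed if self.smoothed is not None
                            else self.mean_r2),
        })


def _smooth(values: np.ndarray, window: int = SMOOTH_BINS) -> np.ndarray:
    s = pd.Series(values)
    return s.rolling(window, min_periods=1, center=True).median().to_numpy()


def ld_decay_curve(gm: GenotypeMatrix, sample_idx=None, max_dist: int = 500_000,
                   bin_bp: int = 1000, pair_budget: int = 10_000_000,
                   seed: int = 0) -> LdCurve:
    """Mean r^2 per distance bin over all intra-chromosomal pairs within max_dist.

    Pairs above ``pair_budget`` are uniformly subsampled with the given seed,
    so the curve is deterministic. The smoothed track (rolling median over 5
    bins) is attached for feature extraction.
    """
    dosage = gm.dosage if sample_idx is None else gm.dosage[sample_idx]
    pos = gm.sites.pos.to_numpy()
    chroms = gm.sites.chrom.to_numpy()
    pairs_i, pairs_j = [], []
    any_pairable = False
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) < 2:
            continue
        any_pairable = True
        cp = pos[sel]
        # sites are sorted; for each left index find the right bound within max_dist
        hi = np.searchsorted(cp, cp + max_dist, side="right")
        for a in range(len(sel) - 1):
            b = np.arange(a + 1, hi[a])
            pairs_i.append(np.full(len(b), sel[a]))
            pairs_j.append(sel[b])
    if not any_pairable:
        raise ValueError("fewer than 2 sites on every chromosome")
    ii = np.concatenate(pairs_i) if pairs_i else np.array([], dtype=int)
    jj = np.concatenate(pairs_j) if pairs_j else np.array([], dtype=int)
    if len(ii) > pair_budget:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 29]))
        keep = rng.choice(len(ii), size=pair_budget, replace=False)
        ii, jj = ii[keep], jj[keep]
    dist = pos[jj] - pos[ii]

    # pairwise r^2 with per-pair missing handling, computed in chunks to keep
    # memory flat for large pair lists
    D = dosage.astype(float)
    D[dosage == MISSING] = np.nan
    n_bins = int(np.ceil(max_dist / bin_bp))
    which = np.minimum(dist // bin_bp, n_bins - 1).astype(int)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chunk = 200_000
    for lo in range(0, len(ii), chunk):
        sl = slice(lo, lo + chunk)
        a = D[:, ii[sl]]
        b = D[:, jj[sl]]
        ok = ~np.isnan(a) & ~np.isnan(b)
        n = ok.sum(axis=0)
        a0 = np.where(ok, a, 0.0)
        b0 = np.where(ok, b, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ma = a0.sum(axis=0) / n
            mb = b0.sum(axis=0) / n
            cov = (a0 * b0).sum(axis=0) / n - ma * mb
            va = (a0**2).sum(axis=0) / n - ma**2
            vb = (b0**2).sum(axis=0) / n - mb**2
            r2 = cov**2 / (va * vb)
        r2[(n < 2) | (va <= 0) | (vb <= 0)] = np.nan
        valid = ~np.isnan(r2)
        sums += np.bincount(which[sl][valid], weights=r2[valid], minlength=n_bins)
        counts += np.bincount(which[sl][valid], minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r2 = sums / counts
    nonempty = counts > 0
    curve = LdCurve(
        bin_start=np.arange(n_bins)[nonempty] * bin_bp,
        bin_end=(np.arange(n_bins)[nonempty] + 1) * bin_bp,
        mean_r2=mean_r2[nonempty],
        n_pairs=counts[nonempty],
    )
    curve.smoothed = _smooth(curve.mean_r2)
    return curve


def half_decay_distance(curve: LdCurve) -> float:
    """Distance at which mean r^2 first drops to half its maximum.

    Works on the smoothed track when present, with linear interpolation
    between the straddling bins (bin midpoints as distances). Returns NaN
    with a warning when the curve never reaches half its maximum.
    """
    track = curve.smoothed if curve.smoothed is not None else curve.mean_r2
    x = curve.bin_mid
    finite = np.isfinite(track)
    x, track = x[finite], np.asarray(track)[finite]
    if len(track) == 0:
        return float("nan")
    target = np.nanmax(track) / 2.0
    below = np.flatnonzero(track <= target)
    if len(below) == 0:
        warnings.warn("LD curve never drops to half its maximum", stacklevel=2)
        return float("nan")
    j = below[0]
    if j == 0 or track[j] == target:
        return float(x[j])
    x0, x1 = x[j - 1], x[j]
    y0, y1 = track[j - 1], track[j]
    return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))
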