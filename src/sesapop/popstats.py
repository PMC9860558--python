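"""Windowed diversity and differentiation statistics.

Nucleotide diversity pi, Watterson's theta, Tajima's D, and the Weir &
Cockerham (1984) FST estimator, all computed over 10 kb non-overlapping
windows by default. Diploid genotypes contribute two haplotypes under
within-population Hardy-Weinberg (dosage-only input, no phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix

DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict[str, int], size: int = DEFAULT_WINDOW) -> list[Window]:
    """Tile each chromosome with non-overlapping windows; last one truncated."""
    if size <= 0:
        raise ValueError("window size must be positive")
    out = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        for start in range(0, length, size):
            out.append(Window(chrom, start, min(start + size, length)))
    return out


def site_pi(dosage: np.ndarray) -> float:
    """Unbiased per-site diversity from one site's dosage vector.

    With m non-missing haplotypes (2 x calls) and ALT frequency p-hat this is
    2 p (1-p) m/(m-1), which equals the mean pairwise difference over the m
    haplotypes. Sites with fewer than 2 calls return NaN (skipped upstream).
    """
    d = dosage[dosage != MISSING]
    m = 2 * len(d)
    if m < 4:
        return float("nan")
    p = d.sum() / m
    return 2.0 * p * (1.0 - p) * m / (m - 1)


def _site_pi_vec(dosage: np.ndarray) -> np.ndarray:
    """Vectorized site_pi over a samples x sites dosage block."""
    ok = dosage != MISSING
    m = 2 * ok.sum(axis=0)
    alt = np.where(ok, dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / m
        pi = 2.0 * p * (1.0 - p) * m / (m - 1)
    pi[m < 4] = np.nan
    return pi


def window_pi(gm: GenotypeMatrix, window: Window, sample_idx=None) -> float:
    """Per-bp diversity: sum of site_pi over SNPs in the window / window length."""
    mask = ((gm.sites.chrom == window.chrom) & (gm.sites.pos >= window.start)
            & (gm.sites.pos < window.end)).to_numpy()
    if mask.sum() == 0:
        return 0.0
    block = gm.dosage[:, mask] if sample_idx is None else gm.dosage[np.ix_(sample_idx, np.flatnonzero(mask))]
    pi = _site_pi_vec(block)
    return float(np.nansum(pi)) / window.length


def _tajima_constants(n: int) -> tuple[float, float]:
    """e1, e2 for Tajima's variance with n haplotypes."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def watterson_theta(S: int, n_hap: int) -> float:
    """Watterson's theta (per window, not per bp) from S segregating sites."""
    if n_hap < 2:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n_hap))
    return S / a1


def tajimas_d(gm: GenotypeMatrix, window: Window, sample_idx=None) -> float:
    """Tajima's D over the window using complete-case samples (fixed n).

    Only samples non-missing at every SNP in the window contribute, so the
    haplotype count n is constant across sites (VCFtools-style). Returns NaN
    when S = 0 or fewer than 2 complete cases remain.
    """
    mask = ((gm.sites.chrom == window.chrom) & (gm.sites.pos >= window.start)
            & (gm.sites.pos < window.end)).to_numpy()
    if mask.sum() == 0:
        return float("nan")
    block = gm.dosage[:, mask] if sample_idx is None else gm.dosage[np.ix_(sample_idx, np.flatnonzero(mask))]
    complete = (block != MISSING).all(axis=1)
    block = block[complete]
    n = 2 * block.shape[0]
    if n < 4:
        return float("nan")
    alt = block.sum(axis=0)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k = alt[seg].astype(float)
    pi_sum = float(np.sum(2.0 * k * (n - k) / (n * (n - 1))))
    theta_w = watterson_theta(S, n)
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_sum - theta_w) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Weir & Cockerham FST

def wc_components(dosage: np.ndarray, pop_idx: list[np.ndarray],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    ``pop_idx`` lists sample-row indices per population. Sites where any
    population has fewer than 2 non-missing calls get NaN components and are
    excluded from ratio-of-sums aggregation.
    """
    r = len(pop_idx)
    if r < 2:
        raise ValueError("need >= 2 populations")
    m_sites = dosage.shape[1]
    n = np.zeros((r, m_sites))     # non-missing diploid counts
    p = np.zeros((r, m_sites))     # ALT frequency
    h = np.zeros((r, m_sites))     # het proportion among non-missing
    for k, idx in enumerate(pop_idx):
        block = dosage[idx]
        ok = block != MISSING
        n[k] = ok.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p[k] = np.where(ok, block, 0).sum(axis=0) / (2.0 * n[k])
            h[k] = ((block == 1).sum(axis=0)) / n[k]
    valid = (n >= 2).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_tot = n.sum(axis=0)
        n_bar = n_tot / r
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_tot
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = (n_bar / nc) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def wc_fst(gm: GenotypeMatrix, pop_samples: dict[str, list[str]],
           window: Window | None = None, method: str = "ratio_of_sums") -> float:
    """Weir–Cockerham FST over a window (or genome-wide when window is None).

    ``ratio_of_sums`` (the default, VCFtools' "weighted" estimator) returns
    sum(a) / sum(a+b+c); ``mean_of_ratios`` averages per-site ratios instead.
    Sites with a zero denominator are excluded. Negative estimates are
    retained (not clamped) so genome-wide sums stay unbiased.
    """
    if window is None:
        mask = np.ones(gm.n_sites, dtype=bool)
    else:
        mask = ((gm.sites.chrom == window.chrom) & (gm.sites.pos >= window.start)
                & (gm.sites.pos < window.end)).to_numpy()
    if mask.sum() == 0:
        return float("nan")
    pop_idx = [gm.sample_indices(v) for v in pop_samples.values()]
    a, b, c = wc_components(gm.dosage[:, mask], pop_idx)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if ok.sum() == 0:
        return float("nan")
    if method == "ratio_of_sums":
        return float(np.sum(a[ok]) / np.sum(denom[ok]))
    if method == "mean_of_ratios":
        return float(np.mean(a[ok] / denom[ok]))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Per-window table

def window_stats(gm: GenotypeMatrix, groups: dict[str, str],
                 windows: list[Window] | None = None,
                 window_size: int = DEFAULT_WINDOW,
                 chrom_lengths: dict[str, int] | None = None,
                 pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Per-window pi / theta_W / Tajima's D per group and FST per group pair.

    Output coordinates are 1-based inclusive (``start``, ``end`` columns).
    """
    if windows is None:
        windows = make_windows(chrom_lengths or gm.chrom_lengths(), window_size)
    group_names = sorted(set(groups.values()))
    members = {g: [s for s in gm.samples if groups.get(s) == g] for g in group_names}
    members = {g: v for g, v in members.items() if len(v) >= 2}
    group_names = list(members)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(group_names) for b in group_names[i + 1:]]
    idx = {g: gm.sample_indices(v) for g, v in members.items()}
    rows = []
    pos = gm.sites.pos.to_numpy()
    chroms = gm.sites.chrom.to_numpy()
    for w in windows:
        mask = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end)
        rec = {"chrom": w.chrom, "start": w.start + 1, "end": w.end,
               "n_snps": int(mask.sum())}
        for g in group_names:
            rec[f"pi_{g}"] = window_pi(gm, w, idx[g])
            block = gm.dosage[np.ix_(idx[g], np.flatnonzero(mask))]
            complete = (block != MISSING).all(axis=1)
            n_hap = 2 * int(complete.sum())
            if n_hap >= 4 and mask.any():
                sub = block[complete]
                alt = sub.sum(axis=0)
                S = int(((alt > 0) & (alt < n_hap)).sum())
            else:
                S = 0
            rec[f"theta_{g}"] = (watterson_theta(S, n_hap) / w.length
                                 if n_hap >= 4 else float("nan"))
            rec[f"tajd_{g}"] = tajimas_d(gm, w, idx[g])
        for a_, b_ in pairs:
            rec[f"fst_{a_}_{b_}"] = wc_fst(
                gm, {a_: members[a_], b_: members[b_]}, window=w)
        rows.append(rec)
    return pd.DataFrame(rows)
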