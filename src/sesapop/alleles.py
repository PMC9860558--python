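"""Favorable-allele mining: group phenotypes by genotype at a locus and test.

The panel is inbred (selfed for generations), so heterozygotes are rare and
excluded by default; homozygous REF and ALT accessions form the two allele
groups compared by Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import MISSING, GenotypeMatrix


@dataclass
class AlleleGroups:
    site_id: str
    ref: str
    alt: str
    groups: dict[str, list[str]]     # allele (or "het") -> accession ids

    def sizes(self) -> dict[str, int]:
        return {a: len(v) for a, v in self.groups.items()}


@dataclass
class AlleleEffect:
    site_id: str
    allele_a: str
    allele_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p_value: float
    superior_allele: str | None = None
    significant: bool = False
    skipped: bool = False
    note: str = ""


def split_by_allele(gm: GenotypeMatrix, site_index: int,
                    het_policy: str = "exclude") -> AlleleGroups:
    """Partition samples by genotype at one site.

    Homozygous REF -> REF-allele group, homozygous ALT -> ALT-allele group;
    heterozygotes are excluded (default) or kept as a separate "het" group
    (``het_policy="separate"``). Missing genotypes are always excluded.
    """
    site = gm.site_at(site_index)
    d = gm.dosage[:, site_index]
    groups = {site.ref: [s for s, g in zip(gm.samples, d) if g == 0],
              site.alt: [s for s, g in zip(gm.samples, d) if g == 2]}
    hets = [s for s, g in zip(gm.samples, d) if g == 1]
    if het_policy == "separate":
        groups["het"] = hets
    elif het_policy != "exclude":
        raise ValueError(f"unknown het_policy {het_policy!r}")
    return AlleleGroups(site.locus_id, site.ref, site.alt, groups)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite df, and the two-sided p-value.

    Requires >= 2 values per group. Identical constant groups give
    (0, nan, 1) -- no evidence either way.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        return (0.0, float("nan"), 1.0) if a.mean() == b.mean() else \
               (np.inf if a.mean() > b.mean() else -np.inf, float("nan"), 0.0)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def allele_effect(gm: GenotypeMatrix, site_index: int, phenotype: pd.Series,
                  het_policy: str = "exclude", direction: str = "higher",
                  alpha: float = 0.05) -> AlleleEffect:
    """Test the phenotype difference between the two homozygote allele groups."""
    ag = split_by_allele(gm, site_index, het_policy)
    site = gm.site_at(site_index)
    val = {a: phenotype.reindex(ids).dropna().to_numpy(dtype=float)
           for a, ids in ag.groups.items() if a != "het"}
    a_ids, b_ids = site.ref, site.alt
    va, vb = val[a_ids], val[b_ids]
    base = dict(site_id=ag.site_id, allele_a=a_ids, allele_b=b_ids,
                n_a=len(va), n_b=len(vb),
                mean_a=float(va.mean()) if len(va) else float("nan"),
                mean_b=float(vb.mean()) if len(vb) else float("nan"),
                sd_a=float(va.std(ddof=1)) if len(va) > 1 else float("nan"),
                sd_b=float(vb.std(ddof=1)) if len(vb) > 1 else float("nan"))
    if len(va) < 2 or len(vb) < 2:
        return AlleleEffect(**base, t=float("nan"), df=float("nan"),
                            p_value=float("nan"), skipped=True,
                            note="group smaller than 2")
    t, df, p = welch_t_test(va, vb)
    eff = AlleleEffect(**base, t=t, df=df, p_value=p)
    return superior_allele(eff, direction=direction, alpha=alpha)


def superior_allele(effect: AlleleEffect, direction: str = "higher",
                    alpha: float = 0.05) -> AlleleEffect:
    """Annotate the allele whose group mean is higher (or lower) in the trait.

    Ties give None. ``significant`` flags p < alpha.
    """
    if effect.skipped or effect.mean_a == effect.mean_b:
        effect.superior_allele = None
        return effect
    better_a = effect.mean_a > effect.mean_b
    if direction == "lower":
        better_a = not better_a
    elif direction != "higher":
        raise ValueError(f"unknown direction {direction!r}")
    effect.superior_allele = effect.allele_a if better_a else effect.allele_b
    effect.significant = bool(effect.p_value < alpha)
    return effect


def allele_effects_table(effects: list[AlleleEffect]) -> pd.DataFrame:
    rows = []
    for e in effects:
        for allele, n, mean, sd in ((e.allele_a, e.n_a, e.mean_a, e.sd_a),
                                    (e.allele_b, e.n_b, e.mean_b, e.sd_b)):
            rows.append({"site": e.site_id, "allele": allele, "n": n,
                         "mean": mean, "sd": sd, "t": e.t, "df": e.df,
                         "p": e.p_value,
                         "superior_allele": e.superior_allele or ""})
    return pd.DataFrame(rows)
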