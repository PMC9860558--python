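"""Synthetic genotype, annotation, and phenotype generators with known truth.

The generator emulates a structured resequencing panel: subpopulations whose
allele frequencies follow the Balding–Nichols model around a shared ancestral
frequency, localized selective sweeps planted by pushing focal-group
frequencies toward fixation, haplotype-copying LD with distance decay, and a
multi-environment quantitative trait (sesamin-like, mg/g scale) with planted
causal SNPs. Every stochastic step is driven by one seed so downstream scans
can be validated against the recorded truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (MISSING, GeneModel, GenotypeMatrix, SITE_COLUMNS,
                      write_fasta, write_gff, write_vcf)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: focal population, interval, and push intensity in [0,1]."""

    pop: str
    chrom: str
    start: int
    end: int
    intensity: float

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("sweep intensity must be in [0, 1]")
        if self.end <= self.start:
            raise ValueError("empty sweep interval")


@dataclass(frozen=True)
class TraitSpec:
    """Additive trait architecture across environments.

    ``causal_ids`` index sites in the site table; ``effects`` are in trait
    units (mg/g) per ALT allele; ``h2`` is the single-observation narrow-sense
    heritability used to calibrate the residual variance.
    """

    causal_ids: tuple[int, ...]
    effects: tuple[float, ...]
    h2: float = 0.5
    n_envs: int = 6
    mu: float = 2.5
    env_effects: tuple[float, ...] | None = None
    trait: str = "sesamin"

    def __post_init__(self):
        if len(self.causal_ids) != len(self.effects):
            raise ValueError("causal_ids and effects length mismatch")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.env_effects is not None and len(self.env_effects) != self.n_envs:
            raise ValueError("env_effects length != n_envs")


@dataclass
class SimConfig:
    """Study-condition knobs for the structured-panel generator.

    Defaults mirror the resequencing panel the package targets: missing-call
    rate 2%, read depth ~ Poisson(25) (the panel's ~24.93x mean), ancestral
    frequencies Uniform(0.05, 0.95) to keep sites clear of the MAF filter
    boundary, and transition-biased allele pairs (weight 3.8 reproduces a
    Ts/Tv ratio near 1.9).
    """

    pop_sizes: dict[str, int]
    F: dict[str, float] | float = 0.05
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"Chr1": 1_000_000})
    snp_density: float = 0.005
    sweeps: tuple[SweepSpec, ...] = ()
    trait: TraitSpec | None = None
    missing_rate: float = 0.02
    depth_mean: float = 25.0
    ts_weight: float = 3.8
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.F, (int, float)):
            self.F = {p: float(self.F) for p in self.pop_sizes}
        for p, n in self.pop_sizes.items():
            if n < 2:
                raise ValueError(f"pop {p!r} needs >= 2 samples")
        for p, f in self.F.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F for {p!r} must be in [0, 1)")
        for sw in self.sweeps:
            if sw.pop not in self.pop_sizes:
                raise ValueError(f"sweep focal pop {sw.pop!r} unknown")
            if sw.chrom not in self.chrom_lengths or sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError("sweep interval outside chromosome bounds")


@dataclass
class TruthTable:
    """Ground truth recorded by the generator for downstream validation."""

    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    F: dict[str, float]
    groups: dict[str, str]
    sweeps: list[SweepSpec] = field(default_factory=list)
    causal_ids: tuple[int, ...] = ()
    causal_effects: tuple[float, ...] = ()
    genetic_values: pd.Series | None = None

    def true_pi_per_bp(self, pop: str, length: int, site_mask=None) -> float:
        """Expected per-bp diversity Sum 2p(1-p) / L for one population."""
        p = self.pop_freqs[pop]
        if site_mask is not None:
            p = p[site_mask]
        return float(np.sum(2.0 * p * (1.0 - p)) / length)

    def expected_fst(self, pop_a: str, pop_b: str) -> float:
        # under Balding-Nichols with independent pops this is the first-order value
        return 0.5 * (self.F[pop_a] + self.F[pop_b])


def _draw_alleles(rng: np.random.Generator, n: int, ts_weight: float):
    refs = rng.choice(np.array(list("ACGT")), size=n)
    is_ts = rng.random(n) < ts_weight / (ts_weight + 2.0)
    alts = np.empty(n, dtype="<U1")
    tv_pick = rng.integers(0, 2, size=n)
    for i, r in enumerate(refs):
        alts[i] = _TRANSITION[r] if is_ts[i] else _TRANSVERSIONS[r][tv_pick[i]]
    return refs, alts


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    lam = (1.0 - f) / f
    return rng.beta(p * lam, (1.0 - p) * lam)


def simulate_structured_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate a structured diploid panel under the Balding–Nichols model.

    Each site draws an ancestral frequency p ~ Uniform(low, high); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are
    binomial(2, p_pop) per sample, then missingness and Poisson depths are
    injected. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 11]))
    rows = []
    for chrom, length in config.chrom_lengths.items():
        n = int(round(length * config.snp_density))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False))
        refs, alts = _draw_alleles(rng, n, config.ts_weight)
        for p_, r_, a_ in zip(pos, refs, alts):
            rows.append((chrom, int(p_), r_, a_, None))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    m = len(sites)
    anc = rng.uniform(config.ancestral_low, config.ancestral_high, size=m)

    pops = list(config.pop_sizes)
    pop_freqs = {p: _balding_nichols(rng, anc, config.F[p]) for p in pops}
    for sw in config.sweeps:
        in_iv = ((sites.chrom == sw.chrom) & (sites.pos >= sw.start)
                 & (sites.pos < sw.end)).to_numpy()
        pop_freqs[sw.pop][in_iv] = _sweep_frequencies(
            pop_freqs[sw.pop][in_iv], sw.intensity, rng)

    samples, groups, blocks = [], {}, []
    for p in pops:
        n_p = config.pop_sizes[p]
        names = [f"{p}_{i:04d}" for i in range(n_p)]
        samples.extend(names)
        groups.update({s: p for s in names})
        blocks.append(rng.binomial(2, pop_freqs[p][None, :], size=(n_p, m)).astype(np.int8))
    dosage = np.concatenate(blocks, axis=0)
    depth = rng.poisson(config.depth_mean, size=dosage.shape).astype(np.int32)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = MISSING
    gm = GenotypeMatrix(samples, sites, dosage, depth)
    truth = TruthTable(ancestral_freq=anc, pop_freqs=pop_freqs, F=dict(config.F),
                       groups=groups, sweeps=list(config.sweeps))
    return gm, truth


def _sweep_frequencies(p: np.ndarray, intensity: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Hard-sweep frequency distortion for the focal population.

    A hard sweep fixes the alleles carried by the one haplotype the favored
    mutation arose on, so with probability ``intensity`` each site is driven
    to fixation at the allele of a randomly drawn focal haplotype (allele 1
    with probability p). Sites that escape fixation get partial hitchhiking:
    a multiplicative push toward the nearer boundary by (1 - intensity).
    Intensity 1 leaves the focal population monomorphic at every site;
    intensity 0 is the identity. Pushing only toward the nearer boundary
    cannot raise window FST above ~0.35, which is why escaped-site pushes
    alone would not reproduce the joint FST / pi-ratio sweep signature.
    """
    if intensity == 0.0:
        return p.copy()
    fixed = rng.random(len(p)) < intensity
    hitchhiker = (rng.random(len(p)) < p).astype(float)
    lower = p < 0.5
    pushed = np.where(lower, p * (1.0 - intensity),
                      1.0 - (1.0 - p) * (1.0 - intensity))
    return np.where(fixed, hitchhiker, pushed)


def plant_sweep(gm: GenotypeMatrix, truth: TruthTable, spec: SweepSpec,
                seed: int = 0) -> tuple[GenotypeMatrix, TruthTable]:
    """Distort focal-pop frequencies inside an interval and resample those genotypes.

    intensity 0 is a strict no-op (the input objects are returned unchanged);
    intensity 1 fixes the focal population at every site in the interval.
    """
    if spec.intensity == 0.0:
        return gm, truth
    in_iv = ((gm.sites.chrom == spec.chrom) & (gm.sites.pos >= spec.start)
             & (gm.sites.pos < spec.end)).to_numpy()
    if in_iv.sum() == 0 or spec.end - spec.start < 10_000:
        warnings.warn("sweep interval shorter than one window or without sites",
                      stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 13]))
    new_freqs = {p: f.copy() for p, f in truth.pop_freqs.items()}
    pushed = _sweep_frequencies(new_freqs[spec.pop][in_iv], spec.intensity, rng)
    new_freqs[spec.pop][in_iv] = pushed
    focal_rows = np.array([i for i, s in enumerate(gm.samples)
                           if truth.groups[s] == spec.pop])
    dosage = gm.dosage.copy()
    block = rng.binomial(2, pushed[None, :], size=(len(focal_rows), int(in_iv.sum())))
    was_missing = dosage[np.ix_(focal_rows, np.flatnonzero(in_iv))] == MISSING
    block = np.where(was_missing, MISSING, block).astype(np.int8)
    dosage[np.ix_(focal_rows, np.flatnonzero(in_iv))] = block
    gm2 = GenotypeMatrix(list(gm.samples), gm.sites.copy(), dosage,
                         None if gm.depth is None else gm.depth.copy())
    truth2 = TruthTable(ancestral_freq=truth.ancestral_freq, pop_freqs=new_freqs,
                        F=dict(truth.F), groups=dict(truth.groups),
                        sweeps=truth.sweeps + [spec],
                        causal_ids=truth.causal_ids,
                        causal_effects=truth.causal_effects,
                        genetic_values=truth.genetic_values)
    return gm2, truth2


def simulate_haplotype_ld(founders: int, recomb_prob: float, n_samples: int,
                          positions: np.ndarray, seed: int = 0,
                          chrom: str = "Chr1") -> GenotypeMatrix:
    """Diploid panel built by copying haplotypes from a founder pool.

    Each sample haplotype copies one of ``founders`` source haplotypes,
    switching to a uniformly chosen founder between adjacent sites with
    probability 1 - (1 - recomb_prob)^gap. Mean r^2 then decays with distance
    toward the finite-sample baseline; recomb_prob = 0 leaves all sites in
    complete LD within each founder class.
    """
    if founders < 2:
        raise ValueError("need >= 2 founders")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17]))
    positions = np.asarray(sorted(int(p) for p in positions))
    m = len(positions)
    pool = rng.integers(0, 2, size=(founders, m), dtype=np.int8)
    n_hap = 2 * n_samples
    idx = rng.integers(0, founders, size=n_hap)
    haps = np.empty((n_hap, m), dtype=np.int8)
    haps[:, 0] = pool[idx, 0]
    for j in range(1, m):
        gap = positions[j] - positions[j - 1]
        p_switch = 1.0 - (1.0 - recomb_prob) ** gap
        sw = rng.random(n_hap) < p_switch
        idx = np.where(sw, rng.integers(0, founders, size=n_hap), idx)
        haps[:, j] = pool[idx, j]
    dosage = haps[0::2] + haps[1::2]
    refs, alts = _draw_alleles(rng, m, 3.8)
    sites = pd.DataFrame({"chrom": chrom, "pos": positions, "ref": refs,
                          "alt": alts, "id": None})
    samples = [f"LD_{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, sites, dosage.astype(np.int8))


def simulate_trait(gm: GenotypeMatrix, spec: TraitSpec, seed: int = 0,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate phenotypes y_ij = mu + env_j + g_i + eps_ij across environments.

    g_i = sum_k effect_k * dosage_ik (missing dosages mean-imputed); the
    residual variance is sigma_g^2 (1 - h2) / h2 so one observation has
    heritability h2. Returns the tidy phenotype table and the true genetic
    values (series indexed by accession).
    """
    bad = [j for j in spec.causal_ids if not 0 <= j < gm.n_sites]
    if bad:
        raise ValueError(f"causal site ids out of range: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 19]))
    X = gm.dosage_float()[:, list(spec.causal_ids)]
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(col_mean, np.nonzero(nan)[1])
    g = X @ np.asarray(spec.effects, dtype=float)
    var_g = float(np.var(g))
    if spec.h2 == 0.0:
        if any(e != 0 for e in spec.effects):
            warnings.warn("h2 = 0 with nonzero effects: residual variance "
                          "defaults to 1 (trait units^2)", stacklevel=2)
        sigma_e2 = 1.0
        g = np.zeros_like(g)
    elif spec.h2 == 1.0:
        sigma_e2 = 0.0
    else:
        sigma_e2 = var_g * (1.0 - spec.h2) / spec.h2 if var_g > 0 else 1.0
    if spec.env_effects is not None:
        env_eff = np.asarray(spec.env_effects, dtype=float)
    else:
        env_eff = rng.normal(0.0, 0.5, size=spec.n_envs)
    records = []
    for j in range(spec.n_envs):
        eps = (rng.normal(0.0, np.sqrt(sigma_e2), size=gm.n_samples)
               if sigma_e2 > 0 else np.zeros(gm.n_samples))
        y = spec.mu + env_eff[j] + g + eps
        for i, s in enumerate(gm.samples):
            records.append((s, f"E{j + 1}", spec.trait, y[i]))
    pt = pd.DataFrame(records, columns=["accession", "environment", "trait", "value"])
    return pt, pd.Series(g, index=gm.samples, name="genetic_value")


def neutral_window_dosages(n_samples: int, n_sites: int,
                           rng: np.random.Generator) -> np.ndarray:
    """One window of diploid dosages whose allele counts follow the neutral SFS.

    Derived allele counts k in {1..2n-1} are drawn with probability
    proportional to 1/k and assigned to random haplotypes, which are then
    paired into diploids; the expected Tajima's D of such windows is 0.
    """
    n_hap = 2 * n_samples
    ks = np.arange(1, n_hap)
    probs = (1.0 / ks) / np.sum(1.0 / ks)
    counts = rng.choice(ks, size=n_sites, p=probs)
    haps = np.zeros((n_hap, n_sites), dtype=np.int8)
    for j, k in enumerate(counts):
        carriers = rng.choice(n_hap, size=k, replace=False)
        haps[carriers, j] = 1
    return (haps[0::2] + haps[1::2]).astype(np.int8)


# ---------------------------------------------------------------------------
# Fixture bundle

def make_tiling_genes(chrom: str, start: int, end: int, prefix: str,
                      gene_len: int = 2400, spacing: int = 10_000,
                      strand: str = "+") -> list[GeneModel]:
    """Two-exon genes (CDS length divisible by 3) tiling [start, end) every ``spacing`` bp."""
    genes = []
    i = 0
    pos = start
    while pos + gene_len <= end:
        exon1 = (pos, pos + gene_len // 2)
        intron_end = pos + gene_len // 2 + 300
        exon2 = (intron_end, pos + gene_len + 300)
        e1len = exon1[1] - exon1[0]
        phase2 = (3 - e1len % 3) % 3
        genes.append(GeneModel(
            gene_id=f"{prefix}{i:03d}", chrom=chrom, strand=strand,
            start=exon1[0], end=exon2[1],
            exons=(exon1, exon2),
            cds=((exon1[0], exon1[1], 0), (exon2[0], exon2[1], phase2)),
        ))
        i += 1
        pos += spacing
    return genes


def write_fixtures(outdir, gm: GenotypeMatrix, truth: TruthTable,
                   genes: list[GeneModel] | None = None,
                   phenotypes: pd.DataFrame | None = None,
                   chrom_lengths: dict[str, int] | None = None,
                   seed: int = 0, force: bool = False) -> dict[str, str]:
    """Write VCF + GFF3 + FASTA + phenotype CSV + groups CSV + truth JSON.

    The FASTA is random sequence with the REF base placed at every SNP
    position so coding-effect annotation round-trips. Refuses to write into a
    non-empty directory unless ``force``.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (pass force=True)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 23]))
    lengths = chrom_lengths or gm.chrom_lengths()
    paths = {}

    write_vcf(gm, outdir / "genotypes.vcf", contig_lengths=lengths)
    paths["vcf"] = str(outdir / "genotypes.vcf")

    if genes is None:
        genes = []
        for sw in truth.sweeps:
            genes += make_tiling_genes(sw.chrom, sw.start, sw.end, f"SW{sw.pop}_")
    write_gff(genes, outdir / "genes.gff3")
    paths["gff"] = str(outdir / "genes.gff3")

    seqs = {}
    for chrom, L in lengths.items():
        seq = rng.choice(np.array(list("ACGT")), size=L)
        sub = gm.sites[gm.sites.chrom == chrom]
        seq[sub.pos.to_numpy()] = sub.ref.to_numpy()
        seqs[chrom] = "".join(seq)
    write_fasta(seqs, outdir / "reference.fa")
    paths["fasta"] = str(outdir / "reference.fa")

    if phenotypes is not None:
        phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        paths["phenotypes"] = str(outdir / "phenotypes.csv")

    groups_df = pd.DataFrame(sorted(truth.groups.items()), columns=["accession", "group"])
    groups_df.to_csv(outdir / "groups.csv", index=False)
    paths["groups"] = str(outdir / "groups.csv")

    truth_json = {
        "F": truth.F,
        "sweeps": [{"pop": s.pop, "chrom": s.chrom, "start": s.start,
                    "end": s.end, "intensity": s.intensity} for s in truth.sweeps],
        "causal_sites": [
            {"index": int(j), "locus_id": gm.site_at(int(j)).locus_id, "effect": float(e)}
            for j, e in zip(truth.causal_ids, truth.causal_effects)],
        "genes": [g.gene_id for g in genes],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    paths["truth"] = str(outdir / "truth.json")
    return paths
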