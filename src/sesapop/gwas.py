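"""Mixed-model association: multi-environment BLUPs, kinship, and an
EMMAX-style genome scan.

The association model is y = X b + u + e with u ~ N(0, sg^2 K) for a
standardized genomic relationship matrix K. The null variance components
(sg^2, se^2) are estimated once by spectral REML (eigendecompose K, profile
the restricted likelihood over delta = se^2/sg^2); each SNP is then tested by
generalized least squares under the fixed V-hat = sg^2 K + se^2 I with a Wald
t-test -- the EMMAX approximation. An exact mode re-optimizes delta per SNP
(full per-SNP REML) for cross-checking.

``BlupModel``/``MixedModelGWAS`` follow the Model -> fit() -> Results idiom:
construct from data, fit, and read estimates off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats import GeneModel, GenotypeMatrix

DELTA_LOG10_BOUNDS = (-5.0, 5.0)
DELTA_GRID_POINTS = 100
SIGNIFICANCE_NEGLOG10P = 6.0
LD_WINDOW_BP = 89_000
CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


# ---------------------------------------------------------------------------
# Multi-environment BLUP

class BlupModel:
    """Across-environment BLUP of accession genetic values.

    Model: value_ij = mu + env_j (fixed) + g_i (random, sigma_a^2) + eps_ij.
    Variance components by REML (statsmodels MixedLM); the fitted accession
    value is mu-bar + BLUP(g_i), with mu-bar the fixed-effect prediction at
    the average environment.
    """

    def __init__(self, phenotypes: pd.DataFrame, trait: str):
        self.data = phenotypes[phenotypes.trait == trait].copy()
        if self.data.empty:
            raise ValueError(f"no records for trait {trait!r}")
        self.trait = trait
        self.n_envs = self.data.environment.nunique()
        if self.data.accession.nunique() < 2:
            raise ValueError("need >= 2 accessions")

    def fit(self) -> "BlupResults":
        data = self.data
        if self.n_envs < 2:
            warnings.warn("single environment: returning centered values, no "
                          "shrinkage", stacklevel=2)
            vals = data.groupby("accession").value.mean()
            return BlupResults(self, vals - vals.mean() + vals.mean(),
                               sigma_a2=float("nan"), sigma_e2=float("nan"),
                               converged=True)
        # env-adjusted residual variance ~ 0 -> noiseless fast path (REML is
        # unstable at the boundary); the adjusted accession mean is the BLUP
        env_mean = data.groupby("environment").value.transform("mean")
        adj = data.value - env_mean + data.value.mean()
        resid_within = adj - adj.groupby(data.accession).transform("mean")
        if float(np.var(resid_within)) < 1e-12 * max(1.0, float(np.var(adj))):
            vals = adj.groupby(data.accession).mean()
            vals.index.name = "accession"
            return BlupResults(self, vals, sigma_a2=float(np.var(adj)),
                               sigma_e2=0.0, converged=True)
        import statsmodels.formula.api as smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("value ~ C(environment)", data, groups=data.accession)
            res = md.fit(reml=True)
        sigma_a2 = float(res.cov_re.iloc[0, 0])
        sigma_e2 = float(res.scale)
        fe = res.fe_params
        env_cols = [c for c in fe.index if c.startswith("C(environment)")]
        mu_bar = float(fe["Intercept"] + np.sum([fe[c] for c in env_cols]) / self.n_envs)
        re = {acc: float(v.iloc[0]) for acc, v in res.random_effects.items()}
        vals = pd.Series({acc: mu_bar + re.get(acc, 0.0)
                          for acc in data.accession.unique()}, name="blup")
        vals.index.name = "accession"
        return BlupResults(self, vals.sort_index(), sigma_a2, sigma_e2,
                           converged=bool(res.converged))


@dataclass
class BlupResults:
    model: BlupModel
    values: pd.Series          # fitted value per accession (trait units)
    sigma_a2: float
    sigma_e2: float
    converged: bool

    @property
    def heritability_of_mean(self) -> float:
        r = self.model.n_envs
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2 / r)

    def summary(self) -> str:
        return (f"BLUP of {self.model.trait!r} across {self.model.n_envs} "
                f"environments, {len(self.values)} accessions\n"
                f"  sigma_a^2 = {self.sigma_a2:.4g}  sigma_e^2 = {self.sigma_e2:.4g}\n"
                f"  shrinkage toward the mean uses factor "
                f"sigma_a^2/(sigma_a^2 + sigma_e^2/r), r = {self.model.n_envs}")


def blup_phenotype(phenotypes: pd.DataFrame, trait: str) -> pd.Series:
    """Functional wrapper: per-accession BLUP values for one trait."""
    return BlupModel(phenotypes, trait).fit().values


def phenotype_summary(phenotypes: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-environment min, max, mean, CV% (sample sd) for one trait."""
    sub = phenotypes[phenotypes.trait == trait]
    rows = []
    for env, grp in sub.groupby("environment"):
        v = grp.value.to_numpy(dtype=float)
        if len(v) == 0:
            warnings.warn(f"environment {env!r} empty for {trait!r}", stacklevel=2)
            continue
        mean = v.mean()
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        rows.append({"environment": env, "n": len(v), "min": v.min(),
                     "max": v.max(), "mean": mean, "cv_percent": cv})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kinship and PCA

def _imputed_standardized(gm: GenotypeMatrix, sample_idx=None):
    X = gm.dosage_float(sample_idx)
    p = np.nanmean(X, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic sites present: filter before kinship/scan")
    nan = np.isnan(X)
    X[nan] = np.take(2.0 * p, np.nonzero(nan)[1])
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return X, Z


def kinship_matrix(gm: GenotypeMatrix, sample_idx=None) -> np.ndarray:
    """Standardized (VanRaden) GRM: K = Z Z^T / m over mean-imputed dosages."""
    _, Z = _imputed_standardized(gm, sample_idx)
    return Z @ Z.T / Z.shape[1]


def pca(K: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of a kinship matrix.

    Returns (components, eigenvalues) with components scaled by
    sqrt(eigenvalue) -- the usual PC scores for stratification plots.
    """
    n = K.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k), vals_k


# ---------------------------------------------------------------------------
# Spectral REML for the null model

@dataclass
class NullModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float                 # se^2 / sg^2
    reml_loglik: float
    eigenvalues: np.ndarray      # of K
    eigenvectors: np.ndarray
    X: np.ndarray                # fixed-effect design (rotated lazily by users)
    boundary: bool = False

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _reml_neg_loglik(log10_delta: float, s: np.ndarray, yt: np.ndarray,
                     Xt: np.ndarray, logdet_xtx: float) -> float:
    delta = 10.0 ** log10_delta
    d = s + delta
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / d))
    n, q = Xt.shape
    df = n - q
    sigma = rss / df
    ll = -0.5 * (df * np.log(2 * np.pi * sigma) + np.sum(np.log(d))
                 + np.linalg.slogdet(A)[1] - logdet_xtx + df)
    return -ll


def fit_null_mlm(y: np.ndarray, K: np.ndarray,
                 covariates: np.ndarray | None = None) -> NullModelFit:
    """Spectral REML fit of y = X b + u + e, u ~ N(0, sg^2 K).

    Eigendecomposes K once, profiles the restricted likelihood over log10
    delta on a 100-point grid in [-5, 5], then refines with bounded scalar
    minimization (tolerance 1e-6). An intercept is always included.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("y length does not match K")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6:
        raise ValueError(f"K is not PSD (min eigenvalue {s.min():.3g})")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    logdet_xtx = np.linalg.slogdet(X.T @ X)[1]
    lo, hi = DELTA_LOG10_BOUNDS
    grid = np.linspace(lo, hi, DELTA_GRID_POINTS)
    vals = [_reml_neg_loglik(g, s, yt, Xt, logdet_xtx) for g in grid]
    j = int(np.argmin(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(a, b), args=(s, yt, Xt, logdet_xtx),
        method="bounded", options={"xatol": 1e-6})
    best = res.x if res.fun <= vals[j] else grid[j]
    boundary = j in (0, len(grid) - 1)
    if boundary:
        warnings.warn("delta at grid boundary: variance-component split is "
                      "weakly identified", stacklevel=2)
    delta = 10.0 ** best
    d = s + delta
    Xw = Xt / d[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma_g2 = float(resid @ (resid / d)) / (n - X.shape[1])
    return NullModelFit(sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta, delta=delta,
                        reml_loglik=-float(res.fun), eigenvalues=s, eigenvectors=U,
                        X=X, boundary=boundary)


# ---------------------------------------------------------------------------
# EMMAX scan

def emmax_scan(gm: GenotypeMatrix, y: np.ndarray, null: NullModelFit,
               sample_idx=None, mode: str = "emmax") -> pd.DataFrame:
    """Per-SNP association under the fitted mixed model.

    ``mode="emmax"`` holds V-hat from the null and runs GLS with a Wald
    t-test (df = n - rank(X) - 1); ``mode="exact"`` re-optimizes delta per
    SNP (full per-SNP REML), used as the slow cross-checking oracle.
    Collinear/monomorphic SNPs get p = 1 and a flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_imp = gm.dosage_float(sample_idx)
    p_site = np.nanmean(X_imp, axis=0) / 2.0
    nan = np.isnan(X_imp)
    X_imp[nan] = np.take(2.0 * p_site, np.nonzero(nan)[1])
    n, m = X_imp.shape
    U, s, X = null.eigenvectors, null.eigenvalues, null.X
    d = s + null.delta
    yt = U.T @ y
    Xt = U.T @ X
    Gt = U.T @ X_imp
    q = X.shape[1]
    w = 1.0 / d
    A = Xt.T @ (Xt * w[:, None])                      # q x q
    Ainv = np.linalg.inv(A)
    u_vec = Xt.T @ (yt * w)                           # q
    yWy = float(yt @ (yt * w))
    B = Xt.T @ (Gt * w[:, None])                      # q x m
    c_vec = np.einsum("ij,ij->j", Gt, Gt * w[:, None])
    v_vec = Gt.T @ (yt * w)
    AinvB = Ainv @ B
    denom = c_vec - np.einsum("ij,ij->j", B, AinvB)
    bad = denom <= 1e-12 * np.maximum(c_vec, 1.0)
    denom_safe = np.where(bad, 1.0, denom)
    beta_snp = (v_vec - B.T @ (Ainv @ u_vec)) / denom_safe
    beta_cov = Ainv @ (u_vec[:, None] - B * beta_snp[None, :])   # q x m
    rss = yWy - np.einsum("i,ij->j", u_vec, beta_cov) - v_vec * beta_snp
    df = n - q - 1
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / denom_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta_snp / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta_snp[bad] = 0.0
    se[bad] = np.nan
    pvals[bad] = 1.0

    if mode == "exact":
        for j in range(m):
            if bad[j]:
                continue
            fit_j = fit_null_mlm(y, U @ np.diag(s) @ U.T,
                                 covariates=np.column_stack(
                                     [X[:, 1:], X_imp[:, j]])
                                 if q > 1 else X_imp[:, j:j + 1])
            dj = s + fit_j.delta
            Xa = np.column_stack([X, X_imp[:, j]])
            Xat = U.T @ Xa
            wj = 1.0 / dj
            Aj = Xat.T @ (Xat * wj[:, None])
            Ajinv = np.linalg.inv(Aj)
            betaj = Ajinv @ (Xat.T @ (yt * wj))
            residj = yt - Xat @ betaj
            sig = float(residj @ (residj * wj)) / (n - q - 1)
            sej = np.sqrt(sig * Ajinv[-1, -1])
            tj = betaj[-1] / sej
            beta_snp[j], se[j] = betaj[-1], sej
            pvals[j] = 2.0 * stats.t.sf(abs(tj), n - q - 1)
    elif mode != "emmax":
        raise ValueError(f"unknown mode {mode!r}")

    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out = gm.sites[["chrom", "pos", "ref", "alt"]].copy()
    out["pos"] = out.pos + 1  # 1-based on output
    out["id"] = [gm.site_at(j).locus_id for j in range(m)]
    out["beta"] = beta_snp
    out["se"] = se
    out["p_value"] = pvals
    out["minus_log10_p"] = -np.log10(pvals)
    out["flag_collinear"] = bad
    return out


def genomic_inflation(results: pd.DataFrame | np.ndarray) -> float:
    """Lambda-GC: median chi-square quantile of the p-values / 0.4549."""
    p = results["p_value"].to_numpy() if isinstance(results, pd.DataFrame) else np.asarray(results)
    if len(p) < 100:
        raise ValueError("need >= 100 tests for genomic inflation")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def significant_loci(results: pd.DataFrame,
                     threshold: float = SIGNIFICANCE_NEGLOG10P,
                     collapse_bp: int = LD_WINDOW_BP) -> pd.DataFrame:
    """Sites with -log10 p strictly above threshold, collapsed to peak per locus.

    Significant sites within one LD window (+-collapse_bp) of a stronger site
    on the same chromosome are absorbed into that locus.
    """
    sig = results[results.minus_log10_p > threshold].copy()
    sig = sig.sort_values("p_value")
    kept = []
    for _, row in sig.iterrows():
        if any(k.chrom == row.chrom and abs(k.pos - row.pos) <= collapse_bp
               for k in kept):
            continue
        kept.append(row)
    loci = pd.DataFrame(kept).reset_index(drop=True)
    return loci if not loci.empty else sig.head(0)


def candidate_window(chrom: str, pos_1based: int, genes: list[GeneModel],
                     half_width: int = LD_WINDOW_BP) -> list[str]:
    """Gene ids overlapping the +-half_width LD window around a locus."""
    lo = pos_1based - 1 - half_width
    hi = pos_1based + half_width
    return sorted(g.gene_id for g in genes
                  if g.chrom == chrom and g.start < hi and lo < g.end)


# ---------------------------------------------------------------------------
# Model / Results facade

class MixedModelGWAS:
    """EMMAX-style mixed-model genome scan.

    Parameters
    ----------
    gm : filtered genotype matrix
    y : phenotype per sample (BLUP values), aligned to ``gm.samples`` or a
        pandas Series indexed by accession
    K : kinship; computed from ``gm`` when omitted
    covariates : optional fixed covariates (e.g. PCs); intercept is implicit
    """

    def __init__(self, gm: GenotypeMatrix, y, K: np.ndarray | None = None,
                 covariates: np.ndarray | None = None):
        self.gm = gm
        if isinstance(y, pd.Series):
            missing = [s for s in gm.samples if s not in y.index]
            if missing:
                raise ValueError(f"{len(missing)} samples lack phenotype values")
            y = y.reindex(gm.samples).to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if len(self.y) != gm.n_samples:
            raise ValueError("phenotype length != sample count")
        self.K = kinship_matrix(gm) if K is None else K
        self.covariates = covariates

    def fit(self, mode: str = "emmax") -> "GWASResults":
        null = fit_null_mlm(self.y, self.K, self.covariates)
        table = emmax_scan(self.gm, self.y, null, mode=mode)
        return GWASResults(self, null, table)


@dataclass
class GWASResults:
    model: MixedModelGWAS
    null: NullModelFit
    table: pd.DataFrame

    @property
    def lambda_gc(self) -> float:
        return genomic_inflation(self.table)

    def significant_loci(self, threshold: float = SIGNIFICANCE_NEGLOG10P,
                         collapse_bp: int = LD_WINDOW_BP) -> pd.DataFrame:
        return significant_loci(self.table, threshold, collapse_bp)

    def candidate_genes(self, genes: list[GeneModel],
                        threshold: float = SIGNIFICANCE_NEGLOG10P,
                        half_width: int = LD_WINDOW_BP) -> pd.DataFrame:
        loci = self.significant_loci(threshold)
        rows = []
        for _, row in loci.iterrows():
            for gid in candidate_window(row.chrom, int(row.pos), genes, half_width):
                rows.append({"locus": row.id, "chrom": row.chrom,
                             "pos": int(row.pos), "gene_id": gid})
        return pd.DataFrame(rows, columns=["locus", "chrom", "pos", "gene_id"])

    def qq_data(self) -> pd.DataFrame:
        p = np.sort(self.table.p_value.to_numpy())
        n = len(p)
        expected = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame({"expected_minus_log10_p": -np.log10(expected),
                             "observed_minus_log10_p": -np.log10(p)})

    def summary(self) -> str:
        n_sig = int((self.table.minus_log10_p > SIGNIFICANCE_NEGLOG10P).sum())
        return (f"Mixed-model scan: {self.model.gm.n_samples} samples, "
                f"{len(self.table)} SNPs\n"
                f"  sigma_g^2 = {self.null.sigma_g2:.4g}  "
                f"sigma_e^2 = {self.null.sigma_e2:.4g}  "
                f"h2 = {self.null.heritability:.3f}\n"
                f"  lambda_GC = {self.lambda_gc:.3f}; {n_sig} SNPs with "
                f"-log10 p > {SIGNIFICANCE_NEGLOG10P:g}")
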