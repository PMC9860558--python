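"""BLUP, kinship/PCA, spectral REML, and the EMMAX scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

import sesapop as sp
from sesapop.gwas import (BlupModel, MixedModelGWAS, candidate_window,
                          fit_null_mlm, genomic_inflation, kinship_matrix, pca,
                          phenotype_summary, significant_loci)

from conftest import make_gm


def sim_panel(n_per_pop=100, m_density=0.005, F=0.1, seed=0, length=100_000):
    cfg = sp.SimConfig(pop_sizes={"A": n_per_pop, "B": n_per_pop}, F=F,
                       chrom_lengths={"Chr1": length}, snp_density=m_density,
                       missing_rate=0.0, seed=seed)
    gm, truth = sp.simulate_structured_genotypes(cfg)
    return sp.filter_sites(gm, depth_min=0)[0], truth


class TestBlup:
    def _balanced(self, seed=1, r=2, n=40, sa=1.0, se=1.0):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(sa), n)
        recs = []
        for j in range(r):
            for i in range(n):
                recs.append((f"a{i:03d}", f"E{j + 1}", "sesamin",
                             2.5 + 0.4 * j + g[i] + rng.normal(0, np.sqrt(se))))
        return pd.DataFrame(recs, columns=["accession", "environment",
                                           "trait", "value"]), g

    def test_noiseless_equals_env_adjusted_mean(self):
        pt, g = self._balanced(se=0.0)
        pt["value"] = pt.value.round(12)
        res = BlupModel(pt, "sesamin").fit()
        adj = pt.value - pt.groupby("environment").value.transform("mean") \
            + pt.value.mean()
        expected = adj.groupby(pt.accession).mean()
        np.testing.assert_allclose(res.values.sort_index(),
                                   expected.sort_index(), atol=1e-9)

    def test_balanced_closed_form_shrinkage(self):
        """BLUP deviations equal sigma_a^2/(sigma_a^2 + sigma_e^2/r) times the
        env-adjusted accession-mean deviations (balanced case)."""
        pt, _ = self._balanced()
        res = BlupModel(pt, "sesamin").fit()
        r = 2
        shrink = res.sigma_a2 / (res.sigma_a2 + res.sigma_e2 / r)
        adj = pt.value - pt.groupby("environment").value.transform("mean") \
            + pt.value.mean()
        means = adj.groupby(pt.accession).mean()
        expected = means.mean() + shrink * (means - means.mean())
        np.testing.assert_allclose(res.values.sort_index(),
                                   expected.sort_index(), atol=1e-6)

    def test_single_environment_warns_and_centers(self):
        pt, _ = self._balanced(r=1)
        with pytest.warns(UserWarning, match="single environment"):
            res = BlupModel(pt, "sesamin").fit()
        assert len(res.values) == 40

    def test_blup_beats_raw_mean_unbalanced(self):
        """With unbalanced environments the env-adjusted BLUP correlates with
        the true genetic value better than the raw accession mean."""
        wins = 0
        reps = 25
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            n, r = 80, 6
            g = rng.normal(0, 1, n)
            env = rng.normal(0, 1.5, r)
            recs = []
            for j in range(r):
                for i in range(n):
                    if rng.random() < 0.35:     # missing visits
                        continue
                    recs.append((f"a{i:03d}", f"E{j}", "t",
                                 2.5 + env[j] + g[i] + rng.normal()))
            pt = pd.DataFrame(recs, columns=["accession", "environment",
                                             "trait", "value"])
            keep = pt.accession.value_counts()
            pt = pt[pt.accession.isin(keep[keep >= 1].index)]
            idx = sorted(pt.accession.unique())
            gser = pd.Series(g, index=[f"a{i:03d}" for i in range(n)])[idx]
            blup = sp.blup_phenotype(pt, "t")[idx]
            raw = pt.groupby("accession").value.mean()[idx]
            wins += (np.corrcoef(blup, gser)[0, 1]
                     > np.corrcoef(raw, gser)[0, 1])
        assert wins / reps >= 0.9

    def test_phenotype_summary_cv(self):
        pt = pd.DataFrame({"accession": list("abc"), "environment": "E1",
                           "trait": "t", "value": [1.0, 2.0, 3.0]})
        s = phenotype_summary(pt, "t")
        assert s.cv_percent.iloc[0] == pytest.approx(50.0)
        pt2 = pt.assign(value=[2.0, 2.0, 2.0])
        assert phenotype_summary(pt2, "t").cv_percent.iloc[0] == 0.0


class TestKinshipPca:
    def test_duplicated_sample_matches_diagonal(self):
        gm, _ = sim_panel(n_per_pop=20, seed=5)
        dosage = np.vstack([gm.dosage, gm.dosage[:1]])
        gm2 = make_gm(dosage, positions=gm.sites.pos.to_numpy(),
                      refs=list(gm.sites.ref), alts=list(gm.sites.alt))
        K = kinship_matrix(gm2)
        assert K[0, -1] == pytest.approx(K[0, 0])

    def test_unrelated_mean_offdiag_near_zero(self):
        cfg = sp.SimConfig(pop_sizes={"A": 60}, F=0.0,
                           chrom_lengths={"Chr1": 2_000_000},
                           snp_density=0.005, missing_rate=0.0, seed=6)
        gm, _ = sp.simulate_structured_genotypes(cfg)
        gm, _ = sp.filter_sites(gm, depth_min=0)
        K = kinship_matrix(gm)
        off = K[~np.eye(len(K), dtype=bool)]
        assert abs(off.mean()) < 0.02
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)

    def test_leading_eigenvector_separates_pops(self):
        gm, truth = sim_panel(n_per_pop=40, F=0.15, seed=7)
        K = kinship_matrix(gm)
        pcs, _ = pca(K, 1)
        labels = np.array([truth.groups[s] for s in gm.samples])
        a = pcs[labels == "A", 0]
        b = pcs[labels == "B", 0]
        assert (a.mean() - b.mean()) ** 2 > 4 * (a.var() + b.var())

    def test_three_pop_silhouette(self):
        from sklearn.metrics import silhouette_score

        cfg = sp.SimConfig(pop_sizes={"A": 40, "B": 40, "C": 40}, F=0.15,
                           chrom_lengths={"Chr1": 200_000}, snp_density=0.01,
                           missing_rate=0.0, seed=8)
        gm, truth = sp.simulate_structured_genotypes(cfg)
        gm, _ = sp.filter_sites(gm, depth_min=0)
        pcs, _ = pca(kinship_matrix(gm), 2)
        labels = [truth.groups[s] for s in gm.samples]
        assert silhouette_score(pcs, labels) > 0.5

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            pca(np.eye(4), 5)


class TestNullModel:
    def test_pure_noise_gives_small_heritability(self):
        h2s = []
        for seed in range(10):
            gm, _ = sim_panel(n_per_pop=60, F=0.0, seed=40 + seed)
            rng = np.random.default_rng(seed)
            y = rng.normal(size=gm.n_samples)
            K = kinship_matrix(gm)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")   # delta often at boundary here
                null = fit_null_mlm(y, K)
            h2s.append(null.heritability)
        assert np.median(h2s) < 0.1

    def test_equal_variance_recovery(self):
        h2s = []
        for seed in range(10):
            gm, _ = sim_panel(n_per_pop=75, seed=60 + seed)
            K = kinship_matrix(gm)
            rng = np.random.default_rng(seed)
            L = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
            y = L @ rng.normal(size=len(K)) + rng.normal(size=len(K))
            null = fit_null_mlm(y, K)
            h2s.append(null.heritability)
        assert np.median(h2s) == pytest.approx(0.5, abs=0.15)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            fit_null_mlm(np.ones(10), np.eye(10))


class TestEmmaxScan:
    def test_identity_kinship_reduces_to_ols(self):
        """With K = I the mixed model is an ordinary regression: p-values
        match per-SNP OLS within 1e-8."""
        gm, _ = sim_panel(n_per_pop=50, F=0.0, seed=70)
        rng = np.random.default_rng(70)
        y = rng.normal(size=gm.n_samples) + 0.5 * gm.dosage_float()[:, 3]
        null = fit_null_mlm(y, np.eye(gm.n_samples))
        res = sp.emmax_scan(gm, y, null)
        for j in range(0, gm.n_sites, 7):
            x = gm.dosage_float()[:, j]
            lr = st.linregress(x, y)
            assert res.p_value.iloc[j] == pytest.approx(lr.pvalue, abs=1e-8)

    def test_collinear_snp_flagged(self):
        gm, _ = sim_panel(n_per_pop=30, seed=71)
        gm.dosage[:, 0] = 1  # constant after imputation -> collinear
        y = np.random.default_rng(0).normal(size=gm.n_samples)
        null = fit_null_mlm(y, np.eye(gm.n_samples))
        res = sp.emmax_scan(gm, y, null)
        assert res.p_value.iloc[0] == 1.0 and bool(res.flag_collinear.iloc[0])

    def test_structured_null_calibrated_where_ols_inflates(self):
        """Population structure: EMMAX lambda stays near 1 while naive OLS
        inflates past 1.2."""
        lams, ols = [], []
        for seed in range(8):
            gm, _ = sim_panel(n_per_pop=150, F=0.1, seed=80 + seed)
            rng = np.random.default_rng(seed)
            K = kinship_matrix(gm)
            L = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
            y = L @ rng.normal(size=len(K)) + rng.normal(size=len(K))
            null = fit_null_mlm(y, K)
            lams.append(genomic_inflation(sp.emmax_scan(gm, y, null)))
            X = gm.dosage_float()
            pv = [st.linregress(X[:, j], y).pvalue for j in range(gm.n_sites)]
            ols.append(genomic_inflation(np.array(pv)))
        assert 0.9 <= np.median(lams) <= 1.1
        assert np.median(ols) > 1.2


class TestDiagnostics:
    def test_uniform_p_lambda_one(self):
        rng = np.random.default_rng(1)
        assert genomic_inflation(rng.uniform(size=20_000)) == pytest.approx(1.0, abs=0.03)

    def test_halved_p_inflates(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20_000)
        assert genomic_inflation(p / 2) > 1.0

    def test_too_few_tests_error(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.full(10, 0.5))


class TestLoci:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "p_value"])
        df["minus_log10_p"] = -np.log10(df.p_value)
        return df

    def test_strict_threshold(self):
        df = self._results([("Chr1", 100, "a", 1e-7), ("Chr1", 500_000, "b", 1e-6)])
        loci = significant_loci(df)
        assert list(loci.id) == ["a"]   # 1e-6 exactly -> excluded by strict >

    def test_collapse_within_ld_window(self):
        df = self._results([("Chr1", 100_000, "a", 1e-9),
                            ("Chr1", 130_000, "b", 1e-8),   # 30 kb away
                            ("Chr1", 400_000, "c", 1e-8)])
        loci = significant_loci(df)
        assert list(loci.id) == ["a", "c"]

    def test_candidate_window_edge_inclusion(self):
        from sesapop.formats import GeneModel
        genes = [GeneModel("edge", "Chr1", "+", 188_999, 200_000,
                           exons=((188_999, 200_000),)),   # 1 bp overlap
                 GeneModel("out", "Chr1", "+", 189_000, 200_000,
                           exons=((189_000, 200_000),)),   # just past the edge
                 GeneModel("far", "Chr1", "+", 300_000, 310_000,
                           exons=((300_000, 310_000),))]
        got = candidate_window("Chr1", 100_000, genes)
        assert got == ["edge"]
        assert candidate_window("Chr2", 100_000, genes) == []


class TestEndToEndModel:
    def test_causal_gene_in_candidates(self):
        """A causal SNP planted inside a fixture gene surfaces that gene."""
        gm, truth = sim_panel(n_per_pop=150, F=0.05, seed=90, length=200_000)
        genes = sp.sim.make_tiling_genes("Chr1", 0, 200_000, "GENE",
                                         spacing=40_000)
        # pick a causal SNP inside the first gene
        g0 = genes[0]
        inside = np.flatnonzero((gm.sites.pos >= g0.start)
                                & (gm.sites.pos < g0.end))
        causal = int(inside[0])
        x = gm.dosage_float()[:, causal]
        rng = np.random.default_rng(91)
        y = 1.0 * x + rng.normal(0, np.sqrt(np.var(x) * 7 / 3), gm.n_samples)
        res = MixedModelGWAS(gm, y).fit()
        cands = res.candidate_genes(genes)
        assert "GENE000" in set(cands.gene_id)
        assert res.summary().startswith("Mixed-model scan")
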