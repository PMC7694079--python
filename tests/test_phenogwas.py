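import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beanpanel import (
    PhenoDesign, PhenotypeTable, SimParams, bic_select_pcs,
    bonferroni_threshold, gwas_scan, ls_means, pairwise_r2,
    permutation_threshold, rcbd_anova, simulate_panel, simulate_phenotypes,
    trait_correlations,
)
from conftest import make_matrix


def rcbd_table(values, trait="DTF"):
    """values: (accessions x blocks) array -> long PhenotypeTable."""
    n, b = values.shape
    rows = [(f"a{i}", j + 1, trait, values[i, j])
            for i in range(n) for j in range(b)]
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["accession", "block", "trait", "value"]))


@pytest.fixture(scope="module")
def qtl_panel():
    params = SimParams(n_meso=95, n_andean=5, n_chrom=2, snps_per_chrom=120,
                       chrom_length_bp=20_000_000, introgression=None, seed=31)
    G, meta, truth = simulate_panel(params)
    P = simulate_phenotypes(G, truth, seed=32)
    return G, truth, P


class TestRcbdAnova:
    def test_balanced_decomposition_is_additive(self):
        rng = np.random.default_rng(0)
        vals = 40 + rng.normal(0, 2, size=(15, 4)) \
            + rng.normal(0, 1, 15)[:, None] + rng.normal(0, 0.5, 4)[None, :]
        P = rcbd_table(vals)
        a = rcbd_anova(P, "DTF")
        ss_total = ((vals - vals.mean()) ** 2).sum()
        ss_model = (a.ms_cultivar * a.df_cultivar + a.ms_block * a.df_block
                    + a.ms_residual * a.df_residual)
        assert ss_model == pytest.approx(ss_total, abs=1e-8)
        assert a.balanced

    def test_h2_formula(self):
        rng = np.random.default_rng(1)
        vals = 40 + rng.normal(0, 1, size=(30, 4)) + rng.normal(0, 3, 30)[:, None]
        a = rcbd_anova(rcbd_table(vals), "DTF")
        assert a.h2 == pytest.approx(
            (a.ms_cultivar - a.ms_residual) / a.ms_cultivar)
        assert a.cv_percent == pytest.approx(
            100 * np.sqrt(a.ms_residual) / vals.mean())

    def test_pure_noise_has_no_heritability(self):
        rng = np.random.default_rng(2)
        vals = 50 + rng.normal(0, 2, size=(40, 4))
        a = rcbd_anova(rcbd_table(vals), "DTF")
        assert a.h2 <= 0.35
        assert a.shapiro_p > 0.001  # Gaussian residuals

    def test_simulator_h2_recovery(self, qtl_panel):
        """Target line-mean h2 ~ 0.78 is recovered within +-0.1."""
        _, truth, P = qtl_panel
        a = rcbd_anova(P, "DTF")
        assert a.h2 == pytest.approx(truth.simulated_h2["DTF"], abs=0.08)
        assert abs(a.h2 - 0.78) < 0.12

    def test_unbalanced_flagged(self):
        rng = np.random.default_rng(3)
        vals = 40 + rng.normal(0, 2, size=(10, 4))
        P = rcbd_table(vals)
        P2 = PhenotypeTable(P.table.iloc[1:].reset_index(drop=True))
        with pytest.warns(UserWarning, match="unbalanced"):
            a = rcbd_anova(P2, "DTF")
        assert not a.balanced


class TestLsMeans:
    def test_balanced_equals_arithmetic_means(self):
        rng = np.random.default_rng(4)
        vals = 40 + rng.normal(0, 2, size=(12, 4))
        P = rcbd_table(vals)
        lsm = ls_means(P, "DTF")
        arith = vals.mean(axis=1)
        for i in range(12):
            assert lsm[f"a{i}"] == pytest.approx(arith[i], abs=1e-12)

    def test_missing_plot_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        vals = 40 + rng.normal(0, 2, size=(6, 3))
        P = rcbd_table(vals)
        sub = P.table.drop(index=0).reset_index(drop=True)  # a0 misses block 1
        lsm = ls_means(PhenotypeTable(sub), "DTF")
        # normal-equations oracle: solve the full two-way design by lstsq
        accs = sorted(sub["accession"].unique())
        blocks = sorted(sub["block"].unique())
        Xd = []
        for _, r in sub.iterrows():
            row = np.zeros(1 + len(accs) + len(blocks))
            row[0] = 1
            row[1 + accs.index(r["accession"])] = 1
            row[1 + len(accs) + blocks.index(r["block"])] = 1
            Xd.append(row)
        Xd = np.array(Xd)
        beta, *_ = np.linalg.lstsq(Xd, sub["value"].to_numpy(), rcond=None)
        for i, a in enumerate(accs):
            expected = beta[0] + beta[1 + i] + beta[1 + len(accs):].mean()
            assert lsm[a] == pytest.approx(expected, abs=1e-8)
        raw_mean = sub[sub["accession"] == "a0"]["value"].mean()
        assert lsm["a0"] != pytest.approx(raw_mean, abs=1e-12)

    def test_constant_trait(self):
        vals = np.full((5, 3), 42.0)
        lsm = ls_means(rcbd_table(vals), "DTF")
        assert np.allclose(lsm.to_numpy(), 42.0)


class TestTraitCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        means = pd.DataFrame({"DTF": x, "COPY": x})
        t = trait_correlations(means)
        assert t.loc[0, "r"] == pytest.approx(1.0)

    def test_shared_qtl_induces_positive_correlation(self, qtl_panel):
        _, _, P = qtl_panel
        means = pd.DataFrame({t: ls_means(P, t) for t in ("DTF", "DTM")})
        t = trait_correlations(means)
        row = t.iloc[0]
        assert row["r"] > 0.2
        assert row["p"] < 0.01

    def test_zero_variance_flagged(self):
        means = pd.DataFrame({"A": np.ones(10), "B": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            t = trait_correlations(means)
        assert np.isnan(t.loc[0, "r"])


class TestBicSelection:
    def test_independent_phenotype_needs_no_pcs(self, qtl_panel):
        G, _, _ = qtl_panel
        rng = np.random.default_rng(7)
        y = rng.normal(size=G.n_accessions)
        assert bic_select_pcs(G, y, max_pcs=5) == 0

    def test_pc_driven_phenotype_selects_pcs(self, qtl_panel):
        from beanpanel import pca
        G, _, _ = qtl_panel
        scores, _ = pca(G, n_components=1)
        rng = np.random.default_rng(8)
        y = scores[:, 0] + rng.normal(0, 0.1 * scores[:, 0].std(),
                                      G.n_accessions)
        assert bic_select_pcs(G, y, max_pcs=5) >= 1

    def test_zero_max_pcs(self, qtl_panel):
        G, _, _ = qtl_panel
        assert bic_select_pcs(G, np.ones(G.n_accessions) + 0.1 *
                              np.arange(G.n_accessions), max_pcs=0) == 0


class TestGwasScan:
    def test_planted_qtl_is_top_hit(self, qtl_panel):
        G, truth, P = qtl_panel
        y = ls_means(P, "DTF").reindex(G.accessions).to_numpy()
        res = gwas_scan(G, y, n_pcs=0)
        top = res.table.sort_values("p").iloc[0]["snp"]
        qtl = [q["snp_id"] for q in truth.qtls if q["trait"] == "DTF"][0]
        if top != qtl:
            r2 = pairwise_r2(G).table
            link = r2[((r2["snp_a"] == top) & (r2["snp_b"] == qtl))
                      | ((r2["snp_b"] == top) & (r2["snp_a"] == qtl))]
            assert len(link) == 1 and link["r2"].iloc[0] >= 0.8
        else:
            assert top == qtl

    def test_permuted_phenotype_p_values_uniform(self, qtl_panel):
        """Under permutation the scan p-value at any SNP is uniform.

        p-values within one scan are dependent (they share the permuted
        phenotype), so calibration is checked across independent
        permutations, one SNP p-value per permutation."""
        from beanpanel.phenogwas import _scan_matrix
        G, _, P = qtl_panel
        rng = np.random.default_rng(9)
        y = ls_means(P, "DTF").reindex(G.accessions).to_numpy()
        Y = np.column_stack([rng.permutation(y) for _ in range(200)])
        _, _, pvals, _ = _scan_matrix(G, Y, n_pcs=0)
        snp_idx = rng.integers(0, G.n_snps, size=200)
        draws = pvals[snp_idx, np.arange(200)]
        ks = stats.kstest(draws, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_phenotype_flagged(self, qtl_panel):
        G, _, _ = qtl_panel
        with pytest.warns(UserWarning, match="constant"):
            res = gwas_scan(G, np.full(G.n_accessions, 5.0))
        assert (res.table["p"] == 1.0).all()

    def test_qtl_detection_power_at_bonferroni(self):
        """Power >= 0.9 for a 1-residual-sd QTL effect, n=140, 500 SNPs."""
        rng = np.random.default_rng(10)
        n, L = 140, 500
        d = 2.0 * (rng.random((n, L)) < rng.uniform(0.2, 0.8, L))
        G = make_matrix(d)
        thr = bonferroni_threshold(L, alpha=0.01)
        hits = 0
        reps = 40
        for rep in range(reps):
            j = int(rng.integers(L))
            y = d[:, j] * 1.0 + rng.normal(0, 1.0, n)
            res = gwas_scan(G, y)
            if res.table["p"].iloc[j] < thr:
                hits += 1
        assert hits / reps >= 0.9


class TestThresholds:
    def test_single_snp_threshold_matches_quantile_level(self):
        """With one SNP the min-p distribution is uniform, so the 5% quantile
        of min-p is ~0.05."""
        rng = np.random.default_rng(11)
        d = 2.0 * (rng.random((120, 1)) < 0.5)
        G = make_matrix(d)
        y = rng.normal(size=120)
        thr = permutation_threshold(G, y, n_perm=2000, seed=3)
        assert thr == pytest.approx(0.05, abs=0.02)

    def test_deterministic_given_seed(self, qtl_panel):
        G, _, P = qtl_panel
        y = ls_means(P, "DTF").reindex(G.accessions).to_numpy()
        t1 = permutation_threshold(G, y, n_perm=50, seed=5)
        t2 = permutation_threshold(G, y, n_perm=50, seed=5)
        assert t1 == t2

    def test_fwer_calibration(self):
        """The fraction of null scans whose min p beats the permutation
        threshold is ~5%."""
        rng = np.random.default_rng(12)
        n, L = 60, 50
        d = 2.0 * (rng.random((n, L)) < rng.uniform(0.2, 0.8, L))
        G = make_matrix(d)
        thr = permutation_threshold(G, rng.normal(size=n), n_perm=400, seed=6)
        from beanpanel.phenogwas import _scan_matrix
        Y = rng.normal(size=(n, 400))
        _, _, pvals, _ = _scan_matrix(G, Y, n_pcs=0)
        frac = (pvals.min(axis=0) < thr).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_low_n_perm_warns(self, qtl_panel):
        G, _, _ = qtl_panel
        rng = np.random.default_rng(13)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(G, rng.normal(size=G.n_accessions), n_perm=10)

    @pytest.mark.parametrize("n,alpha,expected", [
        (1927, 0.01, 0.01 / 1927), (1, 0.05, 0.05), (100, 0.0, 0.0)])
    def test_bonferroni(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_bonferroni_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
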