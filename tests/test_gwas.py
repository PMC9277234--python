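"""Variant filtering, kinship and mixed-model association."""

import numpy as np
import numpy.linalg as la
import pytest
from scipy import stats

from symbiopleio.config import SimConfig
from symbiopleio.datatypes import MISSING, DataError, GenotypePanel
from symbiopleio.gwas import (
    KinshipMatrix,
    LMMWorkspace,
    compute_kinship,
    filter_variants,
    lmm_association,
)
from symbiopleio.simulate import simulate_genotypes


def _panel(geno, **kw):
    s, l = geno.shape
    return GenotypePanel(
        genotypes=geno,
        strain_ids=[f"s{i}" for i in range(s)],
        replicon=np.array(["chromosome"] * l),
        pos=np.arange(1, l + 1),
        **kw,
    )


class TestFilterVariants:
    def test_rare_singleton_removed_at_default_maf(self, rng):
        geno = rng.integers(0, 2, size=(100, 5)).astype(np.int8)
        geno[:, 0] = 0
        geno[0, 0] = 1  # alt count 1/100 -> maf 0.01
        filtered, counts = filter_variants(_panel(geno), maf_min=0.05, miss_max=1.0)
        assert "chromosome:1" not in filtered.site_ids()
        assert counts["n_removed"] >= 1

    def test_noop_bounds_keep_everything_polymorphic(self, rng):
        geno = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
        # guarantee polymorphism
        geno[0] = 0
        geno[1] = 1
        filtered, counts = filter_variants(_panel(geno), maf_min=0.0, miss_max=1.0)
        assert counts["n_kept"] == 40

    def test_surviving_count_matches_brute_force_recount(self):
        cfg = SimConfig(n_strains=60, n_sites=400, seed=17, missing_rate=0.05,
                        n_concordant_pairs=0, n_discordant_pairs=0)
        panel = simulate_genotypes(cfg)
        filtered, counts = filter_variants(panel, maf_min=0.1, miss_max=0.05)
        survive = 0
        for j in range(panel.n_sites):  # independent per-site recount
            col = panel.genotypes[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            p = obs.mean()
            maf = min(p, 1 - p)
            miss = np.mean(col == MISSING)
            survive += maf >= 0.1 and miss <= 0.05
        assert counts["n_kept"] == survive

    def test_all_removed_raises(self, rng):
        geno = np.zeros((20, 5), dtype=np.int8)
        with pytest.raises(DataError):
            filter_variants(_panel(geno), maf_min=0.05, miss_max=1.0)


class TestKinship:
    def test_identical_strains_have_identical_rows(self, rng):
        geno = rng.integers(0, 2, size=(10, 200)).astype(np.int8)
        geno[3] = geno[7]
        k = compute_kinship(_panel(geno))
        np.testing.assert_allclose(k.matrix[3], k.matrix[7], atol=1e-12)

    def test_iid_panel_matches_analytic_expectation(self, rng):
        # Bernoulli(0.5) sites after column centering: E[diag] ~= p(1-p) = 0.25;
        # rows sum to zero exactly, so E[off-diag] = -E[diag]/(S-1)
        geno = (rng.random((50, 20000)) < 0.5).astype(np.int8)
        k = compute_kinship(_panel(geno)).matrix
        off = k[~np.eye(50, dtype=bool)]
        assert abs(np.diag(k).mean() - 0.25) < 0.01
        assert off.mean() == pytest.approx(-np.diag(k).mean() / 49, rel=1e-6)

    def test_strain_permutation_equivariance(self, rng):
        geno = rng.integers(0, 2, size=(12, 150)).astype(np.int8)
        k = compute_kinship(_panel(geno)).matrix
        perm = rng.permutation(12)
        k2 = compute_kinship(_panel(geno[perm])).matrix
        np.testing.assert_allclose(k2, k[np.ix_(perm, perm)], atol=1e-12)

    def test_symmetry_and_psd(self, small_kinship):
        k = small_kinship.matrix
        assert np.allclose(k, k.T, atol=1e-10)
        assert small_kinship.eigenvalues.min() > -1e-8


class TestLMM:
    def test_identity_kinship_reduces_to_ols(self, small_panel, rng):
        y = rng.standard_normal(small_panel.n_strains)
        res = lmm_association(y, small_panel, KinshipMatrix(np.eye(small_panel.n_strains)),
                              standardize=False)
        x0 = small_panel.imputed()
        for j in range(0, small_panel.n_sites, 17):
            X = np.column_stack([np.ones(len(y)), x0[:, j]])
            b, *_ = la.lstsq(X, y, rcond=None)
            r = y - X @ b
            C = la.inv(X.T @ X)
            se = np.sqrt(r @ r / (len(y) - 2) * C[1, 1])
            assert res.beta[j] == pytest.approx(b[1], rel=1e-8)
            assert res.se[j] == pytest.approx(se, rel=1e-8)

    def test_frozen_lambda_matches_explicit_gls_oracle(self, small_panel, small_kinship, rng):
        y = rng.standard_normal(small_panel.n_strains)
        lam = 1.3
        res = lmm_association(y, small_panel, small_kinship, lambda_fixed=lam, standardize=False)
        Vi = la.inv(lam * small_kinship.matrix + np.eye(len(y)))
        x0 = small_panel.imputed()
        for j in range(0, small_panel.n_sites, 11):
            X = np.column_stack([np.ones(len(y)), x0[:, j]])
            C = la.inv(X.T @ Vi @ X)
            b = C @ X.T @ Vi @ y
            r = y - X @ b
            se = np.sqrt((r @ Vi @ r) / (len(y) - 2) * C[1, 1])
            assert res.beta[j] == pytest.approx(b[1], rel=1e-8)
            assert res.se[j] == pytest.approx(se, rel=1e-8)

    def test_beta_flips_sign_under_allele_recoding(self, small_panel, small_kinship, rng):
        y = rng.standard_normal(small_panel.n_strains)
        res = lmm_association(y, small_panel, small_kinship, lambda_fixed=0.5)
        flipped = GenotypePanel(
            genotypes=(1 - small_panel.genotypes).astype(np.int8),
            strain_ids=small_panel.strain_ids,
            replicon=small_panel.replicon,
            pos=small_panel.pos,
        )
        res2 = lmm_association(y, flipped, small_kinship, lambda_fixed=0.5)
        np.testing.assert_allclose(res2.beta, -res.beta, atol=1e-10)

    def test_results_invariant_to_strain_and_site_order(self, small_panel, rng):
        y = rng.standard_normal(small_panel.n_strains)
        k = compute_kinship(small_panel)
        base = lmm_association(y, small_panel, k)
        perm_s = rng.permutation(small_panel.n_strains)
        perm_l = rng.permutation(small_panel.n_sites)
        shuffled = GenotypePanel(
            genotypes=small_panel.genotypes[np.ix_(perm_s, perm_l)],
            strain_ids=[small_panel.strain_ids[i] for i in perm_s],
            replicon=small_panel.replicon[perm_l],
            pos=small_panel.pos[perm_l],
        )
        res = lmm_association(y[perm_s], shuffled, compute_kinship(shuffled))
        merged = base.set_index("site_id").join(
            res.set_index("site_id"), lsuffix="_a", rsuffix="_b"
        )
        np.testing.assert_allclose(merged.beta_a, merged.beta_b, atol=1e-10)
        np.testing.assert_allclose(merged.p_wald_a, merged.p_wald_b, atol=1e-10)

    def test_se_scales_inverse_sqrt_sample_size(self):
        med = {}
        for s in (50, 200):
            cfg = SimConfig(n_strains=s, n_sites=300, seed=23, missing_rate=0.0,
                            n_concordant_pairs=0, n_discordant_pairs=0)
            panel, _ = filter_variants(simulate_genotypes(cfg), 0.05, 0.2)
            k = compute_kinship(panel)
            y = np.random.default_rng(s).standard_normal(s)
            res = lmm_association(y, panel, k, lambda_fixed=0.0)
            med[s] = np.median(res.se)
        assert med[50] / med[200] == pytest.approx(2.0, rel=0.2)

    def test_structured_null_is_calibrated_while_ols_inflates(self):
        cfg = SimConfig(n_strains=80, n_sites=1500, fst=0.3, n_subpops=4, seed=31,
                        effect_size=0.0, h2_polygenic=0.5,
                        n_concordant_pairs=0, n_discordant_pairs=0)
        panel = simulate_genotypes(cfg)
        fp, _ = filter_variants(panel, 0.05, 0.2)
        k = compute_kinship(fp)
        from symbiopleio.simulate import simulate_phenotypes

        phen, _ = simulate_phenotypes(panel, cfg)
        y = (
            phen[(phen.trait == "shoot_biomass") & (phen.host == "DZA")]
            .groupby("strain")["value"].mean().loc[fp.strain_ids].to_numpy()
        )
        lmm = lmm_association(y, fp, k)
        chi2_med = np.median((lmm.beta / lmm.se) ** 2) / stats.chi2.ppf(0.5, 1)
        assert 0.9 < chi2_med < 1.1
        ols = lmm_association(y, fp, KinshipMatrix(np.eye(80)), lambda_fixed=0.0)
        ols_med = np.median((ols.beta / ols.se) ** 2) / stats.chi2.ppf(0.5, 1)
        assert ols_med > 1.2

    def test_input_errors(self, small_panel, small_kinship):
        with pytest.raises(DataError):
            lmm_association(np.full(small_panel.n_strains, np.nan), small_panel, small_kinship)
        with pytest.raises(DataError):
            lmm_association(np.ones(small_panel.n_strains), small_panel, small_kinship)
        with pytest.raises(DataError):
            lmm_association(np.ones(3), small_panel, small_kinship)
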