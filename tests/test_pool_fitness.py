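"""Pool-frequency reconstruction and fold-change relative fitness."""

import numpy as np
import pandas as pd
import pytest

from symbiopleio.config import SimConfig
from symbiopleio.datatypes import DataError, GenotypePanel, PoolObservation
from symbiopleio.pool_fitness import (
    StrainFrequencyEstimate,
    default_pseudo_frequency,
    project_simplex,
    reconstruct_frequencies,
    relative_fitness,
)
from symbiopleio.simulate import simulate_genotypes, simulate_phenotypes, simulate_pools


def _panel(geno):
    s, l = np.asarray(geno).shape
    return GenotypePanel(
        genotypes=np.asarray(geno, dtype=np.int8),
        strain_ids=[f"s{i}" for i in range(s)],
        replicon=np.array(["chromosome"] * l),
        pos=np.arange(1, l + 1),
    )


def _obs(depth, alt, panel, **kw):
    defaults = dict(pool_id="p0", host="DZA", timepoint="final")
    defaults.update(kw)
    return PoolObservation(
        depth=np.asarray(depth), alt_count=np.asarray(alt),
        replicon=panel.replicon, pos=panel.pos, **defaults,
    )


def test_simplex_projection_properties(rng):
    for _ in range(50):
        v = rng.normal(scale=3, size=rng.integers(1, 20))
        p = project_simplex(v)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
    # already-feasible points are fixed points
    f = np.array([0.2, 0.3, 0.5])
    np.testing.assert_allclose(project_simplex(f), f, atol=1e-12)


def test_single_strain_frequency_is_one():
    panel = _panel([[0, 1, 0, 1]])
    est = reconstruct_frequencies(_obs([50] * 4, [10, 40, 5, 45], panel), panel, maf_min=0.0)
    np.testing.assert_array_equal(est.frequencies, [1.0])


def test_two_strains_single_informative_site():
    # strain A ref, strain B alt; alt fraction 0.3 at high depth -> f = (0.7, 0.3)
    panel = _panel([[0], [1]])
    est = reconstruct_frequencies(_obs([100000], [30000], panel), panel, maf_min=0.0)
    np.testing.assert_allclose(est.frequencies, [0.7, 0.3], atol=1e-6)


def test_noiseless_counts_recovered_exactly():
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 2, size=(8, 200)).astype(np.int8)
    f_true = np.arange(1, 9, dtype=float)
    f_true /= f_true.sum()  # multiples of 1/36: exact integer counts at depth 36
    depth = np.full(200, 36)
    alt = np.round(36 * (geno.T.astype(float) @ f_true)).astype(int)
    panel = _panel(geno)
    est = reconstruct_frequencies(_obs(depth, alt, panel), panel, maf_min=0.0, tol=1e-12)
    assert np.abs(est.frequencies - f_true).max() < 1e-6


def test_objective_monotone_nonincreasing():
    cfg = SimConfig(n_strains=15, n_sites=300, seed=12, missing_rate=0.0,
                    n_concordant_pairs=0, n_discordant_pairs=0)
    panel = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(panel, cfg)
    pools, _ = simulate_pools(panel, truth, cfg)
    obs = next(p for p in pools if p.timepoint == "final")
    est = reconstruct_frequencies(obs, panel, track_objective=True)
    h = np.asarray(est.objective_history)
    assert np.all(np.diff(h) <= 1e-15)


def test_recovery_against_truth_ledger():
    cfg = SimConfig(n_strains=20, n_sites=500, mean_depth=1000, n_pools=2, seed=9,
                    missing_rate=0.0, n_concordant_pairs=0, n_discordant_pairs=0)
    panel = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(panel, cfg)
    pools, _ = simulate_pools(panel, truth, cfg)
    for obs in pools:
        if obs.timepoint != "final" or obs.host != "DZA":
            continue
        est = reconstruct_frequencies(obs, panel)
        rmse = np.sqrt(np.mean((est.frequencies - truth.final_frequencies["DZA"]) ** 2))
        assert rmse <= 0.01


def test_zero_depth_everywhere_raises():
    panel = _panel([[0, 1], [1, 0]])
    with pytest.raises(DataError):
        reconstruct_frequencies(_obs([0, 0], [0, 0], panel), panel, maf_min=0.0)


def test_misaligned_sites_raise():
    panel = _panel([[0, 1], [1, 0]])
    obs = PoolObservation(
        pool_id="p", host="DZA", timepoint="final",
        depth=np.array([10, 10]), alt_count=np.array([1, 2]),
        replicon=np.array(["pSymA", "pSymA"]), pos=np.array([1, 2]),
    )
    with pytest.raises(DataError):
        reconstruct_frequencies(obs, panel)


def _est(f, pool_id="p0", host="DZA"):
    return StrainFrequencyEstimate(pool_id, host, "final", np.asarray(f, float), 0.0, 10, True, 1)


class TestRelativeFitness:
    def test_identity_when_final_equals_initial(self):
        f = np.array([0.25, 0.25, 0.5])
        for pseudo in (0.0, 0.01):
            per_pool, summary = relative_fitness([_est(f)], f, ["a", "b", "c"], pseudo=pseudo)
            np.testing.assert_allclose(summary.fold_change, 1.0, atol=1e-12)
            np.testing.assert_allclose(summary.log2_fold_change, 0.0, atol=1e-12)

    def test_fold_change_arithmetic(self):
        init = np.array([0.01, 0.99])
        final = np.array([0.02, 0.98])
        _, summary = relative_fitness([_est(final)], init, ["a", "b"], pseudo=0.0)
        assert summary.set_index("strain").loc["a", "fold_change"] == pytest.approx(2.0)

    def test_zero_final_frequency_flagged_with_zero_pseudo(self):
        per_pool, _ = relative_fitness([_est([0.0, 1.0])], np.array([0.5, 0.5]), ["a", "b"], pseudo=0.0)
        row = per_pool.set_index("strain").loc["a"]
        assert row.fold_change == 0.0 and row.undefined_log2 and np.isnan(row.log2_fold_change)

    def test_log2_is_exact_log_of_fold_change(self):
        _, summary = relative_fitness(
            [_est([0.1, 0.2, 0.7])], np.array([0.3, 0.3, 0.4]), ["a", "b", "c"], pseudo=0.01
        )
        np.testing.assert_allclose(
            summary.log2_fold_change, np.log2(summary.fold_change), atol=1e-12
        )

    def test_mixed_host_pools_rejected(self):
        with pytest.raises(DataError):
            relative_fitness(
                [_est([1.0]), _est([1.0], host="A17")], np.array([1.0]), ["a"]
            )

    def test_invariant_to_common_depth_rescaling(self):
        cfg = SimConfig(n_strains=10, n_sites=200, seed=21, missing_rate=0.0,
                        n_concordant_pairs=0, n_discordant_pairs=0)
        panel = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(panel, cfg)
        pools, _ = simulate_pools(panel, truth, cfg)
        obs = next(p for p in pools if p.timepoint == "final" and p.host == "DZA")
        scaled = PoolObservation(
            pool_id=obs.pool_id, host=obs.host, timepoint=obs.timepoint,
            depth=obs.depth * 3, alt_count=obs.alt_count * 3,
            replicon=obs.replicon, pos=obs.pos,
        )
        e1 = reconstruct_frequencies(obs, panel)
        e2 = reconstruct_frequencies(scaled, panel)
        init = truth.initial_frequencies["DZA"]
        _, s1 = relative_fitness([e1], init, panel.strain_ids, pseudo=0.001)
        _, s2 = relative_fitness([e2], init, panel.strain_ids, pseudo=0.001)
        np.testing.assert_allclose(s1.fold_change, s2.fold_change, atol=1e-6)


def test_selection_recovery_correlates_with_true_fitness():
    from scipy import stats

    cfg = SimConfig(n_strains=20, n_sites=500, mean_depth=1000, n_pools=6, seed=9,
                    missing_rate=0.0, n_concordant_pairs=2, n_discordant_pairs=2,
                    selection_gradient=1.0)
    panel = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(panel, cfg)
    pools, _ = simulate_pools(panel, truth, cfg)
    finals = [reconstruct_frequencies(p, panel)
              for p in pools if p.host == "DZA" and p.timepoint == "final"]
    pseudo = default_pseudo_frequency([p for p in pools if p.host == "DZA" and p.timepoint == "final"])
    _, summary = relative_fitness(finals, truth.initial_frequencies["DZA"], panel.strain_ids, pseudo=pseudo)
    logw = (
        truth.fitness[truth.fitness.host == "DZA"].set_index("strain")
        .loc[summary.strain, "log_w"].to_numpy()
    )
    r, _ = stats.pearsonr(summary.log2_fold_change, logw)
    assert r >= 0.9
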