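"""Eigengene decomposition, the circular-bottleneck autoencoder, ordering
statistics, and phase alignment/evaluation."""

import numpy as np
import pandas as pd
import pytest

from clockscope import (
    SeedGeneList,
    align_phases,
    compute_eigengenes,
    default_seed_genes,
    evaluate_ordering_vs_truth,
    fit_cyclops,
    met_smooth,
    select_seed_genes,
    simulate_population,
    stat_err,
)
from clockscope._circular import TWO_PI, circ_dist, wrap
from clockscope.cyclops_core import EigengeneDecomposition, OrderingResult
from clockscope.rhythm_stats import CosinorFit

from conftest import population_config, rhythmic_seed_list
from test_preprocess_io import toy_matrix


def circle_decomposition(n=64, radius=1.0, jitter=0.0, seed=0, phase_offset=0.0):
    """Eigengene scores lying (near-)exactly on a circle, with true angles."""
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0, TWO_PI, n))
    x = radius * np.cos(theta + phase_offset) + jitter * rng.normal(size=n)
    y = radius * np.sin(theta + phase_offset) + jitter * rng.normal(size=n)
    scores = pd.DataFrame({"E1": x, "E2": y},
                          index=[f"S{i:03d}" for i in range(n)])
    seed_matrix = pd.DataFrame(np.vstack([x, y]), index=["gx", "gy"],
                               columns=scores.index)
    eig = EigengeneDecomposition(
        scores=scores,
        loadings=pd.DataFrame(np.eye(2), index=["gx", "gy"], columns=["E1", "E2"]),
        variance_explained=np.array([0.5, 0.5]),
        k=2,
        seed_matrix=seed_matrix,
    )
    return eig, theta


class TestSelectSeedGenes:
    def test_low_expression_and_constant_genes_excluded(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 15, (12, 40))
        vals = np.vstack([base, np.full((1, 40), 0.1), np.full((1, 40), 50.0)])
        genes = [f"G{i}" for i in range(12)] + ["LOWEXPR", "CONSTANT"]
        m = toy_matrix(vals, genes=genes)
        out = select_seed_genes(m, SeedGeneList(genes, "user_file"),
                                min_mean_expr=1.0, cv_window=(0.05, 2.0))
        assert "LOWEXPR" not in out.index
        assert "CONSTANT" not in out.index

    def test_relative_expression_scaling(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(5, 15, (10, 30))
        genes = [f"G{i}" for i in range(10)]
        out = select_seed_genes(toy_matrix(vals, genes=genes),
                                SeedGeneList(genes, "user_file"), 0.0, (0.0, 10.0))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        expected = (vals[0] - vals[0].mean()) / vals[0].mean()
        np.testing.assert_allclose(out.iloc[0], expected, atol=1e-12)

    def test_all_designed_seed_genes_retained_on_intact_cohort(self):
        ds = simulate_population(population_config(seed=6))
        seeds = rhythmic_seed_list(ds)
        out = select_seed_genes(ds.matrix, seeds)
        assert out.shape[0] == len(seeds.symbols) == 60

    def test_too_few_survivors_errors(self):
        m = toy_matrix(np.random.default_rng(2).uniform(1, 2, (5, 10)))
        with pytest.raises(ValueError, match=">= 10"):
            select_seed_genes(m, SeedGeneList(list(m.genes), "user_file"))

    def test_packaged_default_list_loads(self):
        seeds = default_seed_genes()
        assert "ARNTL" in seeds.symbols and len(seeds.symbols) >= 30


class TestComputeEigengenes:
    def test_planar_data_gives_k2_full_variance(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 20))
        coords = rng.normal(size=(50, 2))
        data = coords @ basis  # samples x genes exactly on a 2-D plane
        sm = pd.DataFrame(data.T, index=[f"G{i}" for i in range(20)],
                          columns=[f"S{i}" for i in range(50)])
        eig = compute_eigengenes(sm, k_mode=("variance", 0.85))
        assert eig.k == 2
        assert eig.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_centered(self):
        rng = np.random.default_rng(4)
        sm = pd.DataFrame(rng.normal(size=(15, 40)),
                          index=[f"G{i}" for i in range(15)],
                          columns=[f"S{i}" for i in range(40)])
        eig = compute_eigengenes(sm, k_mode=("fixed", 3))
        np.testing.assert_allclose(eig.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_intact_simulation_top_pair_traces_ellipse(self):
        """On a noiseless intact cohort the leading eigengene pair forms a
        ring: radius spread below 20% of the mean radius."""
        cfg = population_config(seed=8, noise_cv=0.0)
        ds = simulate_population(cfg)
        sm = select_seed_genes(ds.matrix, rhythmic_seed_list(ds), 0.0, (0.0, 10.0))
        eig = compute_eigengenes(sm)
        x = eig.scores.iloc[:, 0] / eig.scores.iloc[:, 0].std()
        y = eig.scores.iloc[:, 1] / eig.scores.iloc[:, 1].std()
        r = np.hypot(x, y)
        assert r.std() / r.mean() < 0.20

    def test_oscillation_screen_selects_circular_pair(self):
        eig, _ = circle_decomposition(n=80)
        sm = eig.seed_matrix
        # add two strong noise genes so variance ordering alone would differ
        rng = np.random.default_rng(5)
        noise = pd.DataFrame(rng.normal(0, 3.0, size=(2, 80)), index=["n1", "n2"],
                             columns=sm.columns)
        full = pd.concat([sm, noise])
        screened = compute_eigengenes(full, k_mode=("fixed", 4), oscillation_screen=True)
        assert screened.k >= 2


class TestFitCyclops:
    def test_exact_circle_recovered(self):
        eig, theta = circle_decomposition(n=64)
        res = fit_cyclops(eig, n_restarts=20, max_epochs=5000, seed=0)
        assert res.reconstruction_loss < 1e-6
        ev = evaluate_ordering_vs_truth(res, pd.Series(theta, index=eig.scores.index))
        assert ev["circular_correlation"] > 0.999
        assert ev["median_abs_circular_error"] < 0.02

    def test_seeded_determinism(self):
        eig, _ = circle_decomposition(n=48, jitter=0.1)
        r1 = fit_cyclops(eig, n_restarts=5, max_epochs=300, seed=11)
        r2 = fit_cyclops(eig, n_restarts=5, max_epochs=300, seed=11)
        assert r1.phases.equals(r2.phases)
        assert r1.reconstruction_loss == r2.reconstruction_loss

    def test_loss_non_increasing_per_restart(self):
        eig, _ = circle_decomposition(n=48, jitter=0.2)
        res = fit_cyclops(eig, n_restarts=6, max_epochs=400, seed=3,
                          track_history=True)
        hist = res.loss_history
        assert hist is not None
        assert (np.diff(hist, axis=0) <= 1e-12).all()

    def test_phase_invariant_to_seed_gene_rescaling(self):
        ds = simulate_population(population_config(seed=13, n_samples=60))
        seeds = rhythmic_seed_list(ds)
        m1 = ds.matrix
        scaled = m1.values.copy()
        scaled.iloc[:10] *= 7.5
        m2 = type(m1)(scaled, m1.metadata.copy())
        sm1 = select_seed_genes(m1, seeds)
        sm2 = select_seed_genes(m2, seeds)
        np.testing.assert_allclose(sm1.to_numpy(), sm2.to_numpy(), atol=1e-12)

    def test_too_few_samples_rejected(self):
        eig, _ = circle_decomposition(n=10)
        with pytest.raises(ValueError):
            fit_cyclops(eig, n_restarts=2, max_epochs=10, seed=0)


class TestMetSmooth:
    def test_circle_is_smoother_than_pc1(self):
        eig, theta = circle_decomposition(n=64)
        ordering = pd.Series(theta, index=eig.scores.index)
        assert met_smooth(ordering, eig) < 1.0

    def test_direction_reversal_invariant(self):
        eig, theta = circle_decomposition(n=64)
        idx = eig.scores.index
        fwd = met_smooth(pd.Series(theta, index=idx), eig)
        rev = met_smooth(pd.Series(wrap(-theta), index=idx), eig)
        assert fwd == pytest.approx(rev, rel=1e-9)

    def test_collinear_degenerate_case(self):
        # points on a line, phases monotone in the PC1 rank
        n = 50
        x = np.linspace(-1, 1, n)
        scores = pd.DataFrame({"E1": x, "E2": np.zeros(n)},
                              index=[f"S{i}" for i in range(n)])
        eig = EigengeneDecomposition(scores, None, np.array([1.0, 0.0]), 2)
        phases = pd.Series(np.linspace(0, TWO_PI, n, endpoint=False),
                           index=scores.index)
        assert met_smooth(phases, eig) >= 0.9

    def test_too_few_samples(self):
        scores = pd.DataFrame({"E1": [0, 1], "E2": [1, 0]}, index=["a", "b"])
        eig = EigengeneDecomposition(scores, None, np.array([0.5, 0.5]), 2)
        with pytest.raises(ValueError):
            met_smooth(pd.Series([0.0, 1.0], index=["a", "b"]), eig)


class TestStatErr:
    def test_minimum_null_count_enforced(self):
        eig, _ = circle_decomposition(n=48)
        res = fit_cyclops(eig, n_restarts=3, max_epochs=200, seed=0)
        with pytest.raises(ValueError):
            stat_err(eig, res, n_null=5)

    def test_coherent_circle_is_significant(self):
        """A clean circular structure must beat per-gene-permuted nulls."""
        ds = simulate_population(population_config(seed=2, n_samples=120))
        sm = select_seed_genes(ds.matrix, rhythmic_seed_list(ds))
        eig = compute_eigengenes(sm)
        res = fit_cyclops(eig, n_restarts=10, max_epochs=1000, seed=2)
        p = stat_err(eig, res, n_null=19, restarts_null=5, seed=2, max_epochs=1000)
        assert p == pytest.approx(1 / 20)
        assert res.stat_err_p == p


def _fits(acro: dict, rhythmic=True):
    return {g: CosinorFit(g, 100.0, 50.0, 0.5, phi, 0.8, 0.001, 100, rhythmic)
            for g, phi in acro.items()}


class TestAlignPhases:
    def _ordering(self, theta, index):
        return OrderingResult(pd.Series(theta, index=index), 0.5, 0.01, 0.1, 1, 0)

    def test_anchor_set_exactly(self):
        idx = [f"S{i}" for i in range(5)]
        ordering = self._ordering(np.linspace(0, 5, 5), idx)
        fits = _fits({"ARNTL": 1.3, "PER1": 1.3 + 2.8})
        aligned = align_phases(ordering, fits, "ARNTL", 0.0)
        # the anchor acrophase transform: phases rotated by -1.3
        np.testing.assert_allclose(aligned.phases, wrap(ordering.phases - 1.3),
                                   atol=1e-12)

    def test_reflection_when_secondary_leads(self):
        idx = [f"S{i}" for i in range(4)]
        ordering = self._ordering(np.array([0.1, 1.0, 2.0, 3.0]), idx)
        # PER1 4.5 rad *after* ARNTL (> pi): direction must be flipped
        fits = _fits({"ARNTL": 0.0, "PER1": 4.5})
        aligned = align_phases(ordering, fits, "ARNTL", 0.0)
        np.testing.assert_allclose(aligned.phases, wrap(-ordering.phases), atol=1e-12)

    def test_idempotent_on_intact_recovery(self):
        ds = simulate_population(population_config(seed=4, n_samples=150))
        sm = select_seed_genes(ds.matrix, rhythmic_seed_list(ds))
        eig = compute_eigengenes(sm)
        res = fit_cyclops(eig, n_restarts=10, max_epochs=1000, seed=4)
        from clockscope.rhythm_stats import rhythmic_scan, fits_from_table
        scan = rhythmic_scan(ds.matrix, res)
        fits = fits_from_table(scan.table)
        once = align_phases(res, fits, "ARNTL")
        scan2 = rhythmic_scan(ds.matrix, once)
        twice = align_phases(once, fits_from_table(scan2.table), "ARNTL")
        assert np.max(circ_dist(twice.phases.to_numpy(), once.phases.to_numpy())) < 1e-6

    def test_aligned_phases_match_truth(self):
        ds = simulate_population(population_config(seed=4, n_samples=150))
        sm = select_seed_genes(ds.matrix, rhythmic_seed_list(ds))
        eig = compute_eigengenes(sm)
        res = fit_cyclops(eig, n_restarts=10, max_epochs=1000, seed=4)
        from clockscope.rhythm_stats import rhythmic_scan, fits_from_table
        scan = rhythmic_scan(ds.matrix, res)
        aligned = align_phases(res, fits_from_table(scan.table), "ARNTL")
        err = circ_dist(aligned.phases.to_numpy(), ds.truth_phases.to_numpy())
        assert np.median(err) <= 0.5

    def test_non_rhythmic_anchor_rejected(self):
        idx = ["S0", "S1", "S2"]
        ordering = self._ordering(np.array([0.0, 1.0, 2.0]), idx)
        fits = _fits({"ARNTL": 0.5}, rhythmic=False)
        with pytest.raises(ValueError, match="not rhythmic"):
            align_phases(ordering, fits, "ARNTL")


class TestEvaluateOrdering:
    def test_perfect_recovery(self):
        theta = np.random.default_rng(0).uniform(0, TWO_PI, 100)
        idx = [f"S{i}" for i in range(100)]
        res = evaluate_ordering_vs_truth(pd.Series(theta, index=idx),
                                         pd.Series(theta, index=idx))
        assert res["circular_correlation"] == pytest.approx(1.0, abs=1e-9)
        assert res["median_abs_circular_error"] < 1e-9

    def test_rotation_invariance(self):
        theta = np.random.default_rng(1).uniform(0, TWO_PI, 100)
        idx = [f"S{i}" for i in range(100)]
        shifted = wrap(theta + 1.3)
        res = evaluate_ordering_vs_truth(pd.Series(shifted, index=idx),
                                         pd.Series(theta, index=idx))
        assert res["circular_correlation"] == pytest.approx(1.0, abs=1e-9)
        assert res["median_abs_circular_error"] < 1e-9

    def test_random_phases_uncorrelated(self):
        rng = np.random.default_rng(2)
        idx = [f"S{i}" for i in range(200)]
        hits = 0
        for _ in range(40):
            a = rng.uniform(0, TWO_PI, 200)
            b = rng.uniform(0, TWO_PI, 200)
            res = evaluate_ordering_vs_truth(pd.Series(a, index=idx),
                                             pd.Series(b, index=idx))
            hits += res["circular_correlation"] < 0.2
        assert hits >= 38  # 95% of null draws below 0.2

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_ordering_vs_truth(pd.Series([0.0, 1.0], index=["a", "b"]),
                                       pd.Series([0.0], index=["a"]))
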