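import numpy as np
import pandas as pd
import pytest

import emdde
from emdde.emd import EmdStatistic
from emdde.io import ClassLabels
from emdde.significance import (
    NullMedians,
    bh_adjust,
    bootstrap_stability,
    fdr_grid,
    permuted_null,
    run_emd,
)
from emdde.simulate import SimulationSpec, simulate_case


def brute_force_fdr_matrix(obs, med, thresholds):
    """Materialize the full N x |thresholds| FDR matrix, straight from the
    defining formula, and take per-gene minima."""
    n = len(obs)
    q = np.ones(n)
    for j in range(n):
        best = 1.0
        for t in thresholds:
            if obs[j] >= t:
                num = sum(m > t for m in med)
                den = sum(e > t for e in obs)
                fdr = min(num / den, 1.0) if den > 0 else 1.0
            else:
                fdr = 1.0
            best = min(best, fdr)
        q[j] = best
    return q


class TestFdrGrid:
    def test_hand_worked_example(self):
        obs = np.array([3.0, 0.4, 0.3])
        med = np.array([0.5, 0.45, 0.35])
        grid = fdr_grid(obs, med, delta=0.1, t_max=2.0)
        np.testing.assert_allclose(grid.q_values, [0.0, 1.0, 1.0])

    def test_observed_equal_to_null_gives_all_ones(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(0, 2, 50)
        grid = fdr_grid(obs, obs.copy(), delta=0.01)
        np.testing.assert_allclose(grid.q_values, 1.0)

    def test_q_nonincreasing_in_score(self):
        rng = np.random.default_rng(1)
        med = rng.uniform(0, 1, 100)
        obs = np.sort(rng.uniform(0, 3, 100))
        q = fdr_grid(obs, med, delta=0.01).q_values
        assert (np.diff(q) <= 1e-12).all()

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 40))
            obs = rng.uniform(0, 4, n).round(2)
            med = rng.uniform(0, 1.5, n).round(2)
            delta = 0.05
            t_max = max(float(np.round(obs.max())) - 1.0, delta)
            grid = fdr_grid(obs, med, delta=delta, t_max=t_max)
            want = brute_force_fdr_matrix(obs, med, grid.thresholds)
            np.testing.assert_allclose(grid.q_values, want, atol=1e-12)

    def test_threshold_grid_structure(self):
        grid = fdr_grid(np.array([3.2, 0.1]), np.array([0.1, 0.1]), delta=0.001)
        # T = round(max)-1 = 2; descending to 0 with step delta
        assert grid.thresholds[0] == pytest.approx(2.0)
        assert grid.thresholds[-1] == 0.0
        np.testing.assert_allclose(np.diff(grid.thresholds), -0.001, atol=1e-9)

    def test_q_invariant_to_gene_reordering(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(0, 3, 60)
        med = rng.uniform(0, 1, 60)
        q = fdr_grid(obs, med, delta=0.01).q_values
        perm = rng.permutation(60)
        q_perm = fdr_grid(obs[perm], med[perm], delta=0.01).q_values
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-15)

    @pytest.mark.parametrize("delta", [0.0, -1.0])
    def test_bad_delta_rejected(self, delta):
        with pytest.raises(ValueError, match="delta"):
            fdr_grid(np.array([1.0]), np.array([0.5]), delta=delta)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            fdr_grid(np.array([]), np.array([]))


class TestPermutedNull:
    def test_deterministic_given_seed(self, small_dataset):
        m, labels, _ = small_dataset
        stat = EmdStatistic(0.2)
        a = permuted_null(m, labels, stat, n_perm=20, seed=5)
        b = permuted_null(m, labels, stat, n_perm=20, seed=5)
        np.testing.assert_array_equal(a.medians, b.medians)
        c = permuted_null(m, labels, stat, n_perm=20, seed=6)
        assert not np.array_equal(a.medians, c.medians)

    def test_constant_gene_has_zero_null_median(self, tiny_labels):
        m = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
            index=["const", "var"],
            columns=["s1", "s2", "s3", "s4"],
        )
        null = permuted_null(m, tiny_labels, EmdStatistic(0.2), n_perm=10, seed=0)
        assert null.medians[0] == 0.0

    def test_n_perm_must_be_positive(self, small_dataset):
        m, labels, _ = small_dataset
        with pytest.raises(ValueError, match="n_perm"):
            permuted_null(m, labels, EmdStatistic(), n_perm=0)

    def test_pooled_scores_kept_on_request(self, small_dataset):
        m, labels, _ = small_dataset
        null = permuted_null(
            m, labels, EmdStatistic(), n_perm=7, seed=1, keep_pooled=True
        )
        assert null.pooled_sorted.size == 7 * m.shape[0]
        assert (np.diff(null.pooled_sorted) >= 0).all()


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])


class TestRunEmd:
    def test_shifted_gene_ranks_above_identical_gene(self, small_dataset):
        m, labels, truth = small_dataset
        res = run_emd(m, labels, n_perm=50, seed=9)
        assert res.shape[0] == m.shape[0]
        assert res["q_value"].between(0, 1).all()
        de_q = res.loc[truth, "q_value"].median()
        null_q = res.loc[~truth, "q_value"].median()
        assert de_q < null_q

    def test_null_calibration_small_replicates(self):
        """On pure-null data the q < alpha call rate stays at or below alpha."""
        for alpha in (0.05, 0.2):
            rates = []
            for rep in range(4):
                ds = simulate_case(
                    SimulationSpec(n_genes=300, n_de=0, n1=25, n2=35), seed=100 + rep
                )
                res = run_emd(ds.matrix, ds.labels, n_perm=60, seed=rep)
                rates.append((res["q_value"].to_numpy() < alpha).mean())
            assert np.mean(rates) <= alpha + 0.02

    def test_result_is_seed_deterministic(self, small_dataset):
        m, labels, _ = small_dataset
        a = run_emd(m, labels, n_perm=30, seed=3)
        b = run_emd(m, labels, n_perm=30, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestBootstrapStability:
    def test_single_iteration_matches_plain_run_support(self, small_dataset):
        m, labels, _ = small_dataset
        med_q, counts = bootstrap_stability(
            m, labels, method="emd", n_boot=1, seed=2, n_perm=30
        )
        assert med_q.shape == (m.shape[0],)
        assert counts.shape == (1,)
        assert counts[0] == int((med_q < 0.05).sum())

    def test_deterministic_given_seed(self, small_dataset):
        m, labels, _ = small_dataset
        a = bootstrap_stability(m, labels, n_boot=3, seed=8, n_perm=20)
        b = bootstrap_stability(m, labels, n_boot=3, seed=8, n_perm=20)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_n_boot_must_be_positive(self, small_dataset):
        m, labels, _ = small_dataset
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_stability(m, labels, n_boot=0)
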