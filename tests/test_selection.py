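"""PC computation, batched correlation pruning and the adjusted age screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import promclock as pc
from promclock.selection import CascadeConfig, age_screen, compute_pcs, prune_correlated

from conftest import random_covariates, random_promoter_matrix


def brute_force_prune(values, ids, r_max, batch_size):
    """All-pairs greedy keep-first oracle, independent of the implementation."""
    kept = []
    n = len(ids)
    for b0 in range(0, n, batch_size):
        batch = list(range(b0, min(b0 + batch_size, n)))
        kept_local = []
        for j in batch:
            drop = False
            for i in kept_local:
                xi, xj = values[:, i], values[:, j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                if r > r_max:
                    drop = True
                    break
            if not drop:
                kept_local.append(j)
        kept += [ids[j] for j in kept_local]
    return kept


class TestComputePCs:
    def test_rank_one_matrix_concentrates_variance(self):
        rng = np.random.default_rng(0)
        u = rng.random(30)
        v = rng.random(8)
        pm = random_promoter_matrix(rng, 30, 8)
        pm.values = np.outer(u, v) + 1e-9 * rng.random((30, 8))
        pcs = compute_pcs(pm, 3)
        ev = pcs.explained_variance
        assert ev[0] / ev.sum() > 0.999
        assert np.all(np.diff(ev) <= 1e-12)

    def test_scores_centered_and_orthogonal(self):
        rng = np.random.default_rng(1)
        pm = random_promoter_matrix(rng, 25, 40)
        pcs = compute_pcs(pm, 5)
        assert np.allclose(pcs.scores.mean(axis=0), 0, atol=1e-10)
        gram = pcs.scores.T @ pcs.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_reduced_with_warning(self):
        rng = np.random.default_rng(2)
        pm = random_promoter_matrix(rng, 3, 10)
        with pytest.warns(UserWarning, match="reduced"):
            pcs = compute_pcs(pm, 5)
        assert pcs.scores.shape[1] <= 2

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(3)
        pm = random_promoter_matrix(rng, 20, 5)
        pm.values[:, 2] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            compute_pcs(pm, 2)


class TestPruneCorrelated:
    def test_identical_columns_keep_first(self):
        rng = np.random.default_rng(4)
        pm = random_promoter_matrix(rng, 20, 5)
        pm.values[:, 3] = pm.values[:, 1]
        pm.values[:, 4] = pm.values[:, 1]
        kept, report = prune_correlated(pm, 0.9, 1000)
        assert kept == ["P0", "P1", "P2"]
        reasons = report.set_index("promoter_id")["reason"]
        assert reasons["P3"] == "correlated-with:P1"
        assert reasons["P4"] == "correlated-with:P1"

    def test_boundary_r_exactly_at_threshold_kept(self):
        # construct two columns with exact correlation 0.9 via rotation
        rng = np.random.default_rng(5)
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        a -= a.mean(); b -= b.mean()
        b -= (b @ a) / (a @ a) * a  # orthogonalize
        r = 0.9
        x2 = r * a / np.std(a) + np.sqrt(1 - r**2) * b / np.std(b)
        pm = random_promoter_matrix(rng, 200, 2)
        pm.values[:, 0] = a
        pm.values[:, 1] = x2
        got = np.corrcoef(pm.values[:, 0], pm.values[:, 1])[0, 1]
        assert got == pytest.approx(0.9, abs=1e-12)
        kept, _ = prune_correlated(pm, 0.9, 1000)
        assert kept == ["P0", "P1"]  # strict >, both kept

    def test_zero_variance_never_pruned(self):
        rng = np.random.default_rng(6)
        pm = random_promoter_matrix(rng, 15, 3)
        pm.values[:, 1] = 0.7
        kept, _ = prune_correlated(pm, 0.9, 1000)
        assert "P1" in kept

    def test_cross_batch_pairs_not_compared(self):
        rng = np.random.default_rng(7)
        pm = random_promoter_matrix(rng, 20, 4)
        pm.values[:, 2] = pm.values[:, 0]  # duplicate lands in the next batch
        kept, _ = prune_correlated(pm, 0.9, batch_size=2)
        assert kept == ["P0", "P1", "P2", "P3"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_p = int(rng.integers(5, 50))
        pm = random_promoter_matrix(rng, int(rng.integers(5, 30)), n_p)
        # plant duplicated/correlated columns
        for _ in range(int(rng.integers(0, 6))):
            i, j = rng.integers(0, n_p, 2)
            pm.values[:, j] = pm.values[:, i] + rng.normal(0, 0.02, pm.n_samples)
        batch = int(rng.integers(3, n_p + 5))
        kept, _ = prune_correlated(pm, 0.9, batch)
        assert kept == brute_force_prune(pm.values, pm.promoter_ids, 0.9, batch)


class TestAgeScreen:
    def _screen(self, rng, n=40, n_p=12, k=3):
        pm = random_promoter_matrix(rng, n, n_p)
        cov = random_covariates(rng, pm.sample_ids)
        pcs = compute_pcs(pm, k)
        return pm, cov, pcs, age_screen(pm, cov, pcs, 0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_pvalues_match_statsmodels_ols(self, seed):
        rng = np.random.default_rng(seed)
        pm, cov, pcs, result = self._screen(rng)
        y = cov.data["age"].to_numpy()
        base = np.column_stack(
            [cov.data["sex"], cov.data["pmi"], pcs.scores]
        )
        for j, pid in enumerate(pm.promoter_ids):
            x = sm.add_constant(np.column_stack([pm.values[:, j], base]))
            fit = sm.OLS(y, x).fit()
            row = result[result["promoter_id"] == pid].iloc[0]
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_perfect_predictor_kept_with_tiny_p(self):
        rng = np.random.default_rng(10)
        pm = random_promoter_matrix(rng, 30, 5)
        cov = random_covariates(rng, pm.sample_ids)
        pm.values[:, 0] = 0.01 * cov.data["age"].to_numpy() + 0.1  # exact affine
        pcs = compute_pcs(random_promoter_matrix(rng, 30, 20), 3)  # unrelated PCs
        result = age_screen(pm, cov, pcs, 0.05)
        row = result[result["promoter_id"] == "P0"].iloc[0]
        assert row["kept"] and row["p"] < 1e-20

    def test_rank_deficient_promoter_flagged(self):
        rng = np.random.default_rng(11)
        pm = random_promoter_matrix(rng, 30, 3)
        cov = random_covariates(rng, pm.sample_ids)
        pcs = compute_pcs(pm, 2)
        pm.values[:, 1] = 0.25  # constant: inside the intercept span
        result = age_screen(pm, cov, pcs, 0.05)
        row = result[result["promoter_id"] == "P1"].iloc[0]
        assert not row["kept"] and row["reason"] == "rank-deficient"


class TestRunCascade:
    def test_planted_duplicates_pruned_and_effects_kept(self, small_promoter_matrix,
                                                        small_matrix, small_cohort):
        pm, _, _ = small_promoter_matrix
        _, truth = small_matrix
        selected, report = pc.run_cascade(pm, small_cohort, CascadeConfig(k_pcs=5))
        # every input promoter appears exactly once in the report
        assert sorted(report.table["promoter_id"]) == sorted(pm.promoter_ids)
        assert set(selected.promoter_ids) == set(report.kept_ids)
        kept = report.table[report.table["kept"]]
        assert (kept["stage"] == "screen").all()
        assert (kept["p"] < 0.05).all()

    def test_degenerate_thresholds_are_noops(self, small_promoter_matrix, small_cohort):
        pm, _, _ = small_promoter_matrix
        selected, report = pc.run_cascade(
            pm, small_cohort, CascadeConfig(r_max=1.01, alpha=1.0, k_pcs=3)
        )
        assert selected.n_promoters == pm.n_promoters  # both stages pass everything

    def test_cascade_deterministic(self, small_promoter_matrix, small_cohort):
        pm, _, _ = small_promoter_matrix
        cfg = CascadeConfig(k_pcs=5)
        sel1, rep1 = pc.run_cascade(pm, small_cohort, cfg)
        sel2, rep2 = pc.run_cascade(pm, small_cohort, cfg)
        assert sel1.promoter_ids == sel2.promoter_ids
        pd.testing.assert_frame_equal(rep1.table, rep2.table)
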