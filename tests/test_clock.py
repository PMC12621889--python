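"""Elastic-net clock: splitting, fitting, prediction, metrics, attribution, export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import ElasticNet

import promclock as pc
from promclock.clock import ClockModel, TuningConfig

from conftest import random_covariates


def toy_model():
    return ClockModel(
        intercept=60.0,
        betas={"a": 3.0, "b": -2.0, "c": 0.5},
        scaling={"a": (0.5, 0.1), "b": (0.3, 0.2), "c": (0.7, 0.05)},
    )


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        ids = [f"S{i}" for i in range(100)]
        train, test = pc.split_samples(ids, 0.7, seed=1)
        assert len(train) == 70 and len(test) == 30
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_deterministic_and_floor_rounding(self):
        ids = [f"S{i}" for i in range(101)]
        t1, _ = pc.split_samples(ids, 0.7, seed=9)
        t2, _ = pc.split_samples(ids, 0.7, seed=9)
        assert t1 == t2
        assert len(t1) == 70  # floor(101 * 0.7)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 10"):
            pc.split_samples(["a"] * 9, 0.7, seed=0)


class TestFit:
    def test_noiseless_single_feature_reaches_ols_limit(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(60)
        z = (z - z.mean()) / z.std()
        features = pd.DataFrame({"z": z}, index=[f"S{i}" for i in range(60)])
        cov = random_covariates(rng, features.index)
        cov.data["age"] = 2.0 * z + 5.0
        model = pc.fit_clock(
            features, cov,
            tuning=TuningConfig(l1_ratios=(0.5, 1.0), n_lambdas=30,
                                lambda_min_ratio=1e-6, cv_folds=5),
            seed=0,
        )
        assert model.betas["z"] == pytest.approx(2.0, abs=1e-3)
        assert model.intercept == pytest.approx(5.0, abs=1e-3)

    def test_constant_features_give_null_model(self):
        rng = np.random.default_rng(1)
        ids = [f"S{i}" for i in range(30)]
        features = pd.DataFrame({"a": 0.5, "b": 0.1}, index=ids)
        cov = random_covariates(rng, ids)
        model = pc.fit_clock(features, cov, seed=1)
        assert model.intercept == pytest.approx(cov.data["age"].mean())
        assert all(b == 0 for b in model.betas.values())

    def test_planted_effects_recovered(self, small_promoter_matrix, small_matrix,
                                       small_cohort):
        pm, _, _ = small_promoter_matrix
        _, truth = small_matrix
        model = pc.fit_clock(pm, small_cohort, seed=3)
        nonzero = set(model.contributing_features())
        causal = set(truth.causal_ids) & set(pm.promoter_ids)
        assert len(nonzero & causal) >= 0.5 * len(causal)

    def test_lambda_path_l1_norm_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50, 10))
        y = x[:, 0] * 3 + x[:, 1] * -2 + rng.standard_normal(50)
        norms = []
        for lam in np.logspace(-3, 1, 12):
            fit = ElasticNet(alpha=lam, l1_ratio=0.5, max_iter=50000).fit(x, y)
            norms.append(np.abs(fit.coef_).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_fewer_samples_than_folds(self):
        rng = np.random.default_rng(3)
        ids = [f"S{i}" for i in range(4)]
        features = pd.DataFrame({"a": rng.random(4)}, index=ids)
        with pytest.raises(ValueError, match="folds"):
            pc.fit_clock(features, random_covariates(rng, ids),
                         tuning=TuningConfig(cv_folds=5), seed=0)


class TestPredict:
    def test_mean_sample_predicts_intercept_and_zero_betas(self):
        model = toy_model()
        at_mean = pd.DataFrame(
            {"a": [0.5], "b": [0.3], "c": [0.7]}, index=["S0"]
        )
        assert pc.predict(model, at_mean).iloc[0] == pytest.approx(60.0)
        null = ClockModel(50.0, {"a": 0.0}, {"a": (0.5, 0.1)})
        x = pd.DataFrame({"a": [0.9, 0.1]}, index=["S0", "S1"])
        assert np.allclose(pc.predict(null, x), 50.0)

    def test_manual_affine_evaluation(self):
        model = toy_model()
        x = pd.DataFrame({"a": [0.6], "b": [0.1], "c": [0.75]}, index=["S0"])
        expected = 60.0 + 3.0 * (0.6 - 0.5) / 0.1 - 2.0 * (0.1 - 0.3) / 0.2 + 0.5 * (0.75 - 0.7) / 0.05
        assert pc.predict(model, x).iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_missing_feature_is_error_extra_is_warning(self):
        model = toy_model()
        with pytest.raises(ValueError, match="missing"):
            pc.predict(model, pd.DataFrame({"a": [0.5]}, index=["S0"]))
        full = pd.DataFrame(
            {"a": [0.5], "b": [0.3], "c": [0.7], "extra": [1.0]}, index=["S0"]
        )
        with pytest.warns(UserWarning, match="ignoring"):
            pc.predict(model, full)


class TestEvaluate:
    def test_perfect_and_constant_predictions(self):
        truth = pd.Series([40.0, 50.0, 60.0], index=["a", "b", "c"])
        perfect = pc.evaluate(truth.copy(), truth)
        assert perfect.r2_pearson_sq == pytest.approx(1.0)
        assert perfect.mae == 0.0
        const = pc.evaluate(pd.Series(50.0, index=truth.index), truth)
        assert const.r2_cod == pytest.approx(0.0)

    def test_toy_vectors_match_closed_form(self):
        pred = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        truth = pd.Series([1.0, 2.0, 4.0], index=["a", "b", "c"])
        report = pc.evaluate(pred, truth)
        # closed form: r = cov(p,y)/(sd_p sd_y) with n denominator
        p, y = pred.to_numpy(), truth.to_numpy()
        r = ((p - p.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((p - p.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert report.r2_pearson_sq == pytest.approx(r**2, abs=1e-10)
        assert report.r2_cod == pytest.approx(1 - 1.0 / ((y - y.mean()) ** 2).sum(), abs=1e-10)
        assert report.mae == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_zero_variance_truth_is_error(self):
        pred = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="variance"):
            pc.evaluate(pred, pd.Series(5.0, index=pred.index))


def brute_force_shapley(model: ClockModel, x_row: dict) -> dict:
    """Enumerate all coalitions; value of S = intercept + sum of standardized
    contributions of the features in S (independent-features convention)."""
    feats = list(model.betas)
    p = len(feats)

    def contrib(f):
        mean, sd = model.scaling[f]
        return model.betas[f] * (x_row[f] - mean) / sd

    def v(subset):
        return model.intercept + sum(contrib(f) for f in subset)

    phi = {}
    for f in feats:
        others = [g for g in feats if g != f]
        total = 0.0
        for k in range(len(others) + 1):
            for s in itertools.combinations(others, k):
                w = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
                total += w * (v(set(s) | {f}) - v(set(s)))
        phi[f] = total
    return phi


class TestAttribute:
    def test_local_accuracy_on_fitted_clock(self, small_promoter_matrix, small_cohort):
        pm, _, _ = small_promoter_matrix
        model = pc.fit_clock(pm, small_cohort, seed=5)
        imp = pc.attribute(model, pm, small_cohort)
        preds = pc.predict(model, pm, small_cohort)
        recon = imp.attributions.sum(axis=1) + imp.base_value
        assert np.abs(recon - preds).max() < 1e-8

    def test_feature_at_training_mean_gets_zero(self):
        model = toy_model()
        x = pd.DataFrame({"a": [0.5], "b": [0.9], "c": [0.7]}, index=["S0"])
        imp = pc.attribute(model, x)
        assert imp.attributions.loc["S0", "a"] == 0.0
        assert imp.attributions.loc["S0", "c"] == 0.0

    def test_matches_brute_force_shapley_enumeration(self):
        model = toy_model()
        row = {"a": 0.62, "b": 0.11, "c": 0.73}
        imp = pc.attribute(model, pd.DataFrame(row, index=["S0"]))
        phi = brute_force_shapley(model, row)
        for f in model.betas:
            assert imp.attributions.loc["S0", f] == pytest.approx(phi[f], abs=1e-12)

    def test_symmetry_identical_columns(self):
        model = ClockModel(
            50.0, {"a": 1.5, "b": 1.5}, {"a": (0.4, 0.1), "b": (0.4, 0.1)}
        )
        x = pd.DataFrame({"a": [0.55, 0.3], "b": [0.55, 0.3]}, index=["S0", "S1"])
        imp = pc.attribute(model, x)
        assert np.array_equal(imp.attributions["a"], imp.attributions["b"])


class TestAgeGenes:
    def _report(self, rows):
        table = pd.DataFrame(rows, columns=["promoter_id", "p"])
        table["stage"] = "screen"
        table["kept"] = True
        table["reason"] = ""
        table["beta"] = 1.0
        table["batch"] = 0
        return pc.SelectionReport(table=table)

    def test_zero_beta_excluded_and_gene_dedup(self):
        model = ClockModel(
            60.0,
            {"P1": 0.0, "P2": 1.2, "P3": -0.4},
            {p: (0.5, 0.1) for p in ("P1", "P2", "P3")},
        )
        report = self._report([("P1", 1e-10), ("P2", 1e-6), ("P3", 1e-4)])
        gene_map = {"P1": "G1", "P2": "G2", "P3": "G2"}
        genes = pc.extract_age_genes(model, report, gene_map, p_max=1e-3)
        assert genes == ["G2"]  # P1 excluded (beta 0); P2/P3 same gene, once

    def test_empty_result_allowed(self):
        model = ClockModel(60.0, {"P1": 1.0}, {"P1": (0.5, 0.1)})
        report = self._report([("P1", 0.9)])
        assert pc.extract_age_genes(model, report, {"P1": "G1"}, p_max=1e-3) == []


class TestExport:
    def test_roundtrip_predictions_identical(self, tmp_path):
        model = toy_model()
        path = tmp_path / "coef.tsv"
        pc.export_coefficients(model, path)
        back = pc.import_coefficients(path)
        rng = np.random.default_rng(0)
        x = pd.DataFrame(
            {"a": rng.random(20), "b": rng.random(20), "c": rng.random(20)},
            index=[f"S{i}" for i in range(20)],
        )
        assert np.abs(pc.predict(model, x) - pc.predict(back, x)).max() < 1e-12

    def test_row_count_and_raw_scale_reconstruction(self, tmp_path):
        model = toy_model()
        path = tmp_path / "coef.tsv"
        pc.export_coefficients(model, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 4  # 3 betas + intercept
        x = pd.DataFrame({"a": [0.61], "b": [0.22], "c": [0.68]}, index=["S0"])
        feats = df[df["feature_id"] != "(intercept)"]
        raw = float(df.loc[df["feature_id"] == "(intercept)", "beta_std"].iloc[0])
        for r in feats.itertuples():
            raw += float(r.beta_raw) * (x[r.feature_id].iloc[0] - float(r.mean))
        assert raw == pytest.approx(pc.predict(model, x).iloc[0], abs=1e-10)

    def test_unfitted_model_export_error(self, tmp_path):
        with pytest.raises(ValueError, match="coefficients"):
            pc.export_coefficients(ClockModel(0.0, {}, {}), tmp_path / "c.tsv")
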