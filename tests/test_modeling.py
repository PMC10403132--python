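"""VIF pruning, linearity diagnosis, BIC degree selection and model fitting."""

import numpy as np
import pandas as pd
import pytest

from pasablood.modeling import (
    ModelConfig,
    diagnose_linearity,
    fit_polynomial,
    model_parameter,
    prune_multicollinear,
    select_degree,
    vif_scores,
)


def _design(rng, n=80, p=5):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )


class TestVif:
    def test_orthogonal_standardized_features_have_vif_one(self):
        n = 40
        x1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x2 = np.tile([1.0, -1.0], n // 2)
        vifs = vif_scores(pd.DataFrame({"a": x1, "b": x2}))
        assert vifs["a"] == pytest.approx(1.0, abs=1e-10)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_gives_infinite_vif(self, rng):
        x = rng.normal(size=30)
        vifs = vif_scores(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)}))
        assert np.isinf(vifs["a"])
        assert np.isinf(vifs["b"])

    def test_matches_independent_regression_oracle(self, rng):
        import statsmodels.api as sm

        X = _design(rng, n=60, p=5)
        # make the columns correlated so VIFs are interesting
        X["f1"] = X["f0"] * 0.8 + X["f1"] * 0.3
        vifs = vif_scores(X)
        for j, name in enumerate(X.columns):
            others = X.drop(columns=name)
            fit = sm.OLS(X[name], sm.add_constant(others)).fit()
            assert vifs[name] == pytest.approx(1.0 / (1.0 - fit.rsquared), rel=1e-8)

    def test_needs_two_features(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            vif_scores(_design(rng, p=1))


class TestPrune:
    def test_identity_when_all_below_threshold(self, rng):
        X = _design(rng, n=100, p=4)
        retained, log = prune_multicollinear(X)
        assert retained == list(X.columns)
        assert log == []

    def test_single_feature_skipped(self, rng):
        X = _design(rng, p=1)
        retained, log = prune_multicollinear(X)
        assert retained == ["f0"]
        assert log == []

    def test_near_duplicate_pair_loses_exactly_one(self, rng):
        X = _design(rng, n=60, p=3)
        X["f1"] = X["f0"] + rng.normal(0, 0.01, size=60)
        retained, log = prune_multicollinear(X)
        assert len(log) == 1
        assert log[0][0] in ("f0", "f1")
        assert log[0][1] > 10
        final_vifs = vif_scores(X[retained])
        assert final_vifs.max() <= 10

    def test_terminates_with_bounded_removals(self, rng):
        X = _design(rng, n=50, p=6)
        for i in range(1, 6):
            X[f"f{i}"] = X["f0"] + rng.normal(0, 1e-4, size=50)
        retained, log = prune_multicollinear(X)
        assert len(log) <= 5
        assert len(retained) >= 1


class TestDiagnosis:
    def test_type_one_error_near_alpha_under_linear_model(self):
        """Each directional test rejects near its nominal 5% level and the
        overall linear verdict holds for most normal linear datasets."""
        rng = np.random.default_rng(101)
        n, trials = 500, 200
        rates = {"skew": 0, "kurt": 0, "link": 0, "hetero": 0}
        linear_count = 0
        for _ in range(trials):
            x = rng.uniform(0, 1, size=n)
            y = 1.0 + 2.0 * x + rng.normal(size=n)
            d = diagnose_linearity(pd.DataFrame({"x": x}), y)
            rates["skew"] += d.skewness_p <= 0.05
            rates["kurt"] += d.kurtosis_p <= 0.05
            rates["link"] += d.link_p <= 0.05
            rates["hetero"] += d.hetero_p <= 0.05
            linear_count += d.is_linear
        for name, count in rates.items():
            assert 0.005 <= count / trials <= 0.12, (name, count / trials)
        # six simultaneous retentions: (1-alpha)^6 ~ 0.74 when independent
        assert linear_count / trials >= 0.66

    def test_quadratic_data_detected_as_nonlinear(self):
        rng = np.random.default_rng(202)
        n, trials = 200, 200
        nonlinear = 0
        for _ in range(trials):
            x = rng.uniform(0, 2, size=n)
            y = x**2 + rng.normal(0, 0.05, size=n)
            d = diagnose_linearity(pd.DataFrame({"x": x}), y)
            nonlinear += not d.is_linear
        assert nonlinear / trials >= 0.95

    def test_durbin_watson_near_two_for_iid_residuals(self):
        rng = np.random.default_rng(303)
        n, trials = 100, 200
        dws = []
        for _ in range(trials):
            x = rng.uniform(size=n)
            y = x + rng.normal(size=n)
            d = diagnose_linearity(pd.DataFrame({"x": x}), y)
            assert 0.0 <= d.durbin_watson <= 4.0
            dws.append(d.durbin_watson)
        assert 1.8 <= np.mean(dws) <= 2.2

    def test_too_small_sample_rejected(self, rng):
        X = _design(rng, n=6, p=3)
        with pytest.raises(ValueError, match="too few"):
            diagnose_linearity(X, np.arange(6.0))


class TestFitPolynomial:
    def test_perfect_fit_has_unit_r2(self):
        x = np.linspace(0, 1, 20)
        X = pd.DataFrame({"x": x})
        y = 2.0 + 3.0 * x
        fit = fit_polynomial(X, y, 1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_adjusted_r2_formula_at_known_point(self, rng):
        """adj R^2 = 1 - (1-R^2)(n-1)/(n-p-1) evaluated at R^2=0.9, n=12, p=2."""
        # construct data with R^2 exactly 0.9 via orthogonal residual injection
        n = 12
        x1 = np.arange(n, dtype=float)
        x2 = (np.arange(n) % 3).astype(float)
        X = pd.DataFrame({"a": x1, "b": x2})
        import statsmodels.api as sm

        signal = 1.0 + 0.5 * x1 + 2.0 * x2
        resid_dir = rng.normal(size=n)
        design = sm.add_constant(np.column_stack([x1, x2]))
        hat = design @ np.linalg.solve(design.T @ design, design.T @ resid_dir)
        resid_dir = resid_dir - hat  # orthogonal to the design
        var_sig = np.sum((signal - signal.mean()) ** 2)
        resid_dir *= np.sqrt(var_sig / 9.0 / np.sum(resid_dir**2))  # TSS ratio 0.1
        y = signal + resid_dir
        fit = fit_polynomial(X, y, 1)
        assert fit.r2 == pytest.approx(0.9, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1 - 0.1 * 11 / 9, abs=1e-10)
        assert fit.adj_r2 <= fit.r2

    def test_bic_identity(self, rng):
        X = _design(rng, n=40, p=2)
        y = X["f0"] * 2 + rng.normal(size=40)
        fit = fit_polynomial(X, y, 2)
        assert fit.bic == pytest.approx(
            np.log(fit.n) * fit.k - 2 * fit.log_likelihood, rel=1e-12
        )
        assert fit.k == len(fit.coefficients) + 1

    def test_power_terms_without_interactions(self, rng):
        X = _design(rng, n=50, p=2)
        y = rng.normal(size=50)
        fit = fit_polynomial(X, y, 3)
        assert list(fit.coefficients.index) == [
            "const", "f0", "f0^2", "f0^3", "f1", "f1^2", "f1^3"
        ]

    def test_singular_power_expansion_rejected_by_name(self):
        X = pd.DataFrame({"bad": np.tile([0.0, 1.0], 10)})  # x^2 == x
        y = np.arange(20.0)
        with pytest.raises(ValueError, match="bad"):
            fit_polynomial(X, y, 2)

    def test_adj_r2_never_exceeds_r2(self, rng):
        for _ in range(10):
            X = _design(rng, n=30, p=3)
            y = rng.normal(size=30)
            fit = fit_polynomial(X, y, 1)
            assert fit.adj_r2 <= fit.r2 + 1e-12


class TestSelectDegree:
    @staticmethod
    def _run_trials(degree, n, trials, seed):
        rng = np.random.default_rng(seed)
        coefs = {2: (1.0, 2.0, 3.0), 3: (1.0, 1.0, -2.0, 4.0)}[degree]
        hits = 0
        for _ in range(trials):
            x = rng.uniform(0, 1, size=n)
            y = np.polynomial.polynomial.polyval(x, np.array(coefs))
            y = y + rng.normal(0, 0.1, size=n)
            X = pd.DataFrame({"x": x})
            diag = diagnose_linearity(X, y)
            hits += select_degree(X, y, diag) == degree
        return hits / trials

    def test_linear_diagnosis_forces_degree_one(self, rng):
        X = _design(rng, n=100, p=1)
        y = 2 * X["f0"] + rng.normal(size=100)
        diag = diagnose_linearity(X, y)
        assert diag.is_linear
        assert select_degree(X, y, diag) == 1

    def test_recovers_quadratic_degree(self):
        assert self._run_trials(2, n=200, trials=100, seed=11) >= 0.9

    def test_recovers_cubic_degree(self):
        assert self._run_trials(3, n=200, trials=100, seed=12) >= 0.9

    def test_selection_consistency_grows_with_n(self):
        rates = [self._run_trials(2, n=n, trials=40, seed=21) for n in (50, 200, 800)]
        assert rates[2] >= rates[0] - 0.05  # nondecreasing up to MC error
        assert rates[2] >= 0.9


class TestModelParameter:
    @staticmethod
    def _cohort(rng, n=100):
        feats = pd.DataFrame(
            {
                "f_signal": rng.uniform(0.5, 1.5, size=n),
                "f_noise1": rng.normal(size=n),
                "f_noise2": rng.normal(size=n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        return feats

    def test_planted_quadratic_recovered(self, rng):
        """Across replicate cohorts the generating degree dominates and the
        adjusted R^2 tracks the generating R^2 (single draws can land on a
        neighboring degree by BIC sampling noise)."""
        degrees, errors = [], []
        for _ in range(20):
            feats = self._cohort(rng)
            x = feats["f_signal"].to_numpy()
            mu = 2.0 + 3.0 * x**2
            noise_sd = 0.583  # generating R^2 ~ 0.9 for this x spread
            y = mu + rng.normal(0, noise_sd, size=len(x))
            gen_r2 = mu.var(ddof=1) / (mu.var(ddof=1) + noise_sd**2)
            panel = pd.DataFrame({"UA": y}, index=feats.index)
            fit, _ = model_parameter(feats, panel, "UA")
            assert fit is not None
            degrees.append(fit.degree)
            errors.append(abs(fit.adj_r2 - gen_r2))
        assert np.mean(np.asarray(degrees) == 2) >= 0.7
        assert np.mean(errors) <= 0.05

    def test_no_effect_parameter_left_unmodelled(self, rng):
        feats = self._cohort(rng)
        panel = pd.DataFrame({"BUN": rng.normal(size=len(feats))}, index=feats.index)
        fit, prov = model_parameter(feats, panel, "BUN")
        assert fit is None
        assert "no significantly associated" in prov["reason"]

    def test_single_significant_feature_skips_vif_as_na(self, rng):
        feats = self._cohort(rng)
        y = 1.0 + 2.0 * feats["f_signal"] + rng.normal(0, 0.1, size=len(feats))
        panel = pd.DataFrame({"CRE": y}, index=feats.index)
        fit, prov = model_parameter(feats, panel, "CRE")
        assert fit is not None
        assert prov["vif"] == "NA"
        assert prov["significant_features"] == ["f_signal"]

    def test_unknown_parameter_rejected(self, rng):
        feats = self._cohort(rng)
        panel = pd.DataFrame({"UA": rng.normal(size=len(feats))}, index=feats.index)
        with pytest.raises(ValueError, match="nope"):
            model_parameter(feats, panel, "nope")
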