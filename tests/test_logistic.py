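"""Dummy-coded logistic regression: IRLS fit and Wald odds ratios."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mitonuclear import (
    DesignSpec,
    IndividualRecord,
    encode_design,
    fit_logistic,
    fit_stratum_model,
    stratify,
)


def records_from_2x2(a, b, c, d):
    """a/b = exposed cases/controls, c/d = reference cases/controls."""
    recs = []
    for label, cases, controls in [("UK_CG", a, b), ("HV_CC", c, d)]:
        cluster, genotype = label.split("_")
        for i in range(cases):
            recs.append(IndividualRecord(f"{label}c{i}", 1, cluster=cluster, genotype=genotype))
        for i in range(controls):
            recs.append(IndividualRecord(f"{label}n{i}", 0, cluster=cluster, genotype=genotype))
    return recs


class TestEncodeDesign:
    def test_twelve_strata_give_eleven_indicators(self, cohort):
        X, y = encode_design(cohort, DesignSpec(reference_stratum="HV_CC"))
        assert X.shape[1] == 12  # intercept + 11 indicators
        assert "HV_CC" not in X.columns
        assert y.sum() == 1118

    def test_reference_rows_are_all_zero(self, cohort):
        X, _ = encode_design(cohort, DesignSpec(reference_stratum="HV_CC"))
        indicators = X.drop(columns="const")
        n_ref = (indicators.sum(axis=1) == 0).sum()
        assert n_ref == 265  # the HV_CC stratum size

    def test_two_strata_one_indicator(self):
        recs = records_from_2x2(5, 5, 5, 5)
        X, _ = encode_design(recs, DesignSpec(reference_stratum="HV_CC"))
        assert list(X.columns) == ["const", "UK_CG"]

    def test_column_sums_match_label_counts(self, cohort):
        X, _ = encode_design(cohort, DesignSpec(reference_stratum="HV_CC"))
        table = stratify(cohort)
        for label in table.labels:
            if label == "HV_CC":
                continue
            assert X[label].sum() == table.strata[label][1]

    def test_missing_reference_errors(self, cohort):
        with pytest.raises(ValueError, match="reference"):
            encode_design(cohort, DesignSpec(reference_stratum="ZZ_XX"))


class TestFitLogistic:
    def test_intercept_only_half_cases(self):
        X = pd.DataFrame({"const": np.ones(40)})
        y = np.array([1, 0] * 20, dtype=float)
        fit = fit_logistic(X, y)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.odds_ratios["const"] == pytest.approx(1.0, abs=1e-8)

    def test_2x2_closed_form_from_published_counts(self):
        # exposed stratum 184 cases / 52 controls vs reference 183 / 82
        recs = records_from_2x2(184, 52, 183, 82)
        fit = fit_stratum_model(recs, DesignSpec(reference_stratum="HV_CC"))
        expected = (184 * 82) / (52 * 183)
        assert fit.odds_ratios["UK_CG"] == pytest.approx(expected, abs=1e-6)

    def test_2x2_closed_form_on_random_tables(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(3, 80, size=4)
            fit = fit_stratum_model(records_from_2x2(a, b, c, d))
            beta = np.log((a * d) / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.params["UK_CG"] == pytest.approx(beta, abs=1e-6)
            assert fit.bse["UK_CG"] == pytest.approx(se, abs=1e-6)

    def test_fixture_reproduces_published_hv_cg_odds_ratio(self, cohort):
        fit = fit_stratum_model(cohort, DesignSpec(reference_stratum="HV_CC"))
        assert fit.odds_ratios["HV_CG"] == pytest.approx(1.58, rel=0.01)

    def test_matches_statsmodels(self, cohort):
        """Independent oracle: the full 12-stratum fit agrees with statsmodels."""
        X, y = encode_design(cohort, DesignSpec(reference_stratum="HV_CC"))
        fit = fit_logistic(X, y)
        sm_fit = sm.Logit(y, X.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), sm_fit.bse, atol=1e-6)
        assert fit.loglike == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_saturated_model_recovers_stratum_proportions(self, cohort):
        X, y = encode_design(cohort, DesignSpec(reference_stratum="HV_CC"))
        fit = fit_logistic(X, y)
        eta = X.to_numpy() @ fit.params.to_numpy()
        mu = 1 / (1 + np.exp(-eta))
        table = stratify(cohort)
        labels = np.array([r.stratum for r in cohort if r.stratum is not None])
        for label in table.labels:
            k, n = table.strata[label]
            assert mu[labels == label].mean() == pytest.approx(k / n, abs=1e-8)

    def test_confidence_interval_contains_or(self, cohort):
        fit = fit_stratum_model(cohort)
        ci = fit.conf_int_or()
        ors = fit.odds_ratios
        assert ((ci["ci_low"] <= ors) & (ors <= ci["ci_high"])).all()

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"const": np.ones(20), "dup": np.ones(20)})
        y = np.array([0, 1] * 10, dtype=float)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(X, y)

    def test_separation_warns_and_flags(self):
        X = pd.DataFrame({"const": np.ones(20), "x": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_logistic(X, y)
        assert not fit.converged

    def test_nonbinary_response_rejected(self):
        X = pd.DataFrame({"const": np.ones(4)})
        with pytest.raises(ValueError):
            fit_logistic(X, np.array([0.0, 1.0, 2.0, 0.0]))

    def test_covariate_columns(self, rng):
        recs = [
            IndividualRecord(
                f"s{i}",
                int(rng.random() < 0.5),
                sex=str(rng.choice(["M", "F"])),
                age=float(rng.uniform(50, 80)),
                cluster=str(rng.choice(["HV", "UK"])),
                genotype="CC",
            )
            for i in range(200)
        ]
        X, _ = encode_design(
            recs, DesignSpec(reference_stratum="HV_CC", covariates=("sex", "age"))
        )
        assert {"sex_M", "age"} <= set(X.columns)
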