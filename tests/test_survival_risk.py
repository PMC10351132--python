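import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

from lncpath import published_model_path
from lncpath.io_core import BIOTYPE_LNCRNA, ClinicalTable, ExpressionMatrix
from lncpath.survival_risk import (
    RiskModel,
    _cox_frame,
    _fit_cox,
    lasso_cox_select,
    logrank_test,
    multivariate_cox,
    risk_score,
    split_cohort,
    stepwise_aic,
    stratify_and_test,
    time_dependent_auc,
    univariate_screen,
)

from .conftest import SMALL_CFG, make_clinical

PUBLISHED_COEFS = {
    "AC020916.1": -0.442,
    "AC079313.1": 0.933,
    "AC245128.3": 0.333,
    "AL135818.1": -0.861,
    "LINC02818": 1.27,
    "RASA2_IT1": 2.104,
}


def indicator_matrix(active_gene, genes, value=1.0):
    values = pd.DataFrame(0.0, index=list(genes), columns=["S1"])
    values.loc[active_gene, "S1"] = value
    return ExpressionMatrix(values, pd.Series(BIOTYPE_LNCRNA, index=list(genes)))


@pytest.fixture(scope="module")
def published_model():
    return RiskModel.load(published_model_path())


class TestRiskModel:
    def test_published_fixture_matches_printed_formula(self, published_model):
        assert dict(published_model.terms) == PUBLISHED_COEFS

    def test_indicator_vectors_return_each_coefficient(self, published_model):
        for gene, coef in PUBLISHED_COEFS.items():
            expr = indicator_matrix(gene, PUBLISHED_COEFS)
            assert risk_score(published_model, expr)["S1"] == pytest.approx(coef)

    def test_all_ones_returns_coefficient_sum(self, published_model):
        values = pd.DataFrame(1.0, index=list(PUBLISHED_COEFS), columns=["S1"])
        expr = ExpressionMatrix(values, pd.Series(BIOTYPE_LNCRNA, index=list(PUBLISHED_COEFS)))
        assert risk_score(published_model, expr)["S1"] == pytest.approx(
            sum(PUBLISHED_COEFS.values())
        )

    def test_all_zero_expression_scores_zero(self, published_model):
        values = pd.DataFrame(0.0, index=list(PUBLISHED_COEFS), columns=["S1", "S2"])
        expr = ExpressionMatrix(values, pd.Series(BIOTYPE_LNCRNA, index=list(PUBLISHED_COEFS)))
        assert risk_score(published_model, expr).to_numpy() == pytest.approx([0.0, 0.0])

    def test_linearity(self, published_model):
        rng = np.random.default_rng(0)
        genes = list(PUBLISHED_COEFS)
        x = pd.DataFrame(rng.normal(size=(6, 3)), index=genes, columns=["A", "B", "C"])
        y = pd.DataFrame(rng.normal(size=(6, 3)), index=genes, columns=["A", "B", "C"])
        bio = pd.Series(BIOTYPE_LNCRNA, index=genes)
        sx = risk_score(published_model, ExpressionMatrix(x, bio))
        sy = risk_score(published_model, ExpressionMatrix(y, bio))
        combo = risk_score(published_model, ExpressionMatrix(2 * x + 3 * y, bio))
        assert combo.to_numpy() == pytest.approx((2 * sx + 3 * sy).to_numpy())

    def test_missing_gene_listed(self, published_model):
        expr = indicator_matrix("RASA2_IT1", ["RASA2_IT1", "other"])
        with pytest.raises(KeyError, match="AC020916.1"):
            risk_score(published_model, expr)

    def test_json_round_trip(self, tmp_path, published_model):
        published_model.save(tmp_path / "m.json")
        back = RiskModel.load(tmp_path / "m.json")
        assert back == published_model

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            RiskModel(terms=[])


class TestSplitCohort:
    def test_odd_size_splits_evenly(self):
        clin = make_clinical(101)
        train, test = split_cohort(clin, seed=1)
        assert sorted((len(train), len(test))) == [50, 51]

    def test_deterministic_and_disjoint(self):
        clin = make_clinical(60)
        a = split_cohort(clin, seed=3)
        b = split_cohort(clin, seed=3)
        assert a == b
        train, test = a
        assert sorted(train + test) == sorted(clin.sample_ids)
        assert not set(train) & set(test)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(make_clinical(10))


class TestLogrank:
    def test_hand_example_matches_lifelines(self):
        # 8 subjects, two arms
        time = np.array([5.0, 8, 12, 20, 6, 9, 14, 25])
        status = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        group = np.array([True, True, True, True, False, False, False, False])
        chi2, p = logrank_test(time, status, group)
        ref = lifelines_logrank(time[group], time[~group], status[group], status[~group])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_p_is_chi2_sf_of_statistic(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 40)
        status = (rng.random(40) < 0.8).astype(int)
        group = rng.random(40) < 0.5
        chi2, p = logrank_test(time, status, group)
        assert p == stats.chi2.sf(chi2, df=1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.ones(3), np.ones(3, int), np.array([True, True, True]))


class TestStratify:
    def test_cutoff_below_min_rejected(self, small_cohort):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        scores = risk_score(model, expr)
        with pytest.raises(ValueError, match="stratum"):
            stratify_and_test(scores, clin, scores.min() - 1.0)

    def test_true_model_separates(self, small_cohort):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        scores = risk_score(model, expr)
        labels, chi2, p = stratify_and_test(scores, clin, float(scores.median()))
        assert set(labels.unique()) == {"high", "low"}
        assert p < 0.01


class TestUnivariateScreen:
    def test_planted_risk_lncrnas_recovered(self):
        from lncpath.synthetic_data import SimulationConfig, generate_cohort

        for seed in (1, 2, 3):
            expr, _, clin, _, truth = generate_cohort(SimulationConfig(seed=seed))
            candidates = expr.subset_genes(truth.risk_lnc)
            passing, fits = univariate_screen(candidates, clin)
            assert set(passing) == set(truth.risk_lnc), f"seed {seed}"
            for g in truth.risk_lnc:
                assert fits[g].table.loc[g, "hazard_ratio"] == pytest.approx(
                    np.exp(fits[g].table.loc[g, "coef"])
                )

    def test_null_pass_fraction_calibrated(self):
        # no survival signal: pass fraction ~ 5%
        rng = np.random.default_rng(6)
        n, n_genes = 150, 60
        genes = [f"L{i}" for i in range(n_genes)]
        samples = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(n_genes, n)), index=genes, columns=samples),
            pd.Series(BIOTYPE_LNCRNA, index=genes),
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"os_time": rng.exponential(100, n), "os_status": (rng.random(n) < 0.7).astype(int)},
                index=pd.Index(samples, name="sample"),
            )
        )
        passing, _ = univariate_screen(expr, clin)
        # binomial(60, 0.05): central 99.9% well below 12
        assert len(passing) <= 11

    def test_single_proportional_lncrna(self):
        rng = np.random.default_rng(8)
        n = 150
        x = rng.normal(size=n)
        h = 0.01 * np.exp(1.5 * x)
        time = rng.exponential(1 / h)
        samples = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame([x], index=["L1"], columns=samples),
            pd.Series({"L1": BIOTYPE_LNCRNA}),
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"os_time": time, "os_status": np.ones(n, int)},
                index=pd.Index(samples, name="sample"),
            )
        )
        passing, fits = univariate_screen(expr, clin)
        assert passing == ["L1"]
        assert fits["L1"].table.loc["L1", "hazard_ratio"] > 1
        assert fits["L1"].table.loc["L1", "pvalue"] < 0.001

    def test_requires_enough_events(self):
        clin = make_clinical(30, frac_events=0.1)
        expr = ExpressionMatrix(
            pd.DataFrame(
                np.random.default_rng(0).normal(size=(2, 30)),
                index=["L1", "L2"],
                columns=clin.sample_ids,
            ),
            pd.Series(BIOTYPE_LNCRNA, index=["L1", "L2"]),
        )
        if clin.n_events < 10:
            with pytest.raises(ValueError, match="events"):
                univariate_screen(expr, clin)


class TestLasso:
    def test_planted_kept_noise_halved(self):
        from lncpath.synthetic_data import SimulationConfig, generate_cohort

        for seed in (1, 2, 3):
            expr, _, clin, _, truth = generate_cohort(
                SimulationConfig(seed=seed, n_samples=300)
            )
            markers = {g for v in truth.subtype_markers.values() for g in v}
            noise = [
                g
                for g in expr.lncrna_ids
                if g not in set(truth.true_assoc_lnc) and g not in markers
            ][:20]
            selected = lasso_cox_select(
                expr.subset_genes(truth.risk_lnc + noise), clin, seed=seed
            )
            assert set(truth.risk_lnc) <= set(selected), f"seed {seed}"
            assert sum(g in selected for g in noise) <= 10, f"seed {seed}"

    def test_single_strong_candidate_sign(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        time = rng.exponential(1 / (0.01 * np.exp(1.2 * x)))
        samples = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame([x, rng.normal(size=n)], index=["L1", "L2"], columns=samples),
            pd.Series(BIOTYPE_LNCRNA, index=["L1", "L2"]),
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"os_time": time, "os_status": np.ones(n, int)},
                index=pd.Index(samples, name="sample"),
            )
        )
        selected = lasso_cox_select(expr, clin, seed=0)
        assert "L1" in selected and selected["L1"] > 0

    def test_full_shrinkage_limit_empty(self):
        # the largest alpha on the path shrinks every coefficient to zero
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 5))
        y = Surv.from_arrays(rng.random(80) < 0.8, rng.exponential(10, 80))
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01)
        path.fit(X, y)
        assert np.allclose(path.coef_[:, 0], 0.0)


class TestStepwiseAic:
    def _cohort(self, seed, n=400, betas=(1.0, -1.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        genes = [f"L{i}" for i in range(len(betas))]
        samples = [f"S{i}" for i in range(n)]
        X = rng.normal(size=(len(betas), n))
        h = 0.005 * np.exp(np.asarray(betas) @ X)
        time = rng.exponential(1 / h)
        cens = rng.exponential(np.quantile(time, 0.8), n)
        expr = ExpressionMatrix(
            pd.DataFrame(X, index=genes, columns=samples),
            pd.Series(BIOTYPE_LNCRNA, index=genes),
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "os_time": np.minimum(time, cens),
                    "os_status": (time <= cens).astype(int),
                },
                index=pd.Index(samples, name="sample"),
            )
        )
        return expr, clin

    def test_noise_features_pruned(self):
        removed = 0
        for seed in range(10):
            expr, clin = self._cohort(seed)
            model = stepwise_aic(expr, clin)
            removed += "L2" not in model.gene_ids and "L3" not in model.gene_ids
            assert {"L0", "L1"} <= set(model.gene_ids)
        assert removed >= 8

    def test_final_aic_not_worse_than_full(self):
        expr, clin = self._cohort(3)
        model = stepwise_aic(expr, clin)
        full = _fit_cox(_cox_frame(expr, clin, expr.gene_ids))
        final = _fit_cox(_cox_frame(expr, clin, model.gene_ids))
        assert final.AIC_partial_ <= full.AIC_partial_ + 1e-9

    def test_within_top2_of_exhaustive_search(self):
        expr, clin = self._cohort(5, n=250)
        model = stepwise_aic(expr, clin)
        aics = []
        for r in range(1, 5):
            for combo in itertools.combinations(expr.gene_ids, r):
                cph = _fit_cox(_cox_frame(expr, clin, list(combo)))
                aics.append((float(cph.AIC_partial_), frozenset(combo)))
        aics.sort()
        top2 = {s for _, s in aics[:2]}
        assert frozenset(model.gene_ids) in top2

    def test_training_median_is_median_score(self):
        expr, clin = self._cohort(7, n=120)
        model = stepwise_aic(expr, clin)
        scores = risk_score(model, expr)
        assert model.training_median == pytest.approx(float(scores.median()))


class TestTimeDependentAuc:
    def _clin(self, time, status):
        samples = [f"S{i}" for i in range(len(time))]
        return (
            ClinicalTable(
                pd.DataFrame(
                    {"os_time": time, "os_status": status},
                    index=pd.Index(samples, name="sample"),
                )
            ),
            samples,
        )

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(11)
        n = 200
        x = rng.normal(size=n)
        time = rng.exponential(1 / (0.002 * np.exp(x)))
        clin, samples = self._clin(time, np.ones(n, int))
        scores = pd.Series(x, index=samples)
        auc = time_dependent_auc(scores, clin)
        neg = time_dependent_auc(-scores, clin)
        for h in auc:
            assert neg[h] == pytest.approx(1.0 - auc[h], abs=1e-10)

    def test_horizon_beyond_followup_skipped(self, caplog):
        rng = np.random.default_rng(12)
        n = 100
        time = rng.uniform(1, 400, n)
        clin, samples = self._clin(time, np.ones(n, int))
        scores = pd.Series(rng.normal(size=n), index=samples)
        with caplog.at_level("WARNING"):
            auc = time_dependent_auc(scores, clin, horizons=(365, 1825))
        assert 1825.0 not in auc
        assert "skipped" in caplog.text


class TestMultivariateCox:
    def test_risk_score_significant_stage_not(self, small_cohort):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        rng = np.random.default_rng(0)
        features = pd.DataFrame(
            {
                "risk_score": risk_score(model, expr),
                "stage": rng.choice(["I", "II", "III"], size=expr.n_samples),
            },
            index=expr.sample_ids,
        )
        fit, lin_pred, calib = multivariate_cox(features, clin)
        assert fit.table.loc["risk_score", "pvalue"] < 0.01
        stage_rows = [i for i in fit.table.index if i.startswith("stage_")]
        assert min(fit.table.loc[stage_rows, "pvalue"]) > 0.01
        assert len(lin_pred) == expr.n_samples

    def test_reference_level_invariance_up_to_shift(self, small_cohort):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        rng = np.random.default_rng(1)
        stage = rng.choice(["I", "II", "III"], size=expr.n_samples)
        base = pd.DataFrame(
            {"risk_score": risk_score(model, expr), "stage": stage}, index=expr.sample_ids
        )
        relabeled = base.assign(stage=[{"I": "Z-I", "II": "A-II", "III": "III"}[s] for s in stage])
        _, lp_a, _ = multivariate_cox(base, clin)
        _, lp_b, _ = multivariate_cox(relabeled, clin)
        diff = (lp_a - lp_b).to_numpy()
        assert np.ptp(diff) < 1e-6  # constant shift only

    def test_collinear_covariate_dropped(self, small_cohort, caplog):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        scores = risk_score(model, expr)
        features = pd.DataFrame(
            {"risk_score": scores, "twice": 2 * scores}, index=expr.sample_ids
        )
        with caplog.at_level("WARNING"):
            fit, _, _ = multivariate_cox(features, clin)
        assert "collinear" in caplog.text
        assert "twice" not in fit.table.index

    def test_calibration_close_on_oracle_predictor(self, small_cohort):
        expr, _, clin, _, truth = small_cohort
        model = RiskModel(terms=[(g, truth.cox_betas[g]) for g in truth.risk_lnc])
        features = pd.DataFrame({"risk_score": risk_score(model, expr)})
        _, _, calib = multivariate_cox(features, clin, n_bins=5)
        assert not calib.empty
        close = (calib["predicted"] - calib["observed"]).abs() < 0.2
        assert close.mean() >= 0.8
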