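"""Residuals, multistart fitting and BIC model comparison."""

import dataclasses

import numpy as np
import pytest

from selhier.calibrate import (
    CalibrationError,
    FitResult,
    bic_score,
    chi_squared,
    compare_models,
    make_fit_problem,
    multistart_fit,
    weighted_residuals,
)
from selhier.synthetic import GroundTruth, simulate_dataset


@pytest.fixture(scope="module")
def strong_truth(panel_truth):
    _, truth = panel_truth
    g = next(x for x in truth.genes if x.class_label == "strong_up")
    return GroundTruth([g], truth.se_map, truth.noise_cv, truth.seed)


@pytest.fixture(scope="module")
def noiseless_problem(strong_truth):
    g = strong_truth.genes[0]
    ds = simulate_dataset(strong_truth, n_reps=3, seed=0, cv=0.0)
    return g, make_fit_problem(
        ds, g.features.gene_id, "M1", g.features, se_map=strong_truth.se_map,
        pool_variance=True,
    )


class TestResiduals:
    def test_zero_at_generating_parameters_on_noiseless_data(self, noiseless_problem):
        g, problem = noiseless_problem
        r = weighted_residuals(
            problem, {"k_bind": g.params.k_bind, "k_nmd": g.params.k_nmd, "k_sec": g.params.k_sec}
        )
        assert np.abs(r).max() < 1e-10

    def test_doubling_errors_halves_residuals(self, strong_truth):
        g = strong_truth.genes[0]
        ds = simulate_dataset(strong_truth, n_reps=8, seed=3)
        problem = make_fit_problem(ds, g.features.gene_id, "M1", g.features,
                                   se_map=strong_truth.se_map)
        values = {"k_bind": 10.0, "k_nmd": 0.5, "k_sec": 5.0}
        r1 = weighted_residuals(problem, values)
        doubled = dataclasses.replace(problem, obs_se=2 * problem.obs_se)
        r2 = weighted_residuals(doubled, values)
        np.testing.assert_allclose(r2, r1 / 2)

    def test_zero_spread_suggests_pooled_variance(self, strong_truth):
        g = strong_truth.genes[0]
        ds = simulate_dataset(strong_truth, n_reps=3, seed=0, cv=0.0)
        with pytest.raises(CalibrationError, match="pool_variance"):
            make_fit_problem(ds, g.features.gene_id, "M1", g.features,
                             se_map=strong_truth.se_map)

    def test_chi2_at_truth_is_calibrated(self, strong_truth):
        """At the generating parameters the weighted chi-square should sit at
        the scale of the number of informative conditions (4 here)."""
        g = strong_truth.genes[0]
        values = {"k_bind": g.params.k_bind, "k_nmd": g.params.k_nmd, "k_sec": g.params.k_sec}
        chis = []
        for seed in range(30):
            ds = simulate_dataset(strong_truth, n_reps=8, seed=seed)
            problem = make_fit_problem(ds, g.features.gene_id, "M1", g.features,
                                       se_map=strong_truth.se_map)
            chis.append(chi_squared(problem, values))
        assert 1.5 < np.mean(chis) < 12.0


class TestMultistartFit:
    def test_single_parameter_problem_recovered_from_any_seed(self, noiseless_problem):
        g, base = noiseless_problem
        problem = dataclasses.replace(
            base,
            base_params=g.params,
            free_names=("k_nmd",),
            bounds={"k_nmd": (1e-4, 3.0)},
        )
        for seed in (0, 1, 2):
            fit = multistart_fit(problem, n_starts=3, seed=seed)
            assert fit.values["k_nmd"] == pytest.approx(g.params.k_nmd, rel=1e-4)

    def test_noiseless_generative_recovery_reaches_zero_objective(self, noiseless_problem):
        _, problem = noiseless_problem
        fit = multistart_fit(problem, n_starts=6, seed=5)
        assert fit.chi2 < 1e-6

    def test_best_objective_is_minimum_over_starts(self, strong_truth):
        g = strong_truth.genes[0]
        ds = simulate_dataset(strong_truth, n_reps=8, seed=4)
        problem = make_fit_problem(ds, g.features.gene_id, "M1", g.features,
                                   se_map=strong_truth.se_map)
        fit = multistart_fit(problem, n_starts=5, seed=6)
        assert fit.chi2 == pytest.approx(min(s.chi2 for s in fit.starts))
        assert fit.bic == pytest.approx(bic_score(fit.chi2, fit.n_data, fit.k_free))

    def test_flat_gene_objectives_tie_across_starts(self, panel_truth, dataset, features_by_gene):
        """A non-responsive gene leaves the competition rates unconstrained:
        many starts end at indistinguishable objectives (the situation the
        identifiability stage exists for)."""
        problem = make_fit_problem(dataset, "SELK", "M1", features_by_gene["SELK"])
        fit = multistart_fit(problem, n_starts=8, seed=7)
        finals = np.array([s.chi2 for s in fit.starts])
        assert (np.abs(finals - fit.chi2) < 0.05 * max(1.0, fit.chi2)).mean() >= 0.5


class TestBicComparison:
    def test_zero_misfit_zero_parameters_gives_zero(self):
        assert bic_score(0.0, 10, 0) == 0.0

    def test_parameter_penalty_is_log_n(self):
        assert bic_score(5.0, 10, 3) - bic_score(5.0, 10, 2) == pytest.approx(np.log(10))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bic_score(1.0, 0, 1)
        with pytest.raises(ValueError):
            bic_score(1.0, 5, -1)

    def _fit(self, model_id, chi2, k_free, dataset_hash="h", gene="G"):
        from selhier.features import TranscriptFeatures
        from selhier.models import RateParameters

        return FitResult(
            gene_id=gene, model_id=model_id, params=RateParameters(),
            features=TranscriptFeatures(gene, 100, 50, 0), values={},
            chi2=chi2, n_data=5, k_free=k_free,
            bic=bic_score(chi2, 5, k_free), starts=[], seed=0, dataset_hash=dataset_hash,
        )

    def test_equal_fits_prefer_fewer_parameters(self):
        table = compare_models([self._fit("M2", 2.0, 3), self._fit("M1", 2.0, 2)])
        assert table.iloc[0]["model_id"] == "M1"
        assert table["equivalent"].all()  # delta BIC = ln(5) < 2

    def test_single_fit_ranks_itself(self):
        table = compare_models([self._fit("M1", 1.0, 2)])
        assert len(table) == 1 and table.iloc[0]["delta_bic"] == 0.0

    def test_mixed_datasets_rejected(self):
        with pytest.raises(CalibrationError, match="different dataset"):
            compare_models([self._fit("M1", 1.0, 2, "h1"), self._fit("M3", 1.0, 4, "h2")])

    def test_inverse_gene_ranks_deadenylation_model_first(self, dataset, features_by_gene):
        fits = [
            multistart_fit(
                make_fit_problem(dataset, "GPX2", m, features_by_gene["GPX2"]),
                n_starts=4, seed=8,
            )
            for m in ("M1", "M2", "M3")
        ]
        table = compare_models(fits)
        assert table.iloc[0]["model_id"] == "M3"
        assert table[table.model_id == "M1"]["delta_bic"].iloc[0] > 2
        assert table[table.model_id == "M2"]["delta_bic"].iloc[0] > 2
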