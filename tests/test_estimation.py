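"""Likelihood, ML fitting, G², restriction tests, standard errors."""

import logging
import math

import numpy as np
import pytest

from cooppunish import (
    CategoryCounts,
    FitOptions,
    ModelSpec,
    PARAM_NAMES,
    ParameterSet,
    closed_form_mle,
    fit,
    log_likelihood,
    standard_errors,
)
from cooppunish import test_restriction as run_restriction_test
from cooppunish.validation import (
    expected_counts,
    optimizer_vs_closed_form,
    simulate_counts,
)


def one_condition(vec) -> CategoryCounts:
    return CategoryCounts({"only": np.asarray(vec, dtype=float)})


class TestLogLikelihood:
    SPEC = ModelSpec(conditions=["only"])

    def _free(self, **kwargs):
        values = dict(C=0.5, pMoral=0.5, pHypocritical=0.5, pAntisocial=0.5, b=0.5)
        values.update(kwargs)
        return np.array([values[n] for n in PARAM_NAMES])

    def test_zero_counts_give_zero(self):
        assert log_likelihood(self.SPEC, self._free(), one_condition(np.zeros(8))) == 0.0

    def test_certain_category_gives_zero(self):
        counts = one_condition([0, 10, 0, 0, 0, 0, 0, 0])
        free = self._free(C=1, pMoral=0, b=0)
        assert log_likelihood(self.SPEC, free, counts) == pytest.approx(0.0)

    def test_split_punish_cell(self):
        # C=1, pMoral=0.5, b=0: the coop cell splits punish/none 50/50
        counts = one_condition([5, 5, 0, 0, 0, 0, 0, 0])
        free = self._free(C=1, pMoral=0.5, b=0)
        assert log_likelihood(self.SPEC, free, counts) == pytest.approx(10 * math.log(0.5))

    def test_impossible_observation_is_minus_infinity(self):
        counts = one_condition([0, 0, 1, 0, 0, 0, 0, 0])  # a defection observed
        free = self._free(C=1.0)  # but the model says certain cooperation
        assert log_likelihood(self.SPEC, free, counts) == float("-inf")


class TestClosedFormOracle:
    def test_closed_form_is_exact_on_expected_counts(self):
        true = ParameterSet(0.64, 0.47, 0.31, 0.12, 0.09)
        counts = expected_counts({"only": true}, {"only": (4000, 6000)})
        est = closed_form_mle(counts.counts["only"])
        for name in PARAM_NAMES:
            assert getattr(est, name) == pytest.approx(getattr(true, name), abs=1e-10)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_optimizer_matches_closed_form(self, seed):
        assert optimizer_vs_closed_form(n_datasets=3, seed=seed) < 1e-6


class TestFit:
    def test_perfect_fit_recovers_parameters_with_zero_g_squared(self):
        true = {
            "a": ParameterSet(0.70, 0.50, 0.35, 0.15, 0.05),
            "b": ParameterSet(0.56, 0.40, 0.28, 0.10, 0.05),
        }
        counts = expected_counts(true, {"a": (2780, 4170), "b": (3990, 2660)})
        result = fit(ModelSpec(conditions=["a", "b"]), counts, FitOptions(seed=0))
        assert result.converged
        assert result.g_squared == pytest.approx(0.0, abs=1e-6)
        for cond, ps in true.items():
            for name in PARAM_NAMES:
                assert getattr(result.estimates[cond], name) == pytest.approx(
                    getattr(ps, name), abs=1e-6
                )

    def test_p_value_consistent_with_g_squared_and_df(self, exp1_counts):
        from scipy.stats import chi2

        result = fit(ModelSpec(conditions=exp1_counts.conditions), exp1_counts,
                     FitOptions(seed=2))
        assert result.df == 2
        assert result.p_value == pytest.approx(chi2.sf(result.g_squared, 2))

    def test_start_point_robustness(self, exp1_counts):
        spec = ModelSpec(conditions=exp1_counts.conditions)
        objectives = [
            fit(spec, exp1_counts, FitOptions(n_starts=5, seed=s)).best_start_objective
            for s in (101, 202, 303)
        ]
        assert max(objectives) - min(objectives) < 1e-6

    def test_empty_tree_warns_and_still_fits(self, caplog):
        counts = one_condition([30, 50, 10, 40, 0, 0, 0, 0])
        with caplog.at_level(logging.WARNING, logger="cooppunish.estimation"):
            result = fit(ModelSpec(conditions=["only"]), counts, FitOptions(seed=3))
        assert any("no observations" in rec.message for rec in caplog.records)
        assert np.isfinite(result.log_lik)


class TestRestriction:
    def test_identical_conditions_give_null_delta(self):
        vec = np.array([420, 380, 90, 210, 55, 745, 40, 160], dtype=float)
        counts = CategoryCounts({"a": vec, "b": vec.copy()})
        spec = ModelSpec(conditions=["a", "b"])
        result = run_restriction_test(
            spec, counts, (("a", "C"), ("b", "C")), FitOptions(seed=4)
        )
        assert result.df == 1
        assert result.delta_g_squared == pytest.approx(0.0, abs=1e-6)
        assert result.p_value > 0.99

    def test_delta_never_negative_across_battery(self, exp1_counts):
        from cooppunish import default_battery

        spec = ModelSpec(conditions=exp1_counts.conditions)
        base = fit(spec, exp1_counts, FitOptions(seed=5))
        for restriction in default_battery(exp1_counts.conditions):
            result = run_restriction_test(
                spec, exp1_counts, restriction, FitOptions(seed=5), base_fit=base
            )
            assert result.delta_g_squared >= 0.0

    def test_cross_parameter_restriction_equates_across_names(self):
        rng = np.random.default_rng(6)
        true = {
            "a": ParameterSet(0.7, 0.5, 0.3, 0.2, 0.05),
            "b": ParameterSet(0.6, 0.4, 0.3, 0.1, 0.05),
        }
        counts = simulate_counts(true, {"a": (3000, 4500), "b": (4500, 3000)}, rng)
        spec = ModelSpec(conditions=["a", "b"])
        result = run_restriction_test(
            spec, counts, (("a", "pMoral"), ("b", "pAntisocial")), FitOptions(seed=6)
        )
        est = result.restricted_fit.estimates
        assert est["a"].pMoral == pytest.approx(est["b"].pAntisocial, abs=1e-9)
        assert result.delta_g_squared > 10  # 0.5 vs 0.1 truly differ

    def test_null_restriction_statistic_is_chi_square_1(self):
        """Under a true equality, ΔG² should be chi-square(1): mean ≈ 1."""
        rng = np.random.default_rng(7)
        true = {
            "a": ParameterSet(0.65, 0.45, 0.30, 0.12, 0.06),
            "b": ParameterSet(0.65, 0.40, 0.25, 0.10, 0.08),  # equal C only
        }
        totals = {"a": (2500, 3750), "b": (3750, 2500)}
        spec = ModelSpec(conditions=["a", "b"])
        options = FitOptions(n_starts=2, seed=8)
        deltas = []
        for _ in range(500):
            counts = simulate_counts(true, totals, rng)
            result = run_restriction_test(
                spec, counts, (("a", "C"), ("b", "C")), options
            )
            deltas.append(result.delta_g_squared)
        mean = np.mean(deltas)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(mean - 1.0) < 3 * se


class TestStandardErrors:
    def test_cooperation_se_matches_pooled_binomial(self, one_condition_counts):
        spec = ModelSpec(conditions=["only"])
        options = FitOptions(seed=9)
        result = standard_errors(
            fit(spec, one_condition_counts, options), spec, one_condition_counts, options
        )
        n_total = one_condition_counts.total()
        c_hat = result.estimates["only"].C
        expected = math.sqrt(c_hat * (1 - c_hat) / n_total)
        assert result.se_method == "information"
        assert result.standard_errors["only"]["C"] == pytest.approx(expected, abs=1e-6)

    def test_boundary_estimate_falls_back_to_bootstrap(self):
        # equal punish rates in every cell drive all specific punishment
        # parameters to the 0 boundary; SEs must come from the bootstrap
        counts = one_condition([80, 720, 20, 180, 50, 450, 30, 270])
        spec = ModelSpec(conditions=["only"])
        options = FitOptions(seed=10, bootstrap_draws=100)
        result = fit(spec, counts, options)
        # punish rate 0.1 in every cell → all specific params 0 (boundary)
        assert result.estimates["only"].b == pytest.approx(0.1, abs=1e-5)
        assert result.boundary_flags  # specific parameters flagged at 0
        result = standard_errors(result, spec, counts, options)
        assert result.se_method == "parametric-bootstrap"
        assert result.standard_errors["only"]["b"] > 0

    def test_bootstrap_and_information_se_agree(self, exp1_counts):
        spec = ModelSpec(conditions=exp1_counts.conditions)
        options = FitOptions(seed=11, bootstrap_draws=200)
        fitted = fit(spec, exp1_counts, options)
        info = standard_errors(fitted, spec, exp1_counts, options)
        assert info.se_method == "information"
        info_se = {c: dict(v) for c, v in info.standard_errors.items()}
        from cooppunish.estimation import _bootstrap_se

        boot = _bootstrap_se(spec, fitted, exp1_counts, options)
        for (cond, name), idx in spec.sharing.items():
            assert boot[idx] == pytest.approx(info_se[cond][name], rel=0.10)

    def test_unconverged_fit_is_rejected(self, one_condition_counts):
        spec = ModelSpec(conditions=["only"])
        result = fit(spec, one_condition_counts, FitOptions(seed=12))
        result.converged = False
        with pytest.raises(ValueError, match="converged"):
            standard_errors(result, spec, one_condition_counts)
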