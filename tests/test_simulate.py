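"""Experiment simulator: schedules, payoffs, ledger, aggregation."""

import numpy as np
import pandas as pd
import pytest

from cooppunish import (
    ConditionDesign,
    ParameterSet,
    aggregate_counts,
    apply_payoffs,
    experiment_presets,
    simulate_experiment,
)
from cooppunish.validation import generator_consistency
from tests.conftest import TRUE_PARAMS


class TestApplyPayoffs:
    @pytest.mark.parametrize(
        "participant,partner,investment,fine,expected",
        [
            ("cooperate", "cooperate", 0, 0, 10),
            ("defect", "defect", 0, 0, 0),
            ("defect", "cooperate", 0, 0, 20),
            ("cooperate", "defect", 0, 0, -10),
            ("cooperate", "defect", 2, 0, -12),
            ("defect", "cooperate", 0, 20, 0),
        ],
    )
    def test_payoff_deltas(self, participant, partner, investment, fine, expected):
        assert apply_payoffs(participant, partner, investment, fine) == expected

    def test_worked_example_trial(self):
        """Participant cooperates, partner defects, participant invests 2:
        participant nets −12 and the punished partner nets 0 (+20 − 20)."""
        assert apply_payoffs("cooperate", "defect", 2, 0) == -12
        assert apply_payoffs("defect", "cooperate", 0, 20) == 0

    def test_rejects_invalid_amounts(self):
        with pytest.raises(ValueError):
            apply_payoffs("cooperate", "cooperate", 4, 0)
        with pytest.raises(ValueError):
            apply_payoffs("cooperate", "cooperate", 0, 15)


class TestSimulateExperiment:
    def test_same_seed_identical_tables(self, exp1_designs):
        a = simulate_experiment(exp1_designs, TRUE_PARAMS, seed=99)
        b = simulate_experiment(exp1_designs, TRUE_PARAMS, seed=99)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_experiment(exp1_designs, TRUE_PARAMS, seed=100)
        assert not a.equals(c)

    def test_exact_schedule_per_participant(self, exp1_trials):
        per = exp1_trials.groupby(["condition", "participant_id"])[
            "partner_decision"
        ].apply(lambda s: (s == "cooperate").sum())
        by_cond = per.groupby("condition").unique()
        assert list(by_cond["cooperating-majority"]) == [15]
        assert list(by_cond["defecting-majority"]) == [10]

    def test_design_tree_totals(self, exp1_counts):
        totals = exp1_counts.tree_totals("cooperating-majority")
        assert totals == {"partner-defects": 278 * 10, "partner-cooperates": 278 * 15}
        totals = exp1_counts.tree_totals("defecting-majority")
        assert totals == {"partner-defects": 266 * 15, "partner-cooperates": 266 * 10}

    def test_pure_cooperator_never_defects_or_punishes(self):
        designs = [ConditionDesign("c", 0.6, 20, partner_punishes=True)]
        params = {"c": ParameterSet(C=1, pMoral=0, pHypocritical=0, pAntisocial=0, b=0)}
        records = simulate_experiment(designs, params, seed=5)
        assert (records["participant_decision"] == "cooperate").all()
        assert (records["participant_punish_investment"] == 0).all()
        # never a unilateral defector, hence never fined
        assert (records["partner_punish_fine"] == 0).all()

    def test_partner_fines_exactly_unilateral_defection(self):
        designs = [ConditionDesign("c", 0.6, 60, partner_punishes=True)]
        records = simulate_experiment(designs, TRUE_PARAMS | {
            "c": ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1)}, seed=6)
        unilateral = (records["participant_decision"] == "defect") & (
            records["partner_decision"] == "cooperate"
        )
        assert (records.loc[unilateral, "partner_punish_fine"].isin([10, 20, 30])).all()
        assert (records.loc[~unilateral, "partner_punish_fine"] == 0).all()

    def test_unilateral_variant_never_fines(self):
        designs = experiment_presets("exp2")
        assert not designs[0].partner_punishes
        records = simulate_experiment(
            [ConditionDesign("c", 0.6, 40, partner_punishes=False)],
            {"c": ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1)},
            seed=7,
        )
        assert (records["partner_punish_fine"] == 0).all()

    def test_investment_maps_to_tenfold_fine_scale(self, exp1_trials):
        punished = exp1_trials[exp1_trials["participant_punish_investment"] > 0]
        assert set(punished["participant_punish_investment"].unique()) <= {1, 2, 3}
        fined = exp1_trials[exp1_trials["partner_punish_fine"] > 0]
        assert set(fined["partner_punish_fine"].unique()) <= {10, 20, 30}

    def test_balance_is_running_ledger_from_endowment(self, exp1_trials):
        one = exp1_trials[exp1_trials["participant_id"] == 0]
        expected = 150 + one["participant_payoff_delta"].cumsum()
        assert (one["participant_balance"] == expected).all()

    def test_exact_policy_rejects_non_integer_schedule(self):
        with pytest.raises(ValueError, match="bernoulli"):
            ConditionDesign("c", 0.55, 10, trials_per_participant=25)

    def test_bernoulli_schedule_hits_rate_on_average(self):
        design = ConditionDesign("c", 0.55, 400, schedule="bernoulli")
        records = simulate_experiment(
            [design], {"c": ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1)}, seed=8
        )
        rate = (records["partner_decision"] == "cooperate").mean()
        assert rate == pytest.approx(0.55, abs=3 * np.sqrt(0.55 * 0.45 / len(records)))

    def test_presets_match_study_designs(self):
        exp1 = experiment_presets("exp1")
        assert [d.n_participants for d in exp1] == [278, 266]
        assert [d.partner_cooperation_rate for d in exp1] == [0.6, 0.4]
        assert all(d.partner_punishes for d in exp1)
        exp2 = experiment_presets("exp2")
        assert [d.n_participants for d in exp2] == [250, 245]
        assert not any(d.partner_punishes for d in exp2)


class TestAggregateCounts:
    def test_counts_conserve_trials(self, exp1_trials, exp1_counts):
        assert exp1_counts.total() == len(exp1_trials)
        assert exp1_counts.counts["cooperating-majority"].sum() == 278 * 25

    def test_single_participant_counts_sum_to_trials(self):
        designs = [ConditionDesign("c", 0.6, 1)]
        records = simulate_experiment(
            designs, {"c": ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1)}, seed=9
        )
        counts = aggregate_counts(records)
        assert counts.counts["c"].sum() == 25

    def test_empty_input_gives_empty_counts(self):
        empty = pd.DataFrame(
            columns=["condition", "partner_decision", "participant_decision",
                     "participant_punish_investment"]
        )
        assert aggregate_counts(empty).total() == 0

    def test_generator_matches_model_probabilities(self):
        """At 10⁵ decisions every simulated cell frequency must sit within
        3 binomial SEs of the model's branch probability."""
        design = ConditionDesign("c", 0.6, 4000)
        result = generator_consistency(
            design, ParameterSet(0.70, 0.50, 0.35, 0.15, 0.05), seed=10
        )
        assert result.n_decisions == 100_000
        assert result.max_abs_z < 3.0
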