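"""Simulate the Prisoner's-Dilemma-with-costly-punishment experiment.

Generates trial-level data for a two-condition base-rate design: partners
are programmed to cooperate in a fixed proportion of each participant's
trials (60% in the cooperating-majority condition, 40% in the
defecting-majority condition), participants behave according to the five
latent model parameters, punishment investments are graded (1/2/3 points
buying 10/20/30-point fines), and a running account balance tracks the
payoff ledger from a 150-point endowment.  In the bilateral-punishment
variant the partner always fines the participant's unilateral defection by
a random 10/20/30 points; in the unilateral variant partners never punish.

Participant decisions are independent across trials given the parameters —
the measurement model is static, so no learning dynamics are simulated.
Only the analysed decisions are generated (training trials are not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CategoryCounts
from .model import ParameterSet

#: One-shot Prisoner's Dilemma payoffs (points to the focal player):
#: mutual cooperation +10 each, mutual defection 0, unilateral defector +20
#: against a cooperator who loses 10.
PAYOFFS: dict[tuple[str, str], int] = {
    ("cooperate", "cooperate"): 10,
    ("cooperate", "defect"): -10,
    ("defect", "cooperate"): 20,
    ("defect", "defect"): 0,
}

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "trial_index",
    "partner_decision",
    "participant_decision",
    "participant_punish_investment",
    "partner_punish_fine",
    "participant_payoff_delta",
    "participant_balance",
]


@dataclass(frozen=True)
class ConditionDesign:
    """Design of one between-subjects condition.

    ``partner_cooperation_rate`` is the programmed base rate; under the
    default exact schedule every participant sees exactly
    ``rate × trials_per_participant`` partner-cooperation trials in a
    shuffled order (``schedule="bernoulli"`` draws each trial's partner
    move independently instead).  ``partner_punishes`` enables the
    bilateral variant in which unilateral defection by the participant is
    always fined.
    """

    label: str
    partner_cooperation_rate: float
    n_participants: int
    trials_per_participant: int = 25
    partner_punishes: bool = True
    endowment: int = 150
    schedule: str = "exact"

    def __post_init__(self) -> None:
        if not (0 <= self.partner_cooperation_rate <= 1):
            raise ValueError("partner_cooperation_rate must lie in [0, 1]")
        if self.schedule not in ("exact", "bernoulli"):
            raise ValueError("schedule must be 'exact' or 'bernoulli'")
        if self.schedule == "exact":
            exact = self.partner_cooperation_rate * self.trials_per_participant
            if abs(exact - round(exact)) > 1e-9:
                raise ValueError(
                    f"partner_cooperation_rate×trials = {exact} is not an "
                    "integer; use schedule='bernoulli' for non-exact rates"
                )


def experiment_presets(variant: str) -> list[ConditionDesign]:
    """The two studied designs.

    ``"exp1"``: bilateral punishment, n = 278 / 266;
    ``"exp2"``: punishment unilaterally available to participants,
    n = 250 / 245.  Both use 25 analysed trials at 60%/40% partner
    cooperation.
    """
    if variant == "exp1":
        ns, punishes = (278, 266), True
    elif variant == "exp2":
        ns, punishes = (250, 245), False
    else:
        raise ValueError(f"unknown preset {variant!r}; expected 'exp1' or 'exp2'")
    return [
        ConditionDesign("cooperating-majority", 0.6, ns[0], partner_punishes=punishes),
        ConditionDesign("defecting-majority", 0.4, ns[1], partner_punishes=punishes),
    ]


def apply_payoffs(
    participant_decision: str,
    partner_decision: str,
    investment: int,
    fine: int,
) -> int:
    """Participant's payoff delta for one trial.

    Prisoner's Dilemma payoff minus the punishment points invested by the
    participant minus the fine received from the partner.
    """
    if (participant_decision, partner_decision) not in PAYOFFS:
        raise ValueError(
            f"invalid decisions ({participant_decision!r}, {partner_decision!r})"
        )
    if investment not in (0, 1, 2, 3):
        raise ValueError(f"investment must be in 0..3, got {investment}")
    if fine not in (0, 10, 20, 30):
        raise ValueError(f"fine must be one of 0/10/20/30, got {fine}")
    return PAYOFFS[(participant_decision, partner_decision)] - investment - fine


def _punish_probability(params: ParameterSet, participant: str, partner: str) -> float:
    """The fitted model's punish branch probability for one outcome cell."""
    specific = {
        ("cooperate", "defect"): params.pMoral,
        ("defect", "defect"): params.pHypocritical,
        ("defect", "cooperate"): params.pAntisocial,
        ("cooperate", "cooperate"): 0.0,
    }[(participant, partner)]
    return specific + (1.0 - specific) * params.b


def simulate_experiment(
    designs: list[ConditionDesign],
    true_params: dict[str, ParameterSet],
    seed: int,
) -> pd.DataFrame:
    """Simulate all trials of the experiment; one row per participant × trial.

    Same seed ⇒ byte-identical table.  Participant ids are unique across
    conditions.  Columns are :data:`TRIAL_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    pid = 0
    for design in designs:
        if design.label not in true_params:
            raise KeyError(f"no true parameters supplied for {design.label!r}")
        params = true_params[design.label]
        t = design.trials_per_participant
        n_coop = round(design.partner_cooperation_rate * t)
        for _ in range(design.n_participants):
            if design.schedule == "exact":
                partner_coop = np.zeros(t, dtype=bool)
                partner_coop[:n_coop] = True
                rng.shuffle(partner_coop)
            else:
                partner_coop = rng.random(t) < design.partner_cooperation_rate
            participant_coop = rng.random(t) < params.C
            balance = design.endowment
            for trial in range(t):
                partner = "cooperate" if partner_coop[trial] else "defect"
                participant = "cooperate" if participant_coop[trial] else "defect"
                punishes = rng.random() < _punish_probability(params, participant, partner)
                investment = int(rng.integers(1, 4)) if punishes else 0
                unilateral_defection = participant == "defect" and partner == "cooperate"
                fine = (
                    int(rng.integers(1, 4)) * 10
                    if design.partner_punishes and unilateral_defection
                    else 0
                )
                delta = apply_payoffs(participant, partner, investment, fine)
                balance += delta
                rows.append(
                    (pid, design.label, trial, partner, participant,
                     investment, fine, delta, balance)
                )
            pid += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def aggregate_counts(records: pd.DataFrame) -> CategoryCounts:
    """Classify trials into the 8 model categories per condition.

    A trial is "punished" when the participant invested any points.  The
    total of all counts equals the number of trial records.
    """
    required = {"condition", "partner_decision", "participant_decision",
                "participant_punish_investment"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    counts: dict[str, np.ndarray] = {}
    index = {
        ("defect", "cooperate", True): 0,
        ("defect", "cooperate", False): 1,
        ("defect", "defect", True): 2,
        ("defect", "defect", False): 3,
        ("cooperate", "cooperate", True): 4,
        ("cooperate", "cooperate", False): 5,
        ("cooperate", "defect", True): 6,
        ("cooperate", "defect", False): 7,
    }
    for cond, group in records.groupby("condition", sort=False):
        vec = np.zeros(8)
        keys = zip(
            group["partner_decision"],
            group["participant_decision"],
            group["participant_punish_investment"].to_numpy() > 0,
        )
        for key in keys:
            try:
                vec[index[key]] += 1
            except KeyError:
                raise ValueError(
                    f"unclassifiable trial {key!r} in condition {cond!r}"
                ) from None
        counts[str(cond)] = vec
    return CategoryCounts(counts)
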