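"""Two-tree multinomial processing-tree (MPT) model of cooperation and punishment.

The model describes behaviour in a simultaneous one-shot Prisoner's Dilemma
with a costly punishment option.  Trials are split into two trees by the
*partner's* programmed decision (defect / cooperate); within each tree the
participant either cooperates (probability ``C``) or defects (``1 - C``) and
then either punishes the partner or not.  Punishment arises from an
outcome-specific process — moral punishment of unilateral defection
(``pMoral``), hypocritical punishment after mutual defection
(``pHypocritical``), antisocial punishment of unilateral cooperation
(``pAntisocial``) — or, failing that, from an unspecific punishment bias
``b``.  Mutual cooperation offers no specific reason to punish, so that cell
identifies ``b`` alone.

Category probabilities are conditional on the tree (the partner schedule is
set by the experimenter, not modelled).  Each tree therefore contributes
``4 - 1 = 3`` free category probabilities to the degrees-of-freedom count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

PARAM_NAMES = ("C", "pMoral", "pHypocritical", "pAntisocial", "b")

#: Frozen category enumeration for one condition.  Partner-defects tree
#: first, then partner-cooperates; within a tree: cooperate/punish,
#: cooperate/none, defect/punish, defect/none.  File formats and count
#: vectors follow this order everywhere.
CATEGORY_ORDER: tuple[tuple[str, str, str], ...] = (
    ("partner-defects", "cooperate", "yes"),
    ("partner-defects", "cooperate", "no"),
    ("partner-defects", "defect", "yes"),
    ("partner-defects", "defect", "no"),
    ("partner-cooperates", "cooperate", "yes"),
    ("partner-cooperates", "cooperate", "no"),
    ("partner-cooperates", "defect", "yes"),
    ("partner-cooperates", "defect", "no"),
)

TREES = ("partner-defects", "partner-cooperates")


@dataclass(frozen=True)
class ParameterSet:
    """The five latent probabilities of one condition.

    Attributes
    ----------
    C : float
        Probability that the participant cooperates.
    pMoral : float
        Probability of moral punishment of the partner's unilateral defection
        (participant cooperated, partner defected).
    pHypocritical : float
        Probability of hypocritical punishment after mutual defection.
    pAntisocial : float
        Probability of antisocial punishment of the partner's unilateral
        cooperation (participant defected, partner cooperated).
    b : float
        Unspecific punishment bias, identified from the mutual-cooperation
        cell and applied residually in every other cell.
    """

    C: float
    pMoral: float
    pHypocritical: float
    pAntisocial: float
    b: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"parameter {name}={value!r} must lie in [0, 1]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ParameterSet":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


def category_probabilities(params: ParameterSet) -> dict[tuple[str, str, str], float]:
    """Category probabilities for one condition, conditional on the tree.

    Keys are ``(partner_tree, participant_decision, punished)`` in the frozen
    :data:`CATEGORY_ORDER`; within each tree the four probabilities sum to 1.

    The punish branch in each cell with a specific punishment process ``P``
    has probability ``P + (1 - P) * b``: specific punishment, or else the
    unspecific bias.  The mutual-cooperation cell punishes with ``b`` alone.
    """
    C, pm, ph, pa, b = params.as_array()
    probs = {
        ("partner-defects", "cooperate", "yes"): C * (pm + (1 - pm) * b),
        ("partner-defects", "cooperate", "no"): C * (1 - pm) * (1 - b),
        ("partner-defects", "defect", "yes"): (1 - C) * (ph + (1 - ph) * b),
        ("partner-defects", "defect", "no"): (1 - C) * (1 - ph) * (1 - b),
        ("partner-cooperates", "cooperate", "yes"): C * b,
        ("partner-cooperates", "cooperate", "no"): C * (1 - b),
        ("partner-cooperates", "defect", "yes"): (1 - C) * (pa + (1 - pa) * b),
        ("partner-cooperates", "defect", "no"): (1 - C) * (1 - pa) * (1 - b),
    }
    return {key: probs[key] for key in CATEGORY_ORDER}


def category_probability_vector(params: ParameterSet) -> np.ndarray:
    """The 8 category probabilities as an array in :data:`CATEGORY_ORDER`."""
    probs = category_probabilities(params)
    return np.array([probs[key] for key in CATEGORY_ORDER], dtype=float)


@dataclass
class ModelSpec:
    """Conditions plus the parameter-sharing map defining a (restricted) model.

    ``sharing`` maps ``(condition, parameter_name)`` to a free-parameter
    index; entries with equal indices denote equated parameters.  The
    two-condition base design with all ten indices distinct is the base
    model; a restriction test merges exactly one pair of indices.
    """

    conditions: list[str]
    sharing: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("ModelSpec requires at least one condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not self.sharing:
            self.sharing = {
                (cond, name): i * len(PARAM_NAMES) + j
                for i, cond in enumerate(self.conditions)
                for j, name in enumerate(PARAM_NAMES)
            }
        expected_keys = {
            (cond, name) for cond in self.conditions for name in PARAM_NAMES
        }
        if set(self.sharing) != expected_keys:
            raise ValueError(
                "sharing must map every (condition, parameter) pair exactly once"
            )
        # compact the index space so free parameters are 0..k-1
        distinct = sorted(set(self.sharing.values()))
        remap = {old: new for new, old in enumerate(distinct)}
        self.sharing = {key: remap[idx] for key, idx in self.sharing.items()}

    @property
    def n_free_parameters(self) -> int:
        return len(set(self.sharing.values()))

    @property
    def n_trees(self) -> int:
        return 2 * len(self.conditions)

    def expand(self, free: np.ndarray) -> dict[str, ParameterSet]:
        """Map a free-parameter vector to one ParameterSet per condition."""
        return {
            cond: ParameterSet(
                **{name: float(free[self.sharing[(cond, name)]]) for name in PARAM_NAMES}
            )
            for cond in self.conditions
        }

    def restrict(
        self,
        first: tuple[str, str],
        second: tuple[str, str],
    ) -> "ModelSpec":
        """A copy with the two named parameters equated (indices merged).

        Supports both within-parameter restrictions across conditions (the
        usual equality test) and cross-parameter restrictions such as
        moral punishment in one condition against antisocial punishment in
        the other.
        """
        for key in (first, second):
            if key not in self.sharing:
                raise KeyError(
                    f"unknown (condition, parameter) pair {key!r}; "
                    f"conditions={self.conditions}, parameters={PARAM_NAMES}"
                )
        i, j = self.sharing[first], self.sharing[second]
        if i == j:
            raise ValueError(f"{first!r} and {second!r} are already equated")
        merged = {
            key: (i if idx == j else idx) for key, idx in self.sharing.items()
        }
        return ModelSpec(conditions=list(self.conditions), sharing=merged)


def degrees_of_freedom(spec: ModelSpec) -> int:
    """G² degrees of freedom: free category probabilities minus free parameters.

    Each of the ``2 × n_conditions`` trees has 4 categories, hence 3 free
    category probabilities; the two-condition base model gives
    ``4·3 − 10 = 2``.
    """
    df = 3 * spec.n_trees - spec.n_free_parameters
    if df < 0:
        raise ValueError(
            f"model has {spec.n_free_parameters} free parameters but only "
            f"{3 * spec.n_trees} free category probabilities"
        )
    return df


def _branch_terms(key: tuple[str, str, str]) -> list[list[str]]:
    """Branches (as parameter-term products) reaching a category.

    Terms use EQN-style notation where ``1-x`` denotes the complement.
    A category reached by several branches gets one line per branch.
    """
    tree, decision, punished = key
    coop = ["C"] if decision == "cooperate" else ["1-C"]
    specific = {
        ("partner-defects", "cooperate"): "pMoral",
        ("partner-defects", "defect"): "pHypocritical",
        ("partner-cooperates", "defect"): "pAntisocial",
        ("partner-cooperates", "cooperate"): None,
    }[(tree, decision)]
    branches: list[list[str]] = []
    if punished == "yes":
        if specific is not None:
            branches.append(coop + [specific])
            branches.append(coop + [f"1-{specific}", "b"])
        else:
            branches.append(coop + ["b"])
    else:
        if specific is not None:
            branches.append(coop + [f"1-{specific}", "1-b"])
        else:
            branches.append(coop + ["1-b"])
    return branches


def to_eqn(conditions: list[str] | None = None) -> str:
    """Render the model as an EQN-style text block for MPT tooling.

    One line per branch: ``<tree> <category> <term*term*...>``, with tree and
    category labels prefixed by the condition.  Single-condition output by
    default.
    """
    conditions = conditions or ["condition1"]
    lines = []
    for cond in conditions:
        for key in CATEGORY_ORDER:
            tree, decision, punished = key
            tree_label = f"{cond}.{tree}"
            cat_label = f"{cond}.{decision}.punish-{punished}"
            for branch in _branch_terms(key):
                lines.append(f"{tree_label} {cat_label} {'*'.join(branch)}")
    return "\n".join(lines) + "\n"


def iter_categories(conditions: list[str]) -> Iterator[tuple[str, str, str, str]]:
    """All ``(condition, tree, decision, punished)`` keys in frozen order."""
    for cond in conditions:
        for tree, decision, punished in CATEGORY_ORDER:
            yield cond, tree, decision, punished
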