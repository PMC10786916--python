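"""Monte-Carlo validation studies: recovery, calibration, consistency.

These routines back the package's simulation-based checks:

* :func:`parameter_recovery` — simulate full experiments at design scale,
  refit, and summarise per-parameter absolute estimation error;
* :func:`g_squared_calibration` — the null distribution of the base-model
  G² (mean should sit near its df) and the type-I error rate of an
  equality-restriction test under a true equality;
* :func:`generator_consistency` — agreement between simulated cell
  frequencies and the model's branch probabilities, in binomial z-units;
* :func:`optimizer_vs_closed_form` — the numeric optimizer against the
  closed-form maximum-likelihood estimator on unrestricted fits.

Counts-level replications draw multinomial samples per (condition, tree)
directly from the model, which is what the fitted likelihood assumes and is
orders of magnitude faster than trial-level simulation; trial-level
simulation is used where the generator itself is under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import (
    CategoryCounts,
    FitOptions,
    closed_form_mle,
    fit,
    test_restriction,
)
from .model import (
    CATEGORY_ORDER,
    PARAM_NAMES,
    ModelSpec,
    ParameterSet,
    category_probability_vector,
)
from .simulate import ConditionDesign, aggregate_counts, simulate_experiment

_TREE_SLICES = (slice(0, 4), slice(4, 8))


def design_tree_totals(design: ConditionDesign) -> tuple[int, int]:
    """(partner-defects, partner-cooperates) decision totals for a condition."""
    n_coop = round(design.partner_cooperation_rate * design.trials_per_participant)
    n_defect = design.trials_per_participant - n_coop
    return (design.n_participants * n_defect, design.n_participants * n_coop)


def simulate_counts(
    params: dict[str, ParameterSet],
    tree_totals: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> CategoryCounts:
    """Draw category counts per (condition, tree) multinomially from the model."""
    counts: dict[str, np.ndarray] = {}
    for cond, ps in params.items():
        p = category_probability_vector(ps)
        vec = np.zeros(8)
        for sl, total in zip(_TREE_SLICES, tree_totals[cond]):
            tree_p = p[sl] / p[sl].sum()
            vec[sl] = rng.multinomial(total, tree_p)
        counts[cond] = vec
    return CategoryCounts(counts)


def expected_counts(
    params: dict[str, ParameterSet], tree_totals: dict[str, tuple[int, int]]
) -> CategoryCounts:
    """Model-expected (generally non-integer) category counts."""
    counts: dict[str, np.ndarray] = {}
    for cond, ps in params.items():
        p = category_probability_vector(ps)
        vec = np.zeros(8)
        for sl, total in zip(_TREE_SLICES, tree_totals[cond]):
            vec[sl] = total * p[sl] / p[sl].sum()
        counts[cond] = vec
    return CategoryCounts(counts)


@dataclass
class RecoveryResult:
    mean_abs_error: dict[str, float]
    overall_mean_abs_error: float
    n_replications: int
    n_participants_total: int


def parameter_recovery(
    designs: list[ConditionDesign],
    true_params: dict[str, ParameterSet],
    n_replications: int,
    seed: int,
    options: FitOptions | None = None,
    trial_level: bool = True,
) -> RecoveryResult:
    """Simulate → aggregate → fit, repeatedly; absolute error per parameter."""
    options = options or FitOptions(n_starts=2)
    rng = np.random.default_rng(seed)
    spec = ModelSpec(conditions=[d.label for d in designs])
    totals = {d.label: design_tree_totals(d) for d in designs}
    errors = {name: [] for name in PARAM_NAMES}
    for _ in range(n_replications):
        if trial_level:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            counts = aggregate_counts(
                simulate_experiment(designs, true_params, seed=sub_seed)
            )
        else:
            counts = simulate_counts(true_params, totals, rng)
        result = fit(spec, counts, options)
        for cond, true_ps in true_params.items():
            est = result.estimates[cond]
            for name in PARAM_NAMES:
                errors[name].append(abs(getattr(est, name) - getattr(true_ps, name)))
    mae = {name: float(np.mean(vals)) for name, vals in errors.items()}
    return RecoveryResult(
        mean_abs_error=mae,
        overall_mean_abs_error=float(np.mean(list(mae.values()))),
        n_replications=n_replications,
        n_participants_total=sum(d.n_participants for d in designs),
    )


@dataclass
class CalibrationResult:
    mean_g_squared: float
    se_mean_g_squared: float
    df: int
    type_i_error_rate: float
    n_replications: int
    alpha: float


def g_squared_calibration(
    designs: list[ConditionDesign],
    true_params: dict[str, ParameterSet],
    n_replications: int,
    seed: int,
    restriction: tuple[tuple[str, str], tuple[str, str]] | None = None,
    alpha: float = 0.05,
    options: FitOptions | None = None,
) -> CalibrationResult:
    """Null calibration of the base-model G² and a restriction test.

    ``true_params`` must satisfy the tested restriction (the default
    restriction equates C across the two conditions) so that rejections are
    type-I errors.  Counts are drawn multinomially from the model.
    """
    options = options or FitOptions(n_starts=2)
    rng = np.random.default_rng(seed)
    conditions = [d.label for d in designs]
    spec = ModelSpec(conditions=conditions)
    totals = {d.label: design_tree_totals(d) for d in designs}
    if restriction is None:
        restriction = ((conditions[0], "C"), (conditions[1], "C"))

    g_values = []
    rejections = 0
    for _ in range(n_replications):
        counts = simulate_counts(true_params, totals, rng)
        base = fit(spec, counts, options)
        g_values.append(base.g_squared)
        result = test_restriction(spec, counts, restriction, options, base_fit=base)
        if result.p_value < alpha:
            rejections += 1
    g = np.asarray(g_values)
    return CalibrationResult(
        mean_g_squared=float(g.mean()),
        se_mean_g_squared=float(g.std(ddof=1) / np.sqrt(len(g))),
        df=base.df,
        type_i_error_rate=rejections / n_replications,
        n_replications=n_replications,
        alpha=alpha,
    )


@dataclass
class ConsistencyResult:
    max_abs_z: float
    z_by_category: dict[tuple[str, str, str], float]
    n_decisions: int


def generator_consistency(
    design: ConditionDesign,
    params: ParameterSet,
    seed: int,
) -> ConsistencyResult:
    """Trial-level generator vs model branch probabilities, in z-units.

    Simulates one condition, then compares each tree-conditional category
    frequency against the model probability on the binomial standard-error
    scale; |z| beyond ~3 at large N signals a generator/model mismatch.
    """
    records = simulate_experiment([design], {design.label: params}, seed=seed)
    counts = aggregate_counts(records).counts[design.label]
    p = category_probability_vector(params)
    z: dict[tuple[str, str, str], float] = {}
    for sl in _TREE_SLICES:
        total = counts[sl].sum()
        tree_p = p[sl] / p[sl].sum()
        for offset in range(4):
            idx = sl.start + offset
            se = np.sqrt(tree_p[offset] * (1 - tree_p[offset]) / total)
            observed = counts[idx] / total
            z[CATEGORY_ORDER[idx]] = float(
                (observed - tree_p[offset]) / se if se > 0 else 0.0
            )
    return ConsistencyResult(
        max_abs_z=float(max(abs(v) for v in z.values())),
        z_by_category=z,
        n_decisions=int(len(records)),
    )


def optimizer_vs_closed_form(
    n_datasets: int,
    seed: int,
    n_per_tree: int = 4000,
    options: FitOptions | None = None,
) -> float:
    """Max |numeric MLE − closed-form MLE| over random interior datasets.

    Datasets are drawn from random interior parameters large enough that the
    unclipped closed-form values stay interior; returns the worst absolute
    discrepancy over all parameters and datasets.
    """
    options = options or FitOptions(n_starts=3, seed=seed)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        true = ParameterSet(
            C=rng.uniform(0.3, 0.8),
            pMoral=rng.uniform(0.2, 0.7),
            pHypocritical=rng.uniform(0.2, 0.7),
            pAntisocial=rng.uniform(0.2, 0.7),
            b=rng.uniform(0.05, 0.3),
        )
        counts = simulate_counts(
            {"only": true}, {"only": (n_per_tree, n_per_tree)}, rng
        )
        spec = ModelSpec(conditions=["only"])
        numeric = fit(spec, counts, options).estimates["only"]
        closed = closed_form_mle(counts.counts["only"])
        for name in PARAM_NAMES:
            worst = max(worst, abs(getattr(numeric, name) - getattr(closed, name)))
    return worst
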