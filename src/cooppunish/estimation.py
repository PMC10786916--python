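"""Maximum-likelihood fitting of the cooperation-and-punishment model.

Counts are pooled over participants into per-condition aggregates and fitted
under a product-multinomial likelihood: within each (condition, partner-tree)
the four response categories are multinomial with the tree total fixed by
design.  The fit maximises the log-likelihood on a logit transform of the
probability parameters with multiple random starts; goodness of fit is the
likelihood-ratio statistic G² against the saturated model, and nested
equality restrictions are tested by ΔG².

For an unrestricted per-condition model the likelihood factorises into a
cooperation binomial and four conditional punish-rate binomials, giving the
closed-form estimator in :func:`closed_form_mle`; the numeric optimizer is
validated against it in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .model import (
    PARAM_NAMES,
    TREES,
    ModelSpec,
    ParameterSet,
    category_probability_vector,
    degrees_of_freedom,
)
from .statistics import chi_square_p, cohens_w

logger = logging.getLogger(__name__)

_TREE_SLICES = {"partner-defects": slice(0, 4), "partner-cooperates": slice(4, 8)}


@dataclass
class CategoryCounts:
    """Observed counts for the 8 response categories of each condition.

    ``counts[condition]`` is a length-8 integer vector in the frozen
    category order (partner-defects tree first; within a tree
    cooperate/punish, cooperate/none, defect/punish, defect/none).
    """

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for cond, vec in self.counts.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (8,):
                raise ValueError(
                    f"condition {cond!r}: expected 8 category counts, got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"condition {cond!r}: counts must be non-negative")
            clean[cond] = arr
        self.counts = clean

    @property
    def conditions(self) -> list[str]:
        return list(self.counts)

    def tree_totals(self, condition: str) -> dict[str, float]:
        vec = self.counts[condition]
        return {tree: float(vec[_TREE_SLICES[tree]].sum()) for tree in TREES}

    def total(self) -> float:
        """Total number of decisions entering the fit (the N of Cohen's w)."""
        return float(sum(vec.sum() for vec in self.counts.values()))


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int | None = None
    tol: float = 1e-10
    bootstrap_draws: int = 200


@dataclass
class FitResult:
    estimates: dict[str, ParameterSet]
    standard_errors: dict[str, dict[str, float]] | None
    log_lik: float
    g_squared: float
    df: int
    p_value: float
    converged: bool
    n_starts: int
    best_start_objective: float
    boundary_flags: dict[str, list[str]] = field(default_factory=dict)
    se_method: str = "information"

    def to_dict(self) -> dict:
        return {
            "estimates": {
                cond: {n: getattr(ps, n) for n in PARAM_NAMES}
                for cond, ps in self.estimates.items()
            },
            "standard_errors": self.standard_errors,
            "log_lik": self.log_lik,
            "g_squared": self.g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "boundary_flags": self.boundary_flags,
            "se_method": self.se_method,
        }


@dataclass
class RestrictionTestResult:
    restriction: tuple[tuple[str, str], tuple[str, str]]
    delta_g_squared: float
    df: int
    p_value: float
    w: float
    restricted_fit: FitResult

    def to_dict(self) -> dict:
        return {
            "restriction": [list(self.restriction[0]), list(self.restriction[1])],
            "delta_g_squared": self.delta_g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "w": self.w,
            "restricted_fit": self.restricted_fit.to_dict(),
        }


def _xlogy(n: np.ndarray, p: np.ndarray) -> float:
    """Sum of n·ln(p) with the 0·ln(0) = 0 convention; −inf if n>0, p=0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = special.xlogy(n, p)
    if np.any(np.isneginf(terms)):
        return float("-inf")
    return float(np.sum(terms))


def log_likelihood(
    spec: ModelSpec, free_params: Sequence[float], counts: CategoryCounts
) -> float:
    """Product-multinomial log-likelihood (tree-conditional, up to constants)."""
    free = np.asarray(free_params, dtype=float)
    if free.shape != (spec.n_free_parameters,):
        raise ValueError(
            f"expected {spec.n_free_parameters} free parameters, got {free.shape}"
        )
    param_sets = spec.expand(np.clip(free, 0.0, 1.0))
    total = 0.0
    for cond in spec.conditions:
        if cond not in counts.counts:
            raise KeyError(f"counts missing condition {cond!r}")
        n = counts.counts[cond]
        p = category_probability_vector(param_sets[cond])
        value = _xlogy(n, p)
        if value == float("-inf"):
            return float("-inf")
        total += value
    return total


def saturated_log_likelihood(counts: CategoryCounts) -> float:
    """Log-likelihood of the saturated model (observed tree-conditional rates)."""
    total = 0.0
    for cond, vec in counts.counts.items():
        for tree, sl in _TREE_SLICES.items():
            n = vec[sl]
            tree_total = n.sum()
            if tree_total == 0:
                continue
            total += _xlogy(n, n / tree_total)
    return total


def closed_form_mle(counts_vec: np.ndarray, clip: bool = True) -> ParameterSet:
    """Closed-form MLE for one condition's unrestricted model.

    The likelihood factorises: ``C`` is the overall cooperation rate, ``b``
    the punish rate in the mutual-cooperation cell, and each specific
    punishment parameter inverts its cell's punish rate ``r`` through
    ``r = P + (1 − P)·b``, i.e. ``P = (r − b)/(1 − b)``, clipped to [0, 1]
    when the unconstrained value falls outside.  Cells with no observations
    yield parameter 0.
    """
    n = np.asarray(counts_vec, dtype=float)

    def rate(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    coop = n[0] + n[1] + n[4] + n[5]
    C = rate(coop, n.sum())
    b = rate(n[4], n[4] + n[5])
    denom = 1.0 - b

    def invert(punished: float, total: float) -> float:
        r = rate(punished, total)
        value = (r - b) / denom if denom > 0 else 0.0
        return float(np.clip(value, 0.0, 1.0)) if clip else float(value)

    return ParameterSet(
        C=C,
        pMoral=invert(n[0], n[0] + n[1]),
        pHypocritical=invert(n[2], n[2] + n[3]),
        pAntisocial=invert(n[6], n[6] + n[7]),
        b=b,
    )


_LOGIT_CLIP = 30.0


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.clip(special.logit(p), -_LOGIT_CLIP, _LOGIT_CLIP)


def _expit(x: np.ndarray) -> np.ndarray:
    return special.expit(x)


def _closed_form_start(spec: ModelSpec, counts: CategoryCounts) -> np.ndarray:
    """Per-condition closed-form estimates averaged over shared indices."""
    per_cond = {
        cond: closed_form_mle(counts.counts[cond]) for cond in spec.conditions
    }
    sums = np.zeros(spec.n_free_parameters)
    hits = np.zeros(spec.n_free_parameters)
    for (cond, name), idx in spec.sharing.items():
        sums[idx] += getattr(per_cond[cond], name)
        hits[idx] += 1
    return sums / hits


def fit(
    spec: ModelSpec, counts: CategoryCounts, options: FitOptions | None = None
) -> FitResult:
    """Fit the model by maximum likelihood with multiple starts.

    Optimises the negative log-likelihood on the logit scale (L-BFGS-B),
    starting from the closed-form estimator plus ``n_starts − 1`` random
    interior points.  Returns estimates, G² against the saturated model,
    df, the chi-square p-value and information-based standard errors (with a
    parametric-bootstrap fallback near the boundary).
    """
    options = options or FitOptions()
    for cond in spec.conditions:
        totals = counts.tree_totals(cond)
        for tree, tot in totals.items():
            if tot == 0:
                logger.warning(
                    "condition %r tree %r has no observations; it contributes "
                    "nothing to the fit",
                    cond,
                    tree,
                )

    rng = np.random.default_rng(options.seed)
    k = spec.n_free_parameters

    def objective(x: np.ndarray) -> float:
        ll = log_likelihood(spec, _expit(x), counts)
        # large finite penalty instead of inf keeps L-BFGS-B's finite
        # difference gradient well-defined near saturated logits
        return 1e15 if ll == float("-inf") else -ll

    starts = [_logit(_closed_form_start(spec, counts))]
    starts += [_logit(rng.uniform(0.02, 0.98, size=k)) for _ in range(options.n_starts - 1)]

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"ftol": options.tol, "gtol": 1e-8, "maxiter": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    free_hat = _expit(best.x)
    estimates = spec.expand(free_hat)
    log_lik = -float(best.fun)
    g_squared = 2.0 * (saturated_log_likelihood(counts) - log_lik)
    g_squared = 0.0 if -1e-8 < g_squared < 0 else float(g_squared)
    df = degrees_of_freedom(spec)
    p_value = chi_square_p(max(g_squared, 0.0), df) if df > 0 else float("nan")

    boundary_flags: dict[str, list[str]] = {}
    for cond, ps in estimates.items():
        flagged = [
            name
            for name in PARAM_NAMES
            if getattr(ps, name) < 1e-6 or getattr(ps, name) > 1 - 1e-6
        ]
        if flagged:
            boundary_flags[cond] = flagged

    result = FitResult(
        estimates=estimates,
        standard_errors=None,
        log_lik=log_lik,
        g_squared=g_squared,
        df=df,
        p_value=p_value,
        converged=any_converged,
        n_starts=options.n_starts,
        best_start_objective=float(best.fun),
        boundary_flags=boundary_flags,
    )
    if not any_converged:
        logger.warning("no optimizer start converged; result flagged converged=False")
    return result


def _information_se(
    spec: ModelSpec, free_hat: np.ndarray, counts: CategoryCounts
) -> np.ndarray | None:
    """SEs from the inverse observed information on the probability scale.

    Central-difference Hessian of the negative log-likelihood; returns None
    if the information matrix is singular or yields non-positive variances.
    """
    k = len(free_hat)
    h = 1e-5

    def nll(x: np.ndarray) -> float:
        value = log_likelihood(spec, x, counts)
        return float("inf") if value == float("-inf") else -value

    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            f_pp = nll(free_hat + ei + ej)
            f_pm = nll(free_hat + ei - ej)
            f_mp = nll(free_hat - ei + ej)
            f_mm = nll(free_hat - ei - ej)
            if not all(np.isfinite(v) for v in (f_pp, f_pm, f_mp, f_mm)):
                return None
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    variances = np.diag(cov)
    if np.any(variances <= 0):
        return None
    return np.sqrt(variances)


def _bootstrap_se(
    spec: ModelSpec,
    fitted: FitResult,
    counts: CategoryCounts,
    options: FitOptions,
) -> np.ndarray:
    """Parametric-bootstrap SEs: simulate counts from the fitted model, refit."""
    rng = np.random.default_rng(
        None if options.seed is None else options.seed + 104729
    )
    draws = []
    boot_options = FitOptions(n_starts=2, seed=None, tol=1e-9)
    for _ in range(options.bootstrap_draws):
        sim = {}
        for cond in spec.conditions:
            p = category_probability_vector(fitted.estimates[cond])
            vec = np.zeros(8)
            for tree, sl in _TREE_SLICES.items():
                tree_total = int(counts.counts[cond][sl].sum())
                tree_p = p[sl]
                tree_p = tree_p / tree_p.sum()
                if tree_total > 0:
                    vec[sl] = rng.multinomial(tree_total, tree_p)
            sim[cond] = vec
        refit = fit(spec, CategoryCounts(sim), boot_options)
        free = np.empty(spec.n_free_parameters)
        for (cond, name), idx in spec.sharing.items():
            free[idx] = getattr(refit.estimates[cond], name)
        draws.append(free)
    return np.std(np.asarray(draws), axis=0, ddof=1)


def standard_errors(
    fitted: FitResult,
    spec: ModelSpec,
    counts: CategoryCounts,
    options: FitOptions | None = None,
) -> FitResult:
    """Attach per-parameter standard errors to a converged fit.

    Inverse observed information evaluated on the probability scale; when an
    estimate sits on the boundary or the information matrix is singular, a
    parametric bootstrap supplies the SEs instead and ``se_method`` records
    the fallback.
    """
    if not fitted.converged:
        raise ValueError("standard errors require a converged fit")
    options = options or FitOptions()
    free_hat = np.empty(spec.n_free_parameters)
    for (cond, name), idx in spec.sharing.items():
        free_hat[idx] = getattr(fitted.estimates[cond], name)

    on_boundary = bool(fitted.boundary_flags)
    se_vec = None if on_boundary else _information_se(spec, free_hat, counts)
    if se_vec is None:
        logger.info(
            "information matrix unusable (boundary=%s); falling back to a "
            "parametric bootstrap with %d draws",
            on_boundary,
            options.bootstrap_draws,
        )
        se_vec = _bootstrap_se(spec, fitted, counts, options)
        fitted.se_method = "parametric-bootstrap"
    else:
        fitted.se_method = "information"

    fitted.standard_errors = {
        cond: {
            name: float(se_vec[spec.sharing[(cond, name)]]) for name in PARAM_NAMES
        }
        for cond in spec.conditions
    }
    return fitted


def test_restriction(
    spec: ModelSpec,
    counts: CategoryCounts,
    restriction: tuple[tuple[str, str], tuple[str, str]],
    options: FitOptions | None = None,
    base_fit: FitResult | None = None,
) -> RestrictionTestResult:
    """ΔG² test of a single equality restriction against the base model.

    ``restriction`` names two currently-distinct parameters, e.g.
    ``(("coop-majority", "C"), ("defect-majority", "C"))`` or the
    cross-parameter pair ``(("coop-majority", "pMoral"),
    ("defect-majority", "pAntisocial"))``.  The restricted model merges
    their free-parameter indices; the test has 1 df and Cohen's
    ``w = sqrt(ΔG²/N)`` with N the total decision count.
    """
    options = options or FitOptions()
    if base_fit is None:
        base_fit = fit(spec, counts, options)
    restricted_spec = spec.restrict(*restriction)
    restricted_fit = fit(restricted_spec, counts, options)
    delta = restricted_fit.g_squared - base_fit.g_squared
    delta = 0.0 if -1e-8 < delta < 0 else float(delta)
    delta = max(delta, 0.0)
    df = restricted_fit.df - base_fit.df
    return RestrictionTestResult(
        restriction=restriction,
        delta_g_squared=delta,
        df=df,
        p_value=chi_square_p(delta, df),
        w=cohens_w(delta, counts.total()),
        restricted_fit=restricted_fit,
    )
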