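"""Full analysis pipeline: base-model fit, restriction-test battery, sensitivity.

The default battery mirrors the six between-condition comparisons of the
two-condition design, in this order: cooperation C; moral punishment;
hypocritical punishment; the cross-parameter test of moral punishment in the
cooperating-majority condition against antisocial punishment in the
defecting-majority condition; antisocial punishment; punishment bias.
p-values are reported unadjusted (an optional Bonferroni/Holm column can be
requested); report formatting follows the conventional precision — G² to
2 dp, p to 3 dp, w to 2 dp — while JSON retains full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

from .estimation import (
    CategoryCounts,
    FitOptions,
    FitResult,
    RestrictionTestResult,
    fit,
    standard_errors,
    test_restriction,
)
from .model import ModelSpec, PARAM_NAMES
from .statistics import PowerQuery, sensitivity_w

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def default_battery(
    conditions: list[str],
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The six standard restriction tests for a two-condition design."""
    if len(conditions) != 2:
        raise ValueError("the default battery requires exactly two conditions")
    a, b = conditions
    return [
        ((a, "C"), (b, "C")),
        ((a, "pMoral"), (b, "pMoral")),
        ((a, "pHypocritical"), (b, "pHypocritical")),
        ((a, "pMoral"), (b, "pAntisocial")),
        ((a, "pAntisocial"), (b, "pAntisocial")),
        ((a, "b"), (b, "b")),
    ]


@dataclass
class AnalysisReport:
    base_fit: FitResult
    tests: list[RestrictionTestResult]
    sensitivity: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "base_fit": self.base_fit.to_dict(),
            "tests": [t.to_dict() for t in self.tests],
            "sensitivity": self.sensitivity,
            "provenance": self.provenance,
        }

    def to_markdown(self) -> str:
        """Human-readable report at conventional precision."""
        lines = ["# Cooperation-and-punishment model analysis", ""]
        bf = self.base_fit
        lines.append(
            f"Base model fit: G²({bf.df}) = {bf.g_squared:.2f}, "
            f"p = {bf.p_value:.3f}, converged={bf.converged}"
        )
        lines.append("")
        lines.append("## Parameter estimates")
        lines.append("")
        header = "| condition | " + " | ".join(PARAM_NAMES) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(PARAM_NAMES) + 1))
        for cond, ps in bf.estimates.items():
            cells = []
            for name in PARAM_NAMES:
                est = getattr(ps, name)
                if bf.standard_errors:
                    se = bf.standard_errors[cond][name]
                    cells.append(f"{est:.3f} ({se:.3f})")
                else:
                    cells.append(f"{est:.3f}")
            lines.append(f"| {cond} | " + " | ".join(cells) + " |")
        lines.append("")
        lines.append("## Restriction tests")
        lines.append("")
        lines.append("| restriction | ΔG²(df) | p | w |")
        lines.append("|---|---|---|---|")
        for t in self.tests:
            (c1, p1), (c2, p2) = t.restriction
            label = f"{p1} ({c1}) = {p2} ({c2})" if p1 != p2 else f"{p1} equal across conditions"
            p_str = "< 0.001" if t.p_value < 0.001 else f"{t.p_value:.3f}"
            lines.append(
                f"| {label} | {t.delta_g_squared:.2f} ({t.df}) | {p_str} | {t.w:.2f} |"
            )
        lines.append("")
        s = self.sensitivity
        lines.append(
            f"Sensitivity: minimal detectable w = {s['w']:.2f} at "
            f"power {s['power']}, α = {s['alpha']}, df = {s['df']}, "
            f"N = {s['n_observations']} decisions."
        )
        return "\n".join(lines) + "\n"


def run_full_analysis(
    counts: CategoryCounts,
    options: FitOptions | None = None,
    battery: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    alpha: float = 0.05,
    target_power: float = 0.95,
    compute_se: bool = True,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Fit the base model, run the test battery, and add the sensitivity analysis.

    Deterministic given the counts and the seed in ``options``.
    """
    options = options or FitOptions()
    spec = ModelSpec(conditions=counts.conditions)
    base = fit(spec, counts, options)
    logger.info(
        "base fit: G²(%d)=%.4f p=%.4f converged=%s",
        base.df, base.g_squared, base.p_value, base.converged,
    )
    if compute_se and base.converged:
        standard_errors(base, spec, counts, options)

    tests = []
    for restriction in battery or default_battery(counts.conditions):
        result = test_restriction(spec, counts, restriction, options, base_fit=base)
        logger.info(
            "restriction %s: ΔG²(%d)=%.4f p=%.4f w=%.4f converged=%s",
            restriction, result.df, result.delta_g_squared, result.p_value,
            result.w, result.restricted_fit.converged,
        )
        tests.append(result)

    n_total = int(counts.total())
    query = PowerQuery(n_observations=n_total, df=1, alpha=alpha, power=target_power)
    sensitivity = {
        "w": sensitivity_w(query),
        "alpha": alpha,
        "power": target_power,
        "df": 1,
        "n_observations": n_total,
    }

    prov = dict(provenance or {})
    prov.setdefault("seed", options.seed)
    prov.setdefault("software_version", __version__)
    prov["counts_hash"] = hashlib.sha256(
        json.dumps(
            {c: list(map(float, v)) for c, v in counts.counts.items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    return AnalysisReport(base_fit=base, tests=tests, sensitivity=sensitivity, provenance=prov)


def adjusted_p_values(report: AnalysisReport, method: str = "holm") -> list[float]:
    """Optional multiplicity adjustment over the battery (off by default)."""
    ps = [t.p_value for t in report.tests]
    m = len(ps)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in ps]
    if method == "holm":
        order = sorted(range(m), key=lambda i: ps[i])
        adjusted = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * ps[i])
            adjusted[i] = min(1.0, running)
        return adjusted
    raise ValueError(f"unknown adjustment method {method!r}")
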