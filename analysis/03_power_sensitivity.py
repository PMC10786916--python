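#!/usr/bin/env python
"""Power and sensitivity of the restriction tests at the studied sample sizes.

Computes the minimal detectable Cohen's w at power 0.95 (α = 0.05, df = 1)
for both experiments' decision totals, and a power curve across effect
sizes; writes results/power_sensitivity.json.
"""

from pathlib import Path

from cooppunish import PowerQuery, power, sensitivity_w
from cooppunish.io import write_json

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out: dict = {"sensitivity": {}, "power_curve": {}}
    for label, n in (("exp1", 544 * 25), ("exp2", 495 * 25)):
        w_min = sensitivity_w(PowerQuery(n_observations=n, df=1, alpha=0.05, power=0.95))
        out["sensitivity"][label] = {"n_decisions": n, "minimal_w": w_min}
        print(f"{label}: N = {n} decisions -> minimal detectable w = {w_min:.4f} "
              f"({w_min:.2f} at 2 dp)")
    for w in (0.01, 0.02, 0.03, 0.05, 0.10):
        achieved = power(PowerQuery(n_observations=544 * 25, df=1, alpha=0.05, w=w))
        out["power_curve"][f"w={w}"] = achieved
        print(f"  power at w = {w:.2f} (N = 13600): {achieved:.3f}")
    write_json(out, RESULTS / "power_sensitivity.json")


if __name__ == "__main__":
    main()
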