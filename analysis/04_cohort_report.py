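"""Cohort-level analysis: outliers, group comparisons, correlations.

Runs the full pipeline on the simulated cohort (reusing its seed so the
cohort is identical to 01's) and writes the report bundle under
results/report/. Prints the outlier counts per PK parameter and the
correlation table.
"""

import json
from pathlib import Path

from warfarin_pkpd import load_config, run_pipeline

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260901


def main() -> None:
    cfg = load_config(None, generator={"seed": SEED})
    report = run_pipeline(cfg, BASE / "report")
    print(f"report bundle -> {BASE / 'report'}")
    print("outliers per parameter (mean +/- 1.96 SD):")
    for param, info in report["outliers"].items():
        print(f"  {param}: {info['n_outside']} outside, {info['n_within']} within")
    print("correlations:")
    for row in report["correlations"]:
        print(
            f"  {row['var_x']} ~ {row['var_y']}: r = {row['r']:+.3f}"
            f" (p = {row['p_value']:.3g})"
        )


if __name__ == "__main__":
    main()
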