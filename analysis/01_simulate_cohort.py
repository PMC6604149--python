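#!/usr/bin/env python
"""Generate the study cohort: 171 females / 185 males, 116 AAL regions,
power-law TIV scaling (exponents ~ U[0.430, 1.155]), group TIV gap d=1.6,
and 19 seeded TIV-free group effects (|d| in 0.22-0.38, 10 F>M / 9 M>F).

Writes results/cohort.csv plus the generator report.
"""

import argparse
import json
from pathlib import Path

from tivadjust import default_spec, generate_cohort, write_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=20)
parser.add_argument("--mode", default="with_effects", choices=["with_effects", "null_scaling"])
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

args.outdir.mkdir(parents=True, exist_ok=True)
spec = default_spec(args.mode, seed=args.seed)
cohort, report = generate_cohort(spec)
write_cohort(cohort, args.outdir / "cohort.csv")
spec.voi_params.to_csv(args.outdir / "generator_params.csv", index=False)
with open(args.outdir / "generator_report.json", "w") as fh:
    json.dump(
        {
            "achieved_tiv_d": report.achieved_tiv_d,
            "true_effect_regions": report.true_effect_regions,
            "realized_effects": report.realized_effects,
            "seed": args.seed,
            "mode": args.mode,
        },
        fh,
        indent=2,
    )

print(f"wrote {args.outdir/'cohort.csv'}: n={cohort.n}, {len(cohort.voi_names)} regions")
print(f"achieved TIV standardized difference: {report.achieved_tiv_d:.3f} (target 1.6)")
print(f"{len(report.true_effect_regions)} regions carry a genuine group effect")
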