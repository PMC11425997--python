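#!/usr/bin/env python
"""Parameter-recovery check of the synthetic evidence generator.

Draws 100 synthetic evidence bases of 50 studies around a known ICER of
$50,000 with 20% multiplicative cost noise and moderate lognormal effect
heterogeneity, pools each through the synthesis pipeline, and summarizes
the recovery error.

Finding: the pooled ratio-of-sums estimator is effectively unbiased
(median signed error well under 2%); its spread is set by the noise scale
over the square root of the study count, ~2-3% per evidence base at these
settings.

Writes results/generator_calibration.json.
"""
import json
from pathlib import Path

import numpy as np

from equity_synth.core_types import make_groups
from equity_synth.synth_data import StudySetConfig, generate_studies
from equity_synth.synthesis import pool_group

OUT = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 100
TRUE_ICER = 50_000.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    errors = []
    for seed in range(N_SEEDS):
        cfg = StudySetConfig(
            n_studies=50, true_icer=TRUE_ICER, cost_noise_cv=0.2,
            dominance_prob=0.0, seed=seed,
        )
        icer = pool_group(make_groups(generate_studies(cfg))[0])[2]
        errors.append(icer / TRUE_ICER - 1.0)
    errors = np.array(errors)
    summary = {
        "n_seeds": N_SEEDS,
        "n_studies": 50,
        "true_icer": TRUE_ICER,
        "cost_noise_cv": 0.2,
        "median_relative_error": float(np.median(errors)),
        "median_absolute_relative_error": float(np.median(np.abs(errors))),
        "sd_relative_error": float(errors.std()),
    }
    (OUT / "generator_calibration.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"median signed error   {summary['median_relative_error']:+.4%}")
    print(f"median absolute error {summary['median_absolute_relative_error']:.4%}")
    print(f"sd of error           {summary['sd_relative_error']:.4%}")
    print(f"\nwrote {OUT / 'generator_calibration.json'}")


if __name__ == "__main__":
    main()
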