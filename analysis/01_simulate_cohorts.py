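#!/usr/bin/env python
"""Simulate the study's data sources.

Generates a multi-source cohort (two stratified-cluster national surveys
spanning ages 6 months to 65 years, plus a child cohort) and a pregnancy
cohort, all with known healthy-population centiles, and writes them with
their ground truth under results/analysis/.
"""

import json
from pathlib import Path

from hbref.synthetic import (
    SourceSpec, SurveyBlock, SyntheticConfig,
    generate_cohort, generate_pregnancy_cohort,
)

DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
TABLES = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20240229


def simulation_config(seed=SEED):
    return SyntheticConfig(
        sources=[
            SourceSpec("survey_A", 9000, (0.5, 66.0), survey=SurveyBlock()),
            SourceSpec("survey_B", 7000, (0.5, 66.0),
                       survey=SurveyBlock(n_strata=3)),
            SourceSpec("cohort_C", 6000, (0.5, 12.0)),
        ],
        seed=seed,
    )


def pregnancy_config(seed=SEED + 1):
    return SyntheticConfig(
        sources=[SourceSpec("genR", 9000, (18.0, 45.0), sex="female")],
        seed=seed,
    )


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(simulation_config())
    cohort.to_csv(DATA / "cohort.csv", index=False)
    (TABLES / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    print(f"cohort: {len(cohort)} records across "
          f"{cohort['source_id'].nunique()} sources -> {DATA/'cohort.csv'}")
    print("true healthy 5th centiles (g/L):")
    for gid, g in truth.per_group.items():
        print(f"  {gid:22s} {g['p5']:7.2f}")

    preg = generate_pregnancy_cohort(pregnancy_config(), (0.55, 0.35, 0.10))
    preg.to_csv(DATA / "pregnancy_cohort.csv", index=False)
    print(f"pregnancy cohort: {len(preg)} records -> {DATA/'pregnancy_cohort.csv'}")


if __name__ == "__main__":
    main()
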