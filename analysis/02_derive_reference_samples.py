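#!/usr/bin/env python
"""Derive apparently-healthy reference samples per group and source.

Applies the laboratory (missing labs, iron deficiency, inflammation, elevated
ferritin), clinical-flag, pregnancy-status and altitude exclusions followed
by Tukey outlier removal, and writes the reference samples and full exclusion
waterfalls.  Prints the exclusion accounting — with default prevalences most
exclusions come from iron deficiency, inflammation and clinical flags.
"""

from pathlib import Path

import pandas as pd

from hbref.cohort_io import read_cohort
from hbref.reference_filter import ExclusionConfig, derive_reference_sample

DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
TABLES = Path(__file__).resolve().parents[1] / "results" / "analysis"

GROUPS = ("c6_23m", "c24_59m", "c5_11y", "adol12_17_m", "adol12_17_f",
          "adult18_65_m", "adult18_65_f_nonpreg")


def main():
    cohort = read_cohort(DATA / "cohort.csv")
    preg = read_cohort(DATA / "pregnancy_cohort.csv")
    config = ExclusionConfig()
    rows, ref_dir = [], DATA / "reference_samples"
    ref_dir.mkdir(parents=True, exist_ok=True)

    for gid in GROUPS:
        for sid, sub in cohort.groupby("source_id"):
            kept, wf = derive_reference_sample(sub, config, gid, source_id=sid)
            if wf.n_start == 0:
                continue
            kept.to_csv(ref_dir / f"{gid}__{sid}.csv", index=False)
            rows.extend(wf.to_rows())
            print(f"{gid:22s} {sid:10s} kept {wf.n_reference:5d} / {wf.n_start:5d}")
    for gid in ("preg_t1", "preg_t2", "preg_t3"):
        kept, wf = derive_reference_sample(preg, config, gid, source_id="genR")
        if wf.n_start:
            kept.to_csv(ref_dir / f"{gid}__genR.csv", index=False)
            rows.extend(wf.to_rows())
            print(f"{gid:22s} {'genR':10s} kept {wf.n_reference:5d} / {wf.n_start:5d}")

    table = pd.DataFrame(rows)
    table.to_csv(TABLES / "waterfalls.csv", index=False)
    by_step = table.groupby("step_name")["n_excluded"].sum().sort_values(ascending=False)
    print("\ntotal exclusions by step:")
    print(by_step.to_string())


if __name__ == "__main__":
    main()
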