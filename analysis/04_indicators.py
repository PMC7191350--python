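#!/usr/bin/env python
"""Derive per-person care-continuum indicators for the eligible PLWH.

Disease stage at end of 2017, ever-stage-3, receipt of care in 2017,
viral suppression (ever / last lab / any in 2017), time to suppression,
and 2011-2016 STI/HBV/HCV diagnosis flags. Writes indicators.csv.
"""

import argparse
from pathlib import Path

from cohortlink import io
from cohortlink.config import StudyWindow
from cohortlink.continuum import derive_indicators

parser = argparse.ArgumentParser()
parser.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
parser.add_argument("--population-dir", type=Path, default=Path("results/population"))
parser.add_argument("--out", type=Path, default=Path("results/indicators.csv"))
args = parser.parse_args()

eligible = io.read_csv(args.population_dir / "eligible.csv")
labs = io.read_csv(args.in_dir / "labs.csv")
diagnoses = io.read_csv(args.in_dir / "diagnoses.csv")

indicators = derive_indicators(eligible, labs, diagnoses, StudyWindow())
io.write_csv(indicators, args.out)

print(f"indicators for {len(indicators)} persons -> {args.out}")
for col in ("care_2017", "ever_suppressed_2011_2017", "ever_stage3"):
    print(f"  {col}: {100 * indicators[col].mean():.1f}%")
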