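#!/usr/bin/env python
"""Apply the population definitions and split PLWH into cohort / non-cohort.

Eligible PLWH: diagnosed, last lab on or before 2016-12-31 inside
2011-2016 with an in-jurisdiction address, alive at the end of 2017.
Analysis-eligible roster: consented 2011-2016, resident, not withdrawn.
Writes eligible.csv, groups.csv and the exclusion tallies.
"""

import argparse
from pathlib import Path

import pandas as pd

from cohortlink import io
from cohortlink.config import StudyWindow
from cohortlink.eligibility import partition, select_cohort, select_plwh
from cohortlink.linkage import MatchDecision

parser = argparse.ArgumentParser()
parser.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
parser.add_argument("--linkage-dir", type=Path, default=Path("results/linkage"))
parser.add_argument("--out-dir", type=Path, default=Path("results/population"))
args = parser.parse_args()

window = StudyWindow()
persons = io.read_csv(args.in_dir / "registry.csv")
labs = io.read_csv(args.in_dir / "labs.csv")
roster = io.read_csv(args.in_dir / "roster.csv")
dec_df = io.read_csv(args.linkage_dir / "decisions.csv")

decisions = [
    MatchDecision(
        roster_id=str(r.roster_id),
        registry_id=None if pd.isna(r.registry_id) else str(r.registry_id),
        key_level=None if pd.isna(r.key_level) else int(r.key_level),
        score=float(r.score), review_flag=bool(r.review_flag),
        accepted=bool(r.accepted),
    )
    for r in dec_df.itertuples(index=False)
]

eligible, plwh_tally = select_plwh(persons, labs, window)
eligible_roster, roster_tally = select_cohort(roster, window)
cohort, non_cohort = partition(eligible, decisions, eligible_roster)

io.write_csv(eligible, args.out_dir / "eligible.csv")
groups = pd.DataFrame(
    {
        "person_id": pd.concat([cohort["person_id"], non_cohort["person_id"]]),
        "group": ["cohort"] * len(cohort) + ["non_cohort"] * len(non_cohort),
    }
)
io.write_csv(groups, args.out_dir / "groups.csv")
exclusions = pd.DataFrame(
    [{"population": "plwh", "bucket": k, "count": v} for k, v in plwh_tally.items()]
    + [{"population": "roster", "bucket": k, "count": v} for k, v in roster_tally.items()]
)
io.write_csv(exclusions, args.out_dir / "exclusions.csv")

share = 100 * len(cohort) / len(eligible)
print(f"eligible PLWH: {len(eligible)} of {len(persons)} registry persons")
print(f"cohort {len(cohort)} ({share:.1f}%), non-cohort {len(non_cohort)}")
print(f"PLWH exclusions: { {k: v for k, v in plwh_tally.items() if k != 'included'} }")
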