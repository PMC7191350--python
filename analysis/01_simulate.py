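#!/usr/bin/env python
"""Generate the synthetic surveillance registry and cohort roster.

Emulates a jurisdiction of ~13,000 people living with HIV of whom ~40%
enroll in a clinic-based cohort, with default identifier noise on the
roster. Writes registry.csv, labs.csv, diagnoses.csv, roster.csv and the
ground-truth links to results/synthetic/.
"""

import argparse
from pathlib import Path

from cohortlink import io
from cohortlink.config import SimConfig
from cohortlink.synthetic import simulate

parser = argparse.ArgumentParser()
parser.add_argument("--n-persons", type=int, default=13_000)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()

config = SimConfig(n_persons=args.n_persons, seed=args.seed)
persons, labs, diagnoses, roster, truth = simulate(config)

io.write_csv(persons, args.out_dir / "registry.csv")
io.write_csv(labs, args.out_dir / "labs.csv")
io.write_csv(diagnoses, args.out_dir / "diagnoses.csv")
io.write_csv(roster, args.out_dir / "roster.csv")
io.write_csv(truth.to_frame(), args.out_dir / "truth.csv")

print(f"registry: {len(persons)} persons, {len(labs)} labs, {len(diagnoses)} diagnosis events")
print(f"roster:   {len(roster)} enrollees ({100 * len(roster) / len(persons):.1f}% of registry)")
print(f"wrote tables to {args.out_dir}")
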