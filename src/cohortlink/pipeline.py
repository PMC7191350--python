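"""End-to-end pipeline: simulate -> link -> define population -> indicators -> compare.

A run is fully determined by its :class:`RunConfig` (including the
simulation seed); the manifest records package version, seeds, and row
counts at every stage so no records are silently dropped — the flow
ledger conserves: input persons -> eligible -> matched -> accepted ->
per-group counts.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

import cohortlink
from cohortlink import io
from cohortlink.config import ScoreWeights, SimConfig, StudyWindow
from cohortlink.continuum import derive_indicators
from cohortlink.eligibility import partition, select_cohort, select_plwh
from cohortlink.linkage import DEFAULT_THRESHOLD, decisions_to_frame, evaluate_linkage, link
from cohortlink.reporting import (
    overall_share,
    render_apr_table,
    render_clinical_table,
    render_demographic_table,
)
from cohortlink.stats import prepare_model_frame, run_model_suite
from cohortlink.synthetic import simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; persisting it reproduces the run."""

    out_dir: Path
    sim: Optional[SimConfig] = None          # synthetic run when set
    registry_path: Optional[Path] = None     # else: read inputs from CSVs
    labs_path: Optional[Path] = None
    diagnoses_path: Optional[Path] = None
    roster_path: Optional[Path] = None
    threshold: float = DEFAULT_THRESHOLD
    review_policy: str = "score_gate"
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    window: StudyWindow = field(default_factory=StudyWindow)
    scale: str = "prevalence_ratio"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        if "weights" in raw:
            raw["weights"] = ScoreWeights(**raw["weights"])
        if "window" in raw:
            w = raw["window"]
            raw["window"] = StudyWindow(
                lab_window=tuple(dt.date.fromisoformat(d) for d in w["lab_window"]),
                outcome_year=int(w["outcome_year"]),
                suppression_window=tuple(dt.date.fromisoformat(d) for d in w["suppression_window"]),
            )
        for key in ("out_dir", "registry_path", "labs_path", "diagnoses_path", "roster_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        return simulate(config.sim)
    for key in ("registry_path", "labs_path", "diagnoses_path", "roster_path"):
        path = getattr(config, key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input file for {key}: {path}")
    persons = io.read_csv(config.registry_path)
    labs = io.read_csv(config.labs_path)
    diagnoses = io.read_csv(config.diagnoses_path)
    roster = io.read_csv(config.roster_path)
    return persons, labs, diagnoses, roster, None


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; write artifacts + manifest.json under out_dir.

    Returns the manifest. A stage failure aborts with the stage name
    while artifacts from earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "cohortlink",
        "version": cohortlink.__version__,
        "stages": {},
    }
    if config.sim is not None:
        manifest["sim_config"] = config.sim.to_dict()
    stage = "simulate/load"
    try:
        persons, labs, diagnoses, roster, truth = _load_inputs(config)
        io.write_csv(persons, out / "registry.csv")
        io.write_csv(labs, out / "labs.csv")
        io.write_csv(diagnoses, out / "diagnoses.csv")
        io.write_csv(roster, out / "roster.csv")
        if truth is not None:
            io.write_csv(truth.to_frame(), out / "truth.csv")
        manifest["stages"][stage] = {
            "registry_persons": len(persons),
            "labs": len(labs),
            "diagnosis_events": len(diagnoses),
            "roster_records": len(roster),
        }

        stage = "link"
        decisions = link(
            roster, persons,
            weights=config.weights, policy=config.review_policy, threshold=config.threshold,
        )
        io.write_csv(decisions_to_frame(decisions), out / "decisions.csv")
        accepted = [d for d in decisions if d.accepted]
        manifest["stages"][stage] = {
            "decisions": len(decisions),
            "accepted": len(accepted),
            "review_flagged": sum(d.review_flag for d in decisions),
            "eliminated_below_threshold": sum(
                d.elimination_reason == "below_threshold" for d in decisions
            ),
            "eliminated_duplicates": sum(
                d.elimination_reason == "duplicate_loser" for d in decisions
            ),
        }
        if truth is not None:
            ev = evaluate_linkage(decisions, set(truth.pairs))
            manifest["stages"][stage]["precision"] = ev.precision
            manifest["stages"][stage]["recall"] = ev.recall
            manifest["stages"][stage]["per_level_accepted"] = {
                str(k): v for k, v in ev.per_level_accepted.items()
            }

        stage = "define-population"
        eligible, plwh_tally = select_plwh(persons, labs, config.window)
        eligible_roster, cohort_tally = select_cohort(roster, config.window)
        cohort, non_cohort = partition(eligible, decisions, eligible_roster)
        io.write_csv(eligible, out / "eligible.csv")
        exclusions = pd.DataFrame(
            [{"population": "plwh", "bucket": k, "count": v} for k, v in plwh_tally.items()]
            + [{"population": "roster", "bucket": k, "count": v} for k, v in cohort_tally.items()]
        )
        io.write_csv(exclusions, out / "exclusions.csv")
        manifest["stages"][stage] = {
            "eligible_plwh": len(eligible),
            "eligible_roster": len(eligible_roster),
            "cohort": len(cohort),
            "non_cohort": len(non_cohort),
            "cohort_share_pct": overall_share(len(cohort), len(non_cohort)),
            "plwh_exclusions": plwh_tally,
            "roster_exclusions": cohort_tally,
        }
        assert len(cohort) + len(non_cohort) == len(eligible)

        stage = "indicators"
        indicators = derive_indicators(eligible, labs, diagnoses, config.window)
        io.write_csv(indicators, out / "indicators.csv")
        manifest["stages"][stage] = {"persons": len(indicators)}

        stage = "compare"
        groups = pd.DataFrame(
            {
                "person_id": pd.concat([cohort["person_id"], non_cohort["person_id"]]),
                "group": ["cohort"] * len(cohort) + ["non_cohort"] * len(non_cohort),
            }
        )
        frame = prepare_model_frame(
            indicators, eligible, groups,
            reference_date=str(config.window.outcome_end),
        )
        table2 = render_demographic_table(frame)
        table3 = render_clinical_table(frame, config.window)
        models = run_model_suite(frame, scale=config.scale)
        table4 = render_apr_table(models)
        io.write_csv(table2, out / "table2.csv")
        io.write_csv(table3, out / "table3.csv")
        io.write_csv(table4, out / "table4.csv")
        manifest["stages"][stage] = {
            "model_frame_rows": len(frame),
            "models": {
                r["model"]: {
                    "apr": r["apr"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                    "converged": bool(r["converged"]), "method": r["method"], "n": int(r["n"]),
                }
                for _, r in models.iterrows()
            },
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
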