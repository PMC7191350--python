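"""Population definitions: who is an in-jurisdiction PLWH, who is analysis-eligible.

A person counts as living with HIV in the jurisdiction at the end of the
eligibility window when they (1) have an HIV diagnosis, (2) their most
recent lab on or before the window's end falls inside the window and was
reported with an in-jurisdiction address, and (3) they are alive at the
end of the outcome year. Roster members are analysis-eligible when they
consented inside the enrollment window, reside in the jurisdiction, and
did not withdraw.

All intervals are closed. Exclusion tallies conserve totals: included +
every exclusion bucket = input count.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from cohortlink.config import StudyWindow
from cohortlink.linkage import MatchDecision

logger = logging.getLogger(__name__)

PLWH_EXCLUSION_BUCKETS = (
    "not_diagnosed",
    "no_qualifying_lab",
    "last_lab_outside_window",
    "non_jurisdiction_lab",
    "deceased",
)
COHORT_EXCLUSION_BUCKETS = (
    "missing_consent_date",
    "consent_outside_window",
    "non_resident",
    "withdrawn",
)


def select_plwh(
    persons: pd.DataFrame,
    labs: pd.DataFrame,
    window: StudyWindow,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the PLWH population definition; return (eligible, exclusion tally).

    The "last reported lab" is the most recent lab dated on or before the
    lab window's end; a person whose most recent lab predates the window
    is excluded even if older labs fell inside it. Exclusion buckets are
    assessed in a fixed order and each person lands in exactly one.
    """
    start, end = window.lab_window
    start, end = pd.Timestamp(start), pd.Timestamp(end)

    in_scope = labs.loc[labs["lab_date"] <= end]
    last_idx = in_scope.groupby("person_id")["lab_date"].idxmax()
    last_labs = in_scope.loc[last_idx].set_index("person_id")

    tally = {bucket: 0 for bucket in PLWH_EXCLUSION_BUCKETS}
    eligible_mask = []
    for row in persons.itertuples(index=False):
        pid = row.person_id
        if pd.isna(row.hiv_diagnosis_date):
            tally["not_diagnosed"] += 1
            eligible_mask.append(False)
        elif pid not in last_labs.index:
            tally["no_qualifying_lab"] += 1
            eligible_mask.append(False)
        elif last_labs.at[pid, "lab_date"] < start:
            tally["last_lab_outside_window"] += 1
            eligible_mask.append(False)
        elif not bool(last_labs.at[pid, "jurisdiction_resident"]):
            tally["non_jurisdiction_lab"] += 1
            eligible_mask.append(False)
        elif row.vital_status_end_2017 != "alive":
            tally["deceased"] += 1
            eligible_mask.append(False)
        else:
            eligible_mask.append(True)
    eligible = persons.loc[eligible_mask].reset_index(drop=True)
    tally["included"] = len(eligible)
    assert tally["included"] + sum(tally[b] for b in PLWH_EXCLUSION_BUCKETS) == len(persons)
    return eligible, tally


def select_cohort(
    roster: pd.DataFrame,
    window: StudyWindow,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Analysis-eligible roster members; withdrawn participants are excluded
    here and therefore analyzed with the non-cohort group."""
    start, end = (pd.Timestamp(d) for d in window.lab_window)
    tally = {bucket: 0 for bucket in COHORT_EXCLUSION_BUCKETS}
    keep = []
    for row in roster.itertuples(index=False):
        if pd.isna(row.consent_date):
            tally["missing_consent_date"] += 1
            logger.info("roster %s lacks a consent date; excluded", row.roster_id)
            keep.append(False)
        elif not (start <= row.consent_date <= end):
            tally["consent_outside_window"] += 1
            keep.append(False)
        elif not bool(row.jurisdiction_resident):
            tally["non_resident"] += 1
            keep.append(False)
        elif not pd.isna(row.withdrawal_date):
            tally["withdrawn"] += 1
            keep.append(False)
        else:
            keep.append(True)
    selected = roster.loc[keep].reset_index(drop=True)
    tally["included"] = len(selected)
    assert tally["included"] + sum(tally[b] for b in COHORT_EXCLUSION_BUCKETS) == len(roster)
    return selected, tally


def partition(
    eligible_plwh: pd.DataFrame,
    decisions: Iterable[MatchDecision],
    eligible_roster: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the eligible PLWH into (cohort, non-cohort) groups.

    Cohort = eligible persons accepted-linked to an analysis-eligible
    roster record; non-cohort = the remainder. The groups are disjoint
    and exhaustive. Accepted decisions pointing at non-eligible registry
    persons are ignored (logged).
    """
    eligible_ids = set(eligible_plwh["person_id"])
    roster_ids = set(eligible_roster["roster_id"])
    cohort_ids: set[str] = set()
    for d in decisions:
        if not d.accepted:
            continue
        if d.roster_id not in roster_ids:
            continue
        if d.registry_id not in eligible_ids:
            logger.info("accepted link %s -> %s targets a non-eligible person; ignored",
                        d.roster_id, d.registry_id)
            continue
        cohort_ids.add(d.registry_id)
    in_cohort = eligible_plwh["person_id"].isin(cohort_ids)
    cohort = eligible_plwh.loc[in_cohort].reset_index(drop=True)
    non_cohort = eligible_plwh.loc[~in_cohort].reset_index(drop=True)
    return cohort, non_cohort
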