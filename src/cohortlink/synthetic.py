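"""Synthetic surveillance registry and cohort roster with known truth.

The generator emulates a jurisdiction-level HIV surveillance registry
(person demographics, longitudinal CD4/viral-load labs, STI/HBV/HCV
diagnosis events, vital status) and a cohort enrollment roster drawn from
it, with configurable identifier corruption (missing SSN, typos,
truncation, DOB component errors) and group-differential care/suppression
behavior. Ground-truth identity links are returned so that linkage
precision/recall and downstream group contrasts are testable against a
known answer.

Determinism: every draw flows from ``numpy.random.SeedSequence(seed)``
child streams keyed by stage name, so an identical config reproduces
byte-identical tables, and registry and roster generation agree on which
persons enroll without sharing mutable state.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cohortlink import _names
from cohortlink.config import CorruptionRates, SimConfig, InputError
from cohortlink.linkage import IdentifierRecord

logger = logging.getLogger(__name__)

SUPPRESSION_THRESHOLD = 200.0  # copies/mL

REGISTRY_COLUMNS = [
    "person_id", "first_name", "last_name", "birth_date", "ssn",
    "gender_identity", "race_ethnicity", "transmission_risk",
    "hiv_diagnosis_date", "vital_status_end_2017", "jurisdiction_resident",
]
LAB_COLUMNS = ["person_id", "lab_date", "kind", "value", "jurisdiction_resident"]
DIAGNOSIS_COLUMNS = ["person_id", "event_date", "kind"]
ROSTER_COLUMNS = [
    "roster_id", "first_name", "last_name", "birth_date", "ssn",
    "consent_date", "withdrawal_date", "jurisdiction_resident",
]


@dataclass(frozen=True)
class GroundTruth:
    """True identity links between registry and roster."""

    pairs: frozenset  # of (registry_person_id, roster_person_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.pairs), columns=["registry_person_id", "roster_person_id"])
        return df


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    # stage-keyed child stream; stable across interpreter runs
    key = int.from_bytes(stage.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), key]))


def _random_dates(rng: np.random.Generator, start: dt.date, end: dt.date, n: int) -> np.ndarray:
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=n)
    base = np.datetime64(start.isoformat())
    return base + offsets.astype("timedelta64[D]")


def _categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    labels = list(dist)
    probs = np.asarray([dist[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def enrollment_mask(config: SimConfig) -> np.ndarray:
    """Which registry persons enroll in the cohort (shared by both generators)."""
    rng = _rng(config, "enroll")
    return rng.random(config.n_persons) < config.enroll_fraction


# ---------------------------------------------------------------------------
# Registry


def generate_registry(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (persons, labs, diagnoses) tables for the surveillance registry.

    Persons carry demographics, a diagnosis date on or before the study
    window's end, a vital-status flag at the end of the outcome year, and
    a jurisdiction-residence flag. Labs are typed (CD4 count, CD4
    percent, viral load), dated, and flagged with the person's
    jurisdiction residence. Clinical behavior is group-differential:
    persons destined to enroll follow the cohort outcome probabilities,
    the rest the non-cohort ones.
    """
    n = config.n_persons
    window_start, window_end = config.study_window
    outcome_year = config.outcome_year

    rng_id = _rng(config, "identity")
    rng_demo = _rng(config, "demographics")
    rng_clin = _rng(config, "clinical")
    rng_dx = _rng(config, "diagnoses")

    first = rng_id.choice(_names.FIRST_NAMES, size=n)
    last = rng_id.choice(_names.LAST_NAMES, size=n)
    # unique 9-digit SSNs (rejection-sample duplicates; collisions are rare)
    seen: set[int] = set()
    ssn_ints: list[int] = []
    while len(ssn_ints) < n:
        for s in rng_id.integers(100_000_000, 1_000_000_000, size=n - len(ssn_ints)):
            s = int(s)
            if s not in seen:
                seen.add(s)
                ssn_ints.append(s)
    ssn = np.array([f"{s:09d}" for s in ssn_ints])

    # ages roughly 20-80 at the end of the outcome year
    birth = _random_dates(rng_demo, dt.date(outcome_year - 80, 1, 1), dt.date(outcome_year - 20, 12, 31), n)
    gender = _categorical(rng_demo, config.demographics["gender_identity"], n)
    race = _categorical(rng_demo, config.demographics["race_ethnicity"], n)
    risk = _categorical(rng_demo, config.demographics["transmission_risk"], n)

    # diagnosis between age 18-ish and the window end
    dx_earliest = np.maximum(birth + np.timedelta64(18 * 365, "D"), np.datetime64("1985-01-01"))
    dx_latest = np.datetime64(window_end.isoformat())
    dx_span = np.maximum((dx_latest - dx_earliest) / np.timedelta64(1, "D"), 0).astype(int)
    dx = dx_earliest + (rng_demo.random(n) * (dx_span + 1)).astype(int).astype("timedelta64[D]")

    deceased = rng_demo.random(n) < config.deceased_fraction
    resident = rng_demo.random(n) >= config.non_resident_fraction
    stale = rng_demo.random(n) < config.stale_lab_fraction

    enrolled = enrollment_mask(config)

    persons = pd.DataFrame(
        {
            "person_id": [f"R{i:06d}" for i in range(n)],
            "first_name": first,
            "last_name": last,
            "birth_date": pd.to_datetime(birth),
            "ssn": ssn,
            "gender_identity": gender,
            "race_ethnicity": race,
            "transmission_risk": risk,
            "hiv_diagnosis_date": pd.to_datetime(dx),
            "vital_status_end_2017": np.where(deceased, "deceased", "alive"),
            "jurisdiction_resident": resident,
        }
    )

    labs = _generate_labs(config, persons, enrolled, stale, rng_clin)
    diagnoses = _generate_diagnoses(config, persons, rng_dx)
    return persons, labs, diagnoses


def _generate_labs(
    config: SimConfig,
    persons: pd.DataFrame,
    enrolled: np.ndarray,
    stale: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-person lab trajectories honoring the group outcome model.

    Per person: a Poisson number of labs dated uniformly in the study
    window; if the person is "in care" in the outcome year one lab is
    redated into that year and forced to be a viral load. Within an
    ever-suppressed trajectory the suppressed viral loads form a suffix
    in date order (a changepoint process), except that when the
    last-lab-suppressed flag is false the final outcome-year VL rebounds
    to detectable.
    """
    window_start, window_end = config.study_window
    outcome_year = config.outcome_year
    outcome_start = dt.date(outcome_year, 1, 1)
    outcome_end = dt.date(outcome_year, 12, 31)
    n = config.n_persons

    p_cohort = config.outcome_model["cohort"]
    p_non = config.outcome_model["non_cohort"]
    p_care = np.where(enrolled, p_cohort.care_in_year, p_non.care_in_year)
    p_ever = np.where(enrolled, p_cohort.ever_suppressed, p_non.ever_suppressed)
    p_last = np.where(enrolled, p_cohort.suppressed_last_lab, p_non.suppressed_last_lab)

    care = rng.random(n) < p_care
    last_supp = care & (rng.random(n) < p_last)
    # ever = last OR residual Bernoulli so that P(ever) = p_ever whether or not in care
    resid = np.divide(p_ever - p_last, 1.0 - p_last, out=np.zeros(n), where=p_last < 1.0)
    resid = np.clip(resid, 0.0, 1.0)
    ever = np.where(care, last_supp | (rng.random(n) < resid), rng.random(n) < p_ever)

    counts = rng.poisson(config.labs_per_person_mean, size=n)
    person_mean_cd4 = rng.uniform(150.0, 900.0, size=n)

    person_ids: list[str] = []
    dates: list[np.datetime64] = []
    kinds: list[str] = []
    values: list[float] = []

    ids = persons["person_id"].to_numpy()
    residents = persons["jurisdiction_resident"].to_numpy()
    kind_choices = np.array(["viral_load", "cd4_count", "cd4_percent"])
    kind_probs = np.array([0.55, 0.35, 0.10])

    for i in range(n):
        n_labs = int(counts[i])
        if n_labs == 0:
            continue
        if stale[i]:
            lab_dates = np.sort(_random_dates(rng, dt.date(window_start.year - 3, 1, 1),
                                              window_start - dt.timedelta(days=1), n_labs))
            in_care = False
        else:
            lab_dates = np.sort(_random_dates(rng, window_start, window_end, n_labs))
            in_care = bool(care[i])
            if in_care:
                # redate the chronologically last lab into the outcome year;
                # half the time a second lab too, so rebound trajectories
                # (suppressed earlier in the year, detectable at its end) occur
                lab_dates[-1] = _random_dates(rng, outcome_start, outcome_end, 1)[0]
                if n_labs >= 2 and rng.random() < 0.5:
                    earlier = _random_dates(rng, outcome_start, outcome_end, 1)[0]
                    if earlier >= lab_dates[-1]:
                        lab_dates[-1], earlier = earlier, lab_dates[-1]
                    lab_dates[-2] = earlier
                    if lab_dates[-2] == lab_dates[-1]:
                        lab_dates[-2] = lab_dates[-1] - np.timedelta64(1, "D")
        kind = rng.choice(kind_choices, size=n_labs, p=kind_probs)
        if in_care:
            kind[-1] = "viral_load"  # guarantees an outcome-year VL for in-care persons

        vl_idx = np.flatnonzero(kind == "viral_load")
        is_ever = bool(ever[i]) and not stale[i]
        if is_ever and len(vl_idx) == 0:
            # retype one lab so the ever-suppressed flag is realizable
            j = int(rng.integers(0, n_labs))
            kind[j] = "viral_load"
            vl_idx = np.array([j])

        vals = np.empty(n_labs)
        for j in range(n_labs):
            if kind[j] == "cd4_count":
                vals[j] = max(rng.normal(person_mean_cd4[i], 150.0), 0.0)
            elif kind[j] == "cd4_percent":
                vals[j] = float(np.clip(rng.normal(person_mean_cd4[i] / 30.0, 5.0), 0.0, 100.0))

        if len(vl_idx):
            n_vl = len(vl_idx)
            detect = np.power(10.0, rng.uniform(2.8, 5.7, size=n_vl))  # detectable: > 200
            supp = rng.uniform(0.0, SUPPRESSION_THRESHOLD, size=n_vl)  # suppressed: <= 200
            if not is_ever:
                suppressed_mask = np.zeros(n_vl, dtype=bool)
            else:
                want_last = bool(last_supp[i]) if in_care else True
                if in_care and not want_last:
                    if n_vl == 1:
                        # single VL cannot be both ever-suppressed and detectable at last
                        # lab; honor the last-lab flag by suppressing it (rare)
                        suppressed_mask = np.ones(1, dtype=bool)
                    else:
                        k = int(rng.integers(0, n_vl - 1))
                        suppressed_mask = np.arange(n_vl) >= k
                        suppressed_mask[-1] = False  # rebound at the last outcome-year VL
                else:
                    k = int(rng.integers(0, n_vl))
                    suppressed_mask = np.arange(n_vl) >= k
            vals[vl_idx] = np.where(suppressed_mask, supp, detect)

        person_ids.extend([ids[i]] * n_labs)
        dates.extend(lab_dates)
        kinds.extend(kind)
        values.extend(vals)

    labs = pd.DataFrame(
        {
            "person_id": person_ids,
            "lab_date": pd.to_datetime(np.array(dates, dtype="datetime64[D]")),
            "kind": kinds,
            "value": np.round(values, 1),
        }
    )
    labs["jurisdiction_resident"] = labs["person_id"].map(
        dict(zip(ids, residents))
    )
    # diagnosis precedes every lab: pull the diagnosis date back where needed
    first_lab = labs.groupby("person_id")["lab_date"].min()
    mapped = persons["person_id"].map(first_lab)
    clip_needed = mapped.notna() & (persons["hiv_diagnosis_date"] > mapped)
    persons.loc[clip_needed, "hiv_diagnosis_date"] = mapped[clip_needed]
    return labs


def _generate_diagnoses(config: SimConfig, persons: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """STI / confirmed-HBV / confirmed-HCV / AIDS-defining-OI event table.

    Event dates fall in a span widened one year on each side of the
    study window so the window filter of the comorbidity flags is
    exercised by construction.
    """
    window_start, window_end = config.study_window
    lo = dt.date(window_start.year - 1, 1, 1)
    hi = dt.date(window_end.year + 1, 12, 31)
    ids = persons["person_id"].to_numpy()
    rows_id: list[str] = []
    rows_date: list[np.datetime64] = []
    rows_kind: list[str] = []
    for kind, rate in config.diagnosis_rates.items():
        hit = rng.random(len(ids)) < rate
        hit_ids = ids[hit]
        dates = _random_dates(rng, lo, hi, len(hit_ids))
        rows_id.extend(hit_ids)
        rows_date.extend(dates)
        rows_kind.extend([kind] * len(hit_ids))
    diagnoses = pd.DataFrame(
        {
            "person_id": rows_id,
            "event_date": pd.to_datetime(np.array(rows_date, dtype="datetime64[D]")),
            "kind": rows_kind,
        }
    ).sort_values(["person_id", "event_date", "kind"], ignore_index=True)
    return diagnoses


# ---------------------------------------------------------------------------
# Identifier corruption


def corrupt_identifiers(
    record: IdentifierRecord,
    rates: CorruptionRates,
    rng: np.random.Generator,
) -> IdentifierRecord:
    """Apply identifier noise, each corruption independently at its rate.

    Fixed order (missing SSN, name typo, name truncation, DOB component
    error) so one seeded stream fully determines the output. Typos
    substitute one letter at a random position; truncation keeps a
    random-length prefix of at least 3 letters; the DOB error perturbs
    exactly one of day/month/year. Names shorter than 3 letters pass
    through truncation untouched (logged at debug level).
    """
    first, last, dob, ssn = record.first_name, record.last_name, record.dob, record.ssn

    if rng.random() < rates.ssn_missing:
        ssn = ""

    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for which in ("first", "last"):
        name = first if which == "first" else last
        if name and rng.random() < rates.name_typo:
            pos = int(rng.integers(0, len(name)))
            old = name[pos]
            choices = alphabet.replace(old.upper(), "") or alphabet
            sub = choices[int(rng.integers(0, len(choices)))]
            name = name[:pos] + sub + name[pos + 1 :]
        if rng.random() < rates.name_truncation:
            if len(name) <= 3:
                logger.debug("name %r too short to truncate; passed through", name)
            else:
                keep = int(rng.integers(3, len(name)))
                name = name[:keep]
        if which == "first":
            first = name
        else:
            last = name

    if dob is not None and rng.random() < rates.dob_component_error:
        part = ("day", "month", "year")[int(rng.integers(0, 3))]
        if part == "day":
            day = 1 + (dob.day - 1 + 1 + int(rng.integers(0, 27))) % 28
            dob = dob.replace(day=day)
        elif part == "month":
            month = 1 + (dob.month - 1 + 1 + int(rng.integers(0, 11))) % 12
            dob = dob.replace(month=month, day=min(dob.day, 28))
        else:
            delta = int(rng.integers(1, 10)) * (1 if rng.random() < 0.5 else -1)
            dob = dob.replace(year=dob.year + delta, day=min(dob.day, 28))
    return IdentifierRecord(first_name=first, last_name=last, dob=dob, ssn=ssn)


# ---------------------------------------------------------------------------
# Roster


def generate_roster(
    registry: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Enroll a subset of registry persons into the cohort roster.

    The enrollment subset is the same one the registry generator used
    for group-differential clinical behavior. Roster identifiers pass
    through :func:`corrupt_identifiers`; consent dates are uniform in
    the study window; a small fraction withdraw after consent.
    """
    if registry.empty:
        raise InputError("registry is empty; generate it before the roster")
    mask = enrollment_mask(config)[: len(registry)]
    enrolled = registry.loc[mask].reset_index(drop=True)
    rng = _rng(config, "roster")

    rows = []
    pairs = []
    for i, row in enumerate(enrolled.itertuples(index=False)):
        ident = IdentifierRecord(
            first_name=row.first_name,
            last_name=row.last_name,
            dob=row.birth_date.date() if isinstance(row.birth_date, pd.Timestamp) else row.birth_date,
            ssn=row.ssn,
        )
        ident = corrupt_identifiers(ident, config.corruption_rates, rng)
        roster_id = f"C{i:06d}"
        consent = _random_dates(rng, config.study_window[0], config.study_window[1], 1)[0]
        withdrew = rng.random() < config.withdrawal_fraction
        withdrawal = (
            pd.Timestamp(consent) + pd.Timedelta(days=int(rng.integers(30, 720)))
            if withdrew
            else pd.NaT
        )
        rows.append(
            {
                "roster_id": roster_id,
                "first_name": ident.first_name,
                "last_name": ident.last_name,
                "birth_date": pd.Timestamp(ident.dob) if ident.dob else pd.NaT,
                "ssn": ident.ssn,
                "consent_date": pd.Timestamp(consent),
                "withdrawal_date": withdrawal,
                "jurisdiction_resident": row.jurisdiction_resident,
            }
        )
        pairs.append((row.person_id, roster_id))
    roster = pd.DataFrame(rows, columns=ROSTER_COLUMNS)
    if roster.empty:
        roster = roster.astype({"birth_date": "datetime64[ns]",
                                "consent_date": "datetime64[ns]",
                                "withdrawal_date": "datetime64[ns]"})
    return roster, GroundTruth(pairs=frozenset(pairs))


def simulate(config: SimConfig):
    """Convenience wrapper: registry tables, roster, and ground truth."""
    persons, labs, diagnoses = generate_registry(config)
    roster, truth = generate_roster(persons, config)
    return persons, labs, diagnoses, roster, truth
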