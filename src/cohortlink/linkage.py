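"""Deterministic 11-level match-key cascade with validation scoring.

A roster record links to a registry record at the lowest cascade level
whose composite key agrees on both sides. Levels, in priority order:

 1   social security number
 2   first name (letters 1-6), last name, date of birth
 3   last name (letter 1), last name (letters 3-8), first name (letters 2-8), DOB
 4   same name slices as 3, birth month + birth year
 5   same name slices as 3, birth day + birth year
 6   last name, first name (letters 1-2), DOB
 7   last name (letters 1-3), first name (letters 1-3), DOB
 8   last name (letters 1-4), first name (letters 1-4), birth year
 9   first name (letters 1-3), last name (letters 1-3), birth month + birth year
10   first name (letters 1-3), last name (letters 1-3), birth day + birth year
11   first name (letters 1-3), last name (letters 1-3), birth month + birth year

Letter indices are 1-based inclusive. A name shorter than a slice's start
position yields no key at that level; a name shorter than the slice's end
uses the available substring. Level 11 repeats level 9's definition and is
therefore unreachable (any pair agreeing at 11 already agreed at 9); it is
kept for fidelity to the published cascade and a warning is logged once
per run.

Candidate links at levels 7-11 — partial names only — carry a review flag.
Every candidate link is scored by a weighted field-agreement score on a
0-100 scale and gated at a configurable acceptance threshold (default 80).
One-to-one linkage is enforced: collisions resolve by lowest level, then
highest score, then lowest registry ID.
"""

from __future__ import annotations

import datetime as dt
import logging
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import edlib
import pandas as pd

from cohortlink.config import ConfigurationError, InputError, ScoreWeights

logger = logging.getLogger(__name__)

ReviewPolicy = Literal["auto_accept", "auto_reject", "score_gate"]
EliminationReason = Optional[Literal["manual_review", "below_threshold", "duplicate_loser"]]

REVIEW_LEVELS = frozenset({7, 8, 9, 10, 11})
DEFAULT_THRESHOLD = 80.0
_SEP = "|"


@dataclass(frozen=True)
class IdentifierRecord:
    """Linkage-relevant identity fields of one person.

    ``ssn`` is 9 digits or empty; anything else normalizes to empty
    (treated as missing). ``dob`` may be None when unknown.
    """

    first_name: str
    last_name: str
    dob: Optional[dt.date]
    ssn: str = ""


@dataclass
class MatchDecision:
    """Outcome of linking one roster record against the registry."""

    roster_id: str
    registry_id: Optional[str]
    key_level: Optional[int]
    score: float = 0.0
    review_flag: bool = False
    accepted: bool = False
    elimination_reason: EliminationReason = None


def _fold(name: str) -> str:
    # NFKD-decompose, drop combining marks, keep A-Z only
    decomposed = unicodedata.normalize("NFKD", name.upper())
    return "".join(c for c in decomposed if c.isascii() and c.isalpha())


def normalize(record: IdentifierRecord) -> IdentifierRecord:
    """Return the record in canonical comparison form (idempotent).

    Names: upper-cased, whitespace-trimmed, diacritics folded to ASCII,
    all non-alphabetic characters removed. SSN: digits only; if the
    result is not exactly 9 digits it becomes empty (missing).
    """
    ssn = "".join(c for c in record.ssn if c.isdigit()) if record.ssn else ""
    if len(ssn) != 9:
        ssn = ""
    return IdentifierRecord(
        first_name=_fold(record.first_name.strip()),
        last_name=_fold(record.last_name.strip()),
        dob=record.dob,
        ssn=ssn,
    )


# ---------------------------------------------------------------------------
# Match-key construction


@dataclass(frozen=True)
class _Slice:
    """1-based inclusive letter slice of a name field ('first' or 'last').

    start=None means the whole name. A name shorter than ``start``
    produces no component; a name shorter than ``end`` contributes its
    available suffix of the slice.
    """

    field: str
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass(frozen=True)
class _DobPart:
    part: str  # 'full' | 'day' | 'month' | 'year'


_SSN = ("ssn",)

#: The 11 built-in key specifications, level -> ordered components.
MATCH_KEY_SPECS: dict[int, tuple] = {
    1: (_SSN,),
    2: (_Slice("first", 1, 6), _Slice("last"), _DobPart("full")),
    3: (_Slice("last", 1, 1), _Slice("last", 3, 8), _Slice("first", 2, 8), _DobPart("full")),
    4: (_Slice("last", 1, 1), _Slice("last", 3, 8), _Slice("first", 2, 8), _DobPart("month"), _DobPart("year")),
    5: (_Slice("last", 1, 1), _Slice("last", 3, 8), _Slice("first", 2, 8), _DobPart("day"), _DobPart("year")),
    6: (_Slice("last"), _Slice("first", 1, 2), _DobPart("full")),
    7: (_Slice("last", 1, 3), _Slice("first", 1, 3), _DobPart("full")),
    8: (_Slice("last", 1, 4), _Slice("first", 1, 4), _DobPart("year")),
    9: (_Slice("first", 1, 3), _Slice("last", 1, 3), _DobPart("month"), _DobPart("year")),
    10: (_Slice("first", 1, 3), _Slice("last", 1, 3), _DobPart("day"), _DobPart("year")),
    11: (_Slice("first", 1, 3), _Slice("last", 1, 3), _DobPart("month"), _DobPart("year")),
}

LEVELS: tuple[int, ...] = tuple(sorted(MATCH_KEY_SPECS))


def build_key(record: IdentifierRecord, level: int) -> Optional[str]:
    """Build the level's composite key for a normalized record.

    Returns None when any required component is unavailable: missing
    SSN at level 1, missing DOB where a DOB component is needed, or a
    name shorter than a slice's start letter.
    """
    try:
        spec = MATCH_KEY_SPECS[level]
    except KeyError:
        raise ValueError(f"match level must be in 1..11, got {level!r}") from None
    parts: list[str] = []
    for comp in spec:
        if comp is _SSN:
            if not record.ssn:
                return None
            parts.append(record.ssn)
        elif isinstance(comp, _DobPart):
            if record.dob is None:
                return None
            d = record.dob
            if comp.part == "full":
                parts.append(d.isoformat())
            elif comp.part == "day":
                parts.append(f"D{d.day:02d}")
            elif comp.part == "month":
                parts.append(f"M{d.month:02d}")
            else:
                parts.append(f"Y{d.year:04d}")
        else:  # _Slice
            name = record.first_name if comp.field == "first" else record.last_name
            if comp.start is None:
                if not name:
                    return None
                parts.append(name)
            else:
                if len(name) < comp.start:
                    return None
                parts.append(name[comp.start - 1 : comp.end])
    return _SEP.join(parts)


# ---------------------------------------------------------------------------
# Agreement score


def _name_similarity(a: str, b: str) -> float:
    dist = edlib.align(a, b)["editDistance"]
    longest = max(len(a), len(b))
    return 1.0 - dist / longest if longest else 1.0


def score_pair(a: IdentifierRecord, b: IdentifierRecord, weights: ScoreWeights | None = None) -> float:
    """Weighted field-agreement score between two normalized records, 0-100.

    Per-field agreement: SSN exact match (0/1), names by normalized edit
    distance ratio, DOB day/month/year exact (0/1 each). Only fields
    present on both sides enter the weighting — a field missing on
    either side is not evidence for or against the link, so a pair
    identical on its comparable fields still scores 100. Monotone
    non-decreasing in every field's agreement, symmetric, and affinely
    scaled so full agreement gives 100 and total disagreement 0.
    """
    w = weights or ScoreWeights()
    total = 0.0
    achieved = 0.0

    if a.ssn and b.ssn:
        total += w.ssn
        achieved += w.ssn * float(a.ssn == b.ssn)
    if a.first_name and b.first_name:
        total += w.first_name
        achieved += w.first_name * _name_similarity(a.first_name, b.first_name)
    if a.last_name and b.last_name:
        total += w.last_name
        achieved += w.last_name * _name_similarity(a.last_name, b.last_name)
    if a.dob is not None and b.dob is not None:
        total += w.dob_day + w.dob_month + w.dob_year
        achieved += w.dob_day * float(a.dob.day == b.dob.day)
        achieved += w.dob_month * float(a.dob.month == b.dob.month)
        achieved += w.dob_year * float(a.dob.year == b.dob.year)
    if total == 0:
        return 0.0
    return 100.0 * achieved / total


# ---------------------------------------------------------------------------
# Cascade


def _identifier_from_row(row) -> IdentifierRecord:
    dob = row.birth_date
    if pd.isna(dob):
        dob = None
    elif isinstance(dob, pd.Timestamp):
        dob = dob.date()
    ssn = "" if pd.isna(row.ssn) else str(row.ssn)
    return normalize(
        IdentifierRecord(
            first_name=str(row.first_name) if not pd.isna(row.first_name) else "",
            last_name=str(row.last_name) if not pd.isna(row.last_name) else "",
            dob=dob,
            ssn=ssn,
        )
    )


def _records_from_frame(df: pd.DataFrame, id_col: str) -> list[tuple[str, IdentifierRecord]]:
    out = []
    for row in df.itertuples(index=False):
        out.append((str(getattr(row, id_col)), _identifier_from_row(row)))
    # internal sort makes the cascade independent of input row order
    out.sort(key=lambda t: t[0])
    return out


def cascade_match(
    roster: pd.DataFrame,
    registry: pd.DataFrame,
    weights: ScoreWeights | None = None,
    levels: Sequence[int] = LEVELS,
) -> list[MatchDecision]:
    """Match each roster record into the registry at its lowest agreeing level.

    Both frames need identifier columns (first_name, last_name,
    birth_date, ssn) plus ``roster_id`` / ``person_id``. For each roster
    record, candidates are registry records agreeing on the lowest level
    whose key is defined on both sides; ties (several registry records
    sharing the winning key) all become decisions and are resolved later
    by :func:`resolve_duplicates`. Records with no agreement at any level
    get ``registry_id=None``.
    """
    if registry["person_id"].duplicated().any():
        dupes = registry.loc[registry["person_id"].duplicated(), "person_id"].tolist()
        raise InputError(f"duplicate registry person_id values: {dupes[:5]}")
    if 11 in levels:
        logger.warning(
            "match level 11 duplicates level 9's key definition and is unreachable; "
            "retained for cascade fidelity"
        )

    registry_records = _records_from_frame(registry, "person_id")
    roster_records = _records_from_frame(roster, "roster_id")

    # level -> key -> sorted registry ids
    index: dict[int, dict[str, list[str]]] = {}
    for level in levels:
        table: dict[str, list[str]] = {}
        for rid, rec in registry_records:
            key = build_key(rec, level)
            if key is not None:
                table.setdefault(key, []).append(rid)
        index[level] = table

    registry_by_id = dict(registry_records)
    decisions: list[MatchDecision] = []
    for roster_id, rec in roster_records:
        matched = False
        for level in sorted(levels):
            key = build_key(rec, level)
            if key is None:
                continue
            candidates = index[level].get(key)
            if candidates:
                for rid in candidates:
                    decisions.append(
                        MatchDecision(
                            roster_id=roster_id,
                            registry_id=rid,
                            key_level=level,
                            score=score_pair(rec, registry_by_id[rid], weights),
                            review_flag=level in REVIEW_LEVELS,
                        )
                    )
                matched = True
                break
        if not matched:
            decisions.append(MatchDecision(roster_id=roster_id, registry_id=None, key_level=None))
    return decisions


def resolve_duplicates(decisions: list[MatchDecision]) -> list[MatchDecision]:
    """Enforce one-to-one linkage.

    Among decisions sharing a roster or registry ID, the decision with
    the lowest key level, then the highest score, then the lowest
    registry ID survives; the rest are eliminated as duplicate losers.
    Deterministic for any input order.
    """
    matched = [d for d in decisions if d.registry_id is not None]
    unmatched = [d for d in decisions if d.registry_id is None]
    matched.sort(key=lambda d: (d.key_level, -d.score, d.registry_id, d.roster_id))
    used_roster: set[str] = set()
    used_registry: set[str] = set()
    for d in matched:
        if d.roster_id in used_roster or d.registry_id in used_registry:
            d.elimination_reason = "duplicate_loser"
            d.accepted = False
        else:
            used_roster.add(d.roster_id)
            used_registry.add(d.registry_id)
    out = matched + unmatched
    out.sort(key=lambda d: (d.roster_id, d.registry_id or ""))
    return out


def apply_review_policy(
    decisions: list[MatchDecision],
    policy: ReviewPolicy = "score_gate",
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchDecision]:
    """Set review flags and final acceptance.

    Levels 7-11 carry ``review_flag``. Under ``auto_reject`` they are
    eliminated outright (reason ``manual_review``); under ``auto_accept``
    and ``score_gate`` they pass review and face the same global score
    threshold as every other link (``score_gate`` makes the threshold
    the review instrument, which is also the default policy). Any
    surviving link with score below the threshold is eliminated as
    ``below_threshold``; the rest are accepted.
    """
    if policy not in ("auto_accept", "auto_reject", "score_gate"):
        raise ConfigurationError(f"unknown review policy {policy!r}")
    for d in decisions:
        if d.registry_id is None:
            d.accepted = False
            continue
        d.review_flag = d.key_level in REVIEW_LEVELS
        if d.elimination_reason == "duplicate_loser":
            d.accepted = False
            continue
        if d.review_flag and policy == "auto_reject":
            d.elimination_reason = "manual_review"
            d.accepted = False
            continue
        if d.score < threshold:
            d.elimination_reason = "below_threshold"
            d.accepted = False
            continue
        d.elimination_reason = None
        d.accepted = True
    return decisions


def link(
    roster: pd.DataFrame,
    registry: pd.DataFrame,
    weights: ScoreWeights | None = None,
    policy: ReviewPolicy = "score_gate",
    threshold: float = DEFAULT_THRESHOLD,
    levels: Sequence[int] = LEVELS,
) -> list[MatchDecision]:
    """Full linkage: cascade, deduplication, review policy, acceptance."""
    decisions = cascade_match(roster, registry, weights=weights, levels=levels)
    decisions = resolve_duplicates(decisions)
    return apply_review_policy(decisions, policy=policy, threshold=threshold)


# ---------------------------------------------------------------------------
# Evaluation against ground truth


@dataclass(frozen=True)
class LinkageEvaluation:
    precision: Optional[float]
    recall: Optional[float]
    n_true_links: int
    n_accepted: int
    n_true_accepted: int
    per_level_accepted: dict[int, int]


def evaluate_linkage(decisions: Iterable[MatchDecision], truth: set[tuple[str, str]]) -> LinkageEvaluation:
    """Precision/recall of accepted links against true (registry, roster) pairs.

    Precision is None when nothing was accepted; recall is None (with a
    warning) when the truth set is empty.
    """
    accepted = [d for d in decisions if d.accepted]
    n_true_accepted = sum((d.registry_id, d.roster_id) in truth for d in accepted)
    per_level: dict[int, int] = {}
    for d in accepted:
        per_level[d.key_level] = per_level.get(d.key_level, 0) + 1
    precision = n_true_accepted / len(accepted) if accepted else None
    if truth:
        recall = n_true_accepted / len(truth)
    else:
        logger.warning("empty ground truth: recall is undefined")
        recall = None
    return LinkageEvaluation(
        precision=precision,
        recall=recall,
        n_true_links=len(truth),
        n_accepted=len(accepted),
        n_true_accepted=n_true_accepted,
        per_level_accepted=dict(sorted(per_level.items())),
    )


def decisions_to_frame(decisions: Iterable[MatchDecision]) -> pd.DataFrame:
    """Decision list as the decisions.csv table."""
    rows = [
        {
            "roster_id": d.roster_id,
            "registry_id": d.registry_id,
            "key_level": d.key_level,
            "score": round(d.score, 4),
            "review_flag": d.review_flag,
            "accepted": d.accepted,
            "elimination_reason": d.elimination_reason,
        }
        for d in decisions
    ]
    df = pd.DataFrame(rows, columns=[
        "roster_id", "registry_id", "key_level", "score",
        "review_flag", "accepted", "elimination_reason",
    ])
    if not df.empty:
        df["key_level"] = df["key_level"].astype("Int64")
    return df


def brute_force_match(
    roster: pd.DataFrame,
    registry: pd.DataFrame,
    levels: Sequence[int] = LEVELS,
) -> list[MatchDecision]:
    """All-pairs, all-levels reference implementation of the cascade.

    Evaluates every (roster, registry) pair at every level and keeps,
    per roster record, all registry records achieving the global minimum
    agreeing level. Quadratic; intended as an independent oracle on
    small instances, not for production use.
    """
    registry_records = _records_from_frame(registry, "person_id")
    roster_records = _records_from_frame(roster, "roster_id")
    decisions: list[MatchDecision] = []
    for roster_id, rec in roster_records:
        best_level: Optional[int] = None
        best: list[str] = []
        for rid, reg in registry_records:
            for level in sorted(levels):
                ka, kb = build_key(rec, level), build_key(reg, level)
                if ka is not None and ka == kb:
                    if best_level is None or level < best_level:
                        best_level, best = level, [rid]
                    elif level == best_level:
                        best.append(rid)
                    break
        if best_level is None:
            decisions.append(MatchDecision(roster_id=roster_id, registry_id=None, key_level=None))
        else:
            registry_by_id = dict(registry_records)
            for rid in sorted(best):
                decisions.append(
                    MatchDecision(
                        roster_id=roster_id,
                        registry_id=rid,
                        key_level=best_level,
                        score=score_pair(rec, registry_by_id[rid]),
                        review_flag=best_level in REVIEW_LEVELS,
                    )
                )
    return decisions
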