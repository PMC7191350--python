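"""Per-person HIV care-continuum indicators.

Derived from longitudinal CD4 and viral-load labs plus diagnosis events:

- disease stage at the end of the outcome year (CDC staging: stage 1
  CD4 > 500 cells/uL or CD4% >= 29; stage 2 CD4 200-500 or CD4% 14-28;
  stage 3 CD4 < 200, CD4% < 14, or an AIDS-defining opportunistic
  infection), using the last lab values on or before the outcome year's
  end, CD4 count taking precedence over CD4 percent;
- ever stage 3 (any CD4 < 200, CD4% < 14, or OI event at any time);
- receipt of care (>= 1 CD4 or VL lab in the outcome year);
- viral suppression: ever (any VL <= 200 copies/mL in the suppression
  window), at the last VL of the outcome year, and at any VL of the
  outcome year (the last two differ when a suppressed person rebounds);
- time to suppression: days from the first detectable VL (> 200) to the
  first subsequent suppressed VL, in months of 30.4375 days, categorized
  0-24 vs > 24 months;
- STI / confirmed chronic HBV / confirmed chronic HCV diagnosis flags
  within the enrollment window.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

import numpy as np
import pandas as pd

from cohortlink.config import StudyWindow

SUPPRESSION_THRESHOLD = 200.0  # copies/mL; suppression is VL <= threshold, inclusive
DAYS_PER_MONTH = 30.4375
TTS_BOUNDARY_MONTHS = 24.0  # "0-24" is inclusive of 24

Stage = Literal[1, 2, 3, "unknown"]

#: diagnosis-event kinds that count for each comorbidity flag; antibody-only
#: (unconfirmed) hepatitis records are not in these sets and never count
COMORBIDITY_KINDS = {
    "sti": {"sti"},
    "hbv": {"hbv_chronic_confirmed"},
    "hcv": {"hcv_chronic_confirmed"},
}
OI_KIND = "oi_aids_defining"

INDICATOR_COLUMNS = [
    "person_id", "stage_2017", "ever_stage3", "care_2017",
    "ever_suppressed_2011_2017", "suppressed_last_lab_2017",
    "suppressed_any_2017", "tts_months", "tts_category",
    "sti_2011_2016", "hbv_2011_2016", "hcv_2011_2016", "cd4_recent",
]


def classify_stage(
    cd4_count: Optional[float],
    cd4_percent: Optional[float],
    has_oi: bool = False,
) -> Stage:
    """CDC disease stage from a CD4 count, CD4 percent, and OI history.

    An AIDS-defining OI forces stage 3. Otherwise the CD4 count, when
    present, takes precedence over the percent: < 200 is stage 3,
    200-500 stage 2, > 500 stage 1. With only a percent: < 14 is stage
    3, >= 29 stage 1, the 14-28 band stage 2. With neither input the
    stage is unknown.
    """
    if has_oi:
        return 3
    if cd4_count is not None:
        if cd4_count < 200:
            return 3
        if cd4_count > 500:
            return 1
        return 2
    if cd4_percent is not None:
        if cd4_percent < 14:
            return 3
        if cd4_percent >= 29:
            return 1
        return 2
    return "unknown"


def stage_in_year(labs: pd.DataFrame, window: StudyWindow, has_oi: bool = False) -> Stage:
    """Stage from the most recent CD4 values on or before the outcome year's end."""
    cutoff = pd.Timestamp(window.outcome_end)
    in_scope = labs.loc[labs["lab_date"] <= cutoff]

    def last_value(kind: str) -> Optional[float]:
        sub = in_scope.loc[in_scope["kind"] == kind].sort_values("lab_date", kind="stable")
        if sub.empty:
            return None
        return float(sub["value"].iloc[-1])

    return classify_stage(last_value("cd4_count"), last_value("cd4_percent"), has_oi)


def ever_stage3(labs: pd.DataFrame, diagnoses: pd.DataFrame) -> bool:
    """True iff any CD4 < 200, CD4% < 14, or AIDS-defining OI, at any time."""
    counts = labs.loc[labs["kind"] == "cd4_count", "value"]
    percents = labs.loc[labs["kind"] == "cd4_percent", "value"]
    if (counts < 200).any() or (percents < 14).any():
        return True
    return bool((diagnoses["kind"] == OI_KIND).any())


def received_care(labs: pd.DataFrame, year: int) -> bool:
    """True iff >= 1 CD4 or VL lab dated within the calendar year (inclusive)."""
    start, end = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
    clinical = labs.loc[labs["kind"].isin(("cd4_count", "cd4_percent", "viral_load"))]
    return bool(((clinical["lab_date"] >= start) & (clinical["lab_date"] <= end)).any())


def suppression_indicators(
    labs: pd.DataFrame, window: StudyWindow
) -> tuple[bool, Optional[bool], bool]:
    """(ever_suppressed, suppressed_last_lab_of_outcome_year, suppressed_any_outcome_year).

    ``ever`` spans the suppression window; ``last_lab`` evaluates the
    chronologically last VL of the outcome year and is None when that
    year has no VL; ``any`` is true when any outcome-year VL is
    suppressed. The threshold (<= 200 copies/mL) is inclusive.
    """
    vl = labs.loc[labs["kind"] == "viral_load"].sort_values("lab_date", kind="stable")
    lo, hi = (pd.Timestamp(d) for d in window.suppression_window)
    in_window = vl.loc[(vl["lab_date"] >= lo) & (vl["lab_date"] <= hi)]
    ever = bool((in_window["value"] <= SUPPRESSION_THRESHOLD).any())

    ys, ye = pd.Timestamp(window.outcome_start), pd.Timestamp(window.outcome_end)
    in_year = vl.loc[(vl["lab_date"] >= ys) & (vl["lab_date"] <= ye)]
    if in_year.empty:
        last = None
        any_in_year = False
    else:
        last = bool(in_year["value"].iloc[-1] <= SUPPRESSION_THRESHOLD)
        any_in_year = bool((in_year["value"] <= SUPPRESSION_THRESHOLD).any())
    return ever, last, any_in_year


def time_to_suppression(labs: pd.DataFrame) -> tuple[Optional[float], Optional[str]]:
    """Months from the first detectable VL to the first subsequent suppressed VL.

    None when no detectable VL precedes the first suppressed one (e.g.
    the person's first-ever VL was already suppressed).
    """
    vl = labs.loc[labs["kind"] == "viral_load"].sort_values("lab_date", kind="stable")
    detectable = vl.loc[vl["value"] > SUPPRESSION_THRESHOLD]
    if detectable.empty:
        return None, None
    first_detectable = detectable["lab_date"].iloc[0]
    later_suppressed = vl.loc[
        (vl["lab_date"] >= first_detectable) & (vl["value"] <= SUPPRESSION_THRESHOLD)
    ]
    if later_suppressed.empty:
        return None, None
    days = (later_suppressed["lab_date"].iloc[0] - first_detectable).days
    months = days / DAYS_PER_MONTH
    category = "0-24" if months <= TTS_BOUNDARY_MONTHS else ">24"
    return months, category


def comorbidity_flags(
    diagnoses: pd.DataFrame, window: StudyWindow
) -> tuple[bool, bool, bool]:
    """(sti, hbv, hcv) flags: >= 1 qualifying event inside the closed lab window."""
    lo, hi = (pd.Timestamp(d) for d in window.lab_window)
    dated = diagnoses.loc[(diagnoses["event_date"] >= lo) & (diagnoses["event_date"] <= hi)]
    kinds = set(dated["kind"])
    return tuple(bool(kinds & COMORBIDITY_KINDS[flag]) for flag in ("sti", "hbv", "hcv"))


def derive_indicators_per_person(
    persons: pd.DataFrame,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Reference implementation: compose the per-person rule functions.

    Semantically identical to :func:`derive_indicators` (asserted by
    test) but loops over persons; use for small inputs and as the
    oracle for the vectorized path.
    """
    window = window or StudyWindow()
    labs_by_person = dict(tuple(labs.groupby("person_id")))
    dx_by_person = dict(tuple(diagnoses.groupby("person_id")))
    empty_labs = labs.iloc[0:0]
    empty_dx = diagnoses.iloc[0:0]

    rows = []
    for pid in persons["person_id"]:
        plabs = labs_by_person.get(pid, empty_labs)
        pdx = dx_by_person.get(pid, empty_dx)
        has_oi = bool((pdx["kind"] == OI_KIND).any())
        stage = stage_in_year(plabs, window, has_oi=has_oi)
        ever3 = ever_stage3(plabs, pdx)
        care = received_care(plabs, window.outcome_year)
        ever_supp, last_supp, any_supp = suppression_indicators(plabs, window)
        months, category = (None, None)
        if ever_supp:
            months, category = time_to_suppression(plabs)
        sti, hbv, hcv = comorbidity_flags(pdx, window)
        cd4 = plabs.loc[
            (plabs["kind"] == "cd4_count")
            & (plabs["lab_date"] <= pd.Timestamp(window.outcome_end))
        ].sort_values("lab_date", kind="stable")
        cd4_recent = float(cd4["value"].iloc[-1]) if not cd4.empty else np.nan
        rows.append(
            {
                "person_id": pid,
                "stage_2017": stage,
                "ever_stage3": ever3,
                "care_2017": care,
                "ever_suppressed_2011_2017": ever_supp,
                "suppressed_last_lab_2017": pd.NA if last_supp is None else last_supp,
                "suppressed_any_2017": any_supp,
                "tts_months": np.nan if months is None else months,
                "tts_category": category,
                "sti_2011_2016": sti,
                "hbv_2011_2016": hbv,
                "hcv_2011_2016": hcv,
                "cd4_recent": cd4_recent,
            }
        )
    out = pd.DataFrame(rows, columns=INDICATOR_COLUMNS)
    out["suppressed_last_lab_2017"] = out["suppressed_last_lab_2017"].astype("boolean")
    return out


def derive_indicators(
    persons: pd.DataFrame,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """One indicator row per person in ``persons`` (vectorized).

    ``suppressed_last_lab_2017`` is nullable boolean (pd.NA when the
    person has no outcome-year VL — not applicable rather than false).
    """
    window = window or StudyWindow()
    cutoff = pd.Timestamp(window.outcome_end)
    ys, ye = pd.Timestamp(window.outcome_start), cutoff
    slo, shi = (pd.Timestamp(d) for d in window.suppression_window)
    wlo, whi = (pd.Timestamp(d) for d in window.lab_window)

    idx = pd.Index(persons["person_id"], name="person_id")
    labs = labs.sort_values(["person_id", "lab_date"], kind="stable")
    cd4 = labs.loc[labs["kind"] == "cd4_count"]
    pct = labs.loc[labs["kind"] == "cd4_percent"]
    vl = labs.loc[labs["kind"] == "viral_load"]

    def last_value(frame: pd.DataFrame, date_cutoff) -> pd.Series:
        sub = frame.loc[frame["lab_date"] <= date_cutoff]
        return sub.groupby("person_id")["value"].last()

    cd4_recent = last_value(cd4, cutoff).reindex(idx)
    pct_recent = last_value(pct, cutoff).reindex(idx)
    has_oi = (
        diagnoses.loc[diagnoses["kind"] == OI_KIND].groupby("person_id").size() > 0
    ).reindex(idx, fill_value=False)

    # stage: OI forces 3; else count thresholds; else percent thresholds
    stage = np.select(
        [
            has_oi.to_numpy(),
            cd4_recent.notna() & (cd4_recent < 200),
            cd4_recent.notna() & (cd4_recent > 500),
            cd4_recent.notna(),
            pct_recent.notna() & (pct_recent < 14),
            pct_recent.notna() & (pct_recent >= 29),
            pct_recent.notna(),
        ],
        [3, 3, 1, 2, 3, 1, 2],
        default=0,
    )
    stage_col = pd.Series(stage, index=idx).map({0: "unknown", 1: 1, 2: 2, 3: 3})

    ever3 = (
        (cd4.groupby("person_id")["value"].min() < 200).reindex(idx, fill_value=False)
        | (pct.groupby("person_id")["value"].min() < 14).reindex(idx, fill_value=False)
        | has_oi
    )

    in_year = labs.loc[(labs["lab_date"] >= ys) & (labs["lab_date"] <= ye)]
    care = in_year.groupby("person_id").size().gt(0).reindex(idx, fill_value=False)

    vl_window = vl.loc[(vl["lab_date"] >= slo) & (vl["lab_date"] <= shi)]
    ever_supp = (
        (vl_window["value"] <= SUPPRESSION_THRESHOLD)
        .groupby(vl_window["person_id"]).any().reindex(idx, fill_value=False)
    )

    vl_year = vl.loc[(vl["lab_date"] >= ys) & (vl["lab_date"] <= ye)]
    any_supp = (
        (vl_year["value"] <= SUPPRESSION_THRESHOLD)
        .groupby(vl_year["person_id"]).any().reindex(idx, fill_value=False)
    )
    last_supp = (
        (vl_year.groupby("person_id")["value"].last() <= SUPPRESSION_THRESHOLD)
        .reindex(idx).astype("boolean")
    )

    # time to suppression: first detectable VL, then first suppressed VL on
    # or after it; only meaningful for ever-suppressed persons
    detectable = vl.loc[vl["value"] > SUPPRESSION_THRESHOLD]
    first_det = detectable.groupby("person_id")["lab_date"].min()
    vl_fd = vl.merge(first_det.rename("first_det"), on="person_id")
    supp_after = vl_fd.loc[
        (vl_fd["value"] <= SUPPRESSION_THRESHOLD) & (vl_fd["lab_date"] >= vl_fd["first_det"])
    ]
    first_supp = supp_after.groupby("person_id")["lab_date"].min()
    tts_days = (first_supp - first_det).dt.days
    tts_months = (tts_days / DAYS_PER_MONTH).reindex(idx)
    tts_months = tts_months.where(ever_supp, np.nan)
    tts_category = pd.Series(
        np.select(
            [tts_months.notna() & (tts_months <= TTS_BOUNDARY_MONTHS), tts_months.notna()],
            ["0-24", ">24"],
            default=None,
        ),
        index=idx, dtype=object,
    )

    dx_window = diagnoses.loc[
        (diagnoses["event_date"] >= wlo) & (diagnoses["event_date"] <= whi)
    ]
    flags = {}
    for name in ("sti", "hbv", "hcv"):
        hit = dx_window.loc[dx_window["kind"].isin(COMORBIDITY_KINDS[name])]
        flags[name] = hit.groupby("person_id").size().gt(0).reindex(idx, fill_value=False)

    out = pd.DataFrame(
        {
            "person_id": idx.to_numpy(),
            "stage_2017": stage_col.to_numpy(),
            "ever_stage3": ever3.to_numpy(),
            "care_2017": care.to_numpy(),
            "ever_suppressed_2011_2017": ever_supp.to_numpy(),
            "suppressed_last_lab_2017": last_supp.to_numpy(),
            "suppressed_any_2017": any_supp.to_numpy(),
            "tts_months": tts_months.to_numpy(),
            "tts_category": tts_category.to_numpy(),
            "sti_2011_2016": flags["sti"].to_numpy(),
            "hbv_2011_2016": flags["hbv"].to_numpy(),
            "hcv_2011_2016": flags["hcv"].to_numpy(),
            "cd4_recent": cd4_recent.to_numpy(),
        },
        columns=INDICATOR_COLUMNS,
    )
    out["suppressed_last_lab_2017"] = out["suppressed_last_lab_2017"].astype("boolean")
    return out
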