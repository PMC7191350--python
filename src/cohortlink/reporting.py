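"""Publication-style output tables for the group comparison.

Renders the demographic table (gender identity, race/ethnicity,
transmission risk, age, time since diagnosis, comorbidity flags), the
clinical-outcomes table (ever stage 3, care in the outcome year, CD4
categories, suppression measures, time-to-suppression categories), and
the adjusted prevalence-ratio table, with "<n> (<pct>)" cell formatting,
column percentages to one decimal (round-half-up), ratios to two
decimals, and p-values to three decimals (printed "<.001" below that).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from cohortlink.config import StudyWindow
from cohortlink.stats import (
    ContingencyTable,
    anova_continuous,
    build_table,
    column_percent,
    round_half_up,
)

GENDER_CATEGORIES = ("Male", "Female", "Transgender")
RACE_CATEGORIES = ("White", "Black", "Hispanic", "Other")
TRANSMISSION_CATEGORIES = (
    "MSM", "IDU", "MSM/IDU", "Heterosexual contact", "Perinatal", "Other", "Not identified",
)
CD4_CATEGORIES = ("<200", "200-500", ">500")
TTS_CATEGORIES = ("0-24", ">24")


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col.endswith("_n"):
            df[col] = df[col].astype("Int64")
    return df


def format_p(p: Optional[float]) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if p < 0.001:
        return "<.001"
    return f"{round_half_up(p, 3):.3f}".lstrip("0") or ".000"


def format_cell(count: int, pct: float) -> str:
    return f"{count} ({pct:.1f})"


def table_rows(table: ContingencyTable) -> list[dict]:
    """One formatted row per category: 'Male 3533 (68.0) 5818 (74.9)' style."""
    rows = []
    for cat in table.categories:
        row = {"variable": table.variable, "category": cat}
        for g in table.groups:
            row[f"{g}_n"] = int(table.counts.loc[cat, g])
            row[f"{g}_pct"] = float(table.column_percentages.loc[cat, g])
            row[f"{g}_cell"] = format_cell(row[f"{g}_n"], row[f"{g}_pct"])
        rows.append(row)
    if rows:
        rows[0]["p_value"] = format_p(table.p_value)
    return rows


def overall_share(n_cohort: int, n_non_cohort: int) -> float:
    """Cohort share of the combined population, percent to one decimal."""
    return column_percent(n_cohort, n_cohort + n_non_cohort)


def render_demographic_table(model_frame: pd.DataFrame) -> pd.DataFrame:
    """Demographics & comorbidities by group, with tests."""
    rows: list[dict] = []
    for variable, cats in (
        ("gender_identity", GENDER_CATEGORIES),
        ("race_ethnicity", RACE_CATEGORIES),
        ("transmission_risk", TRANSMISSION_CATEGORIES),
    ):
        rows.extend(table_rows(build_table(model_frame, variable, categories=cats)))

    cohort = model_frame.loc[model_frame["group"] == "cohort"]
    non = model_frame.loc[model_frame["group"] == "non_cohort"]
    for label, col in (
        ("age_years_median_iqr", "age_years"),
        ("years_since_diagnosis_mean_sd", "years_since_diagnosis"),
    ):
        a, b = cohort[col].dropna(), non[col].dropna()
        if len(a) > 1 and len(b) > 1:
            try:
                _, _, p = anova_continuous([a, b])
            except Exception:
                p = None
        else:
            p = None
        if label.endswith("median_iqr"):
            cell_a = f"{round_half_up(a.median(), 0):.0f} ({round_half_up(a.quantile(.75) - a.quantile(.25), 0):.0f})"
            cell_b = f"{round_half_up(b.median(), 0):.0f} ({round_half_up(b.quantile(.75) - b.quantile(.25), 0):.0f})"
        else:
            cell_a = f"{round_half_up(a.mean(), 1):.1f} ({round_half_up(a.std(), 1):.1f})"
            cell_b = f"{round_half_up(b.mean(), 1):.1f} ({round_half_up(b.std(), 1):.1f})"
        rows.append(
            {
                "variable": label, "category": "", "cohort_cell": cell_a,
                "non_cohort_cell": cell_b, "p_value": format_p(p),
            }
        )

    for flag in ("sti_2011_2016", "hbv_2011_2016", "hcv_2011_2016"):
        frame = model_frame.copy()
        frame[flag] = frame[flag].map({True: "yes", False: "no"})
        t = build_table(frame, flag, categories=("yes", "no"))
        row = {"variable": flag, "category": "yes"}
        for g in t.groups:
            row[f"{g}_n"] = int(t.counts.loc["yes", g])
            row[f"{g}_pct"] = float(t.column_percentages.loc["yes", g])
            row[f"{g}_cell"] = format_cell(row[f"{g}_n"], row[f"{g}_pct"])
        row["p_value"] = format_p(t.p_value)
        rows.append(row)
    return _finish(rows)


def render_clinical_table(model_frame: pd.DataFrame, window: StudyWindow | None = None) -> pd.DataFrame:
    """Clinical outcomes by group.

    Suppression in the outcome year is reported at the last lab (the
    stricter, trajectory-sensitive definition); the any-lab variant is
    exposed as its own row since the two definitions genuinely differ.
    """
    rows: list[dict] = []

    def binary_row(label: str, col: str) -> dict:
        frame = model_frame.loc[model_frame[col].notna()].copy()
        frame["_flag"] = frame[col].map(lambda v: "yes" if bool(v) else "no")
        t = build_table(frame, "_flag", categories=("yes", "no"))
        row = {"variable": label, "category": "yes"}
        for g in t.groups:
            # percentages over the full group denominator, not the non-missing subset
            denom = int((model_frame["group"] == g).sum())
            n = int(t.counts.loc["yes", g])
            row[f"{g}_n"] = n
            row[f"{g}_pct"] = column_percent(n, denom)
            row[f"{g}_cell"] = format_cell(n, row[f"{g}_pct"])
        row["p_value"] = format_p(t.p_value)
        return row

    rows.append(binary_row("ever_stage3", "ever_stage3"))
    rows.append(binary_row("care_2017", "care_2017"))

    # most recent CD4 count, categorized; denominators = persons with a CD4
    cd4 = model_frame.loc[model_frame["cd4_recent"].notna()].copy()
    if not cd4.empty:
        cd4["cd4_category"] = pd.cut(
            cd4["cd4_recent"], bins=[-np.inf, 199.999, 500, np.inf], labels=CD4_CATEGORIES
        ).astype(str)
        rows.extend(table_rows(build_table(cd4, "cd4_category", categories=CD4_CATEGORIES)))
        a = cd4.loc[cd4["group"] == "cohort", "cd4_recent"]
        b = cd4.loc[cd4["group"] == "non_cohort", "cd4_recent"]
        p = None
        if len(a) > 1 and len(b) > 1:
            try:
                _, _, p = anova_continuous([a, b])
            except Exception:
                p = None
        rows.append(
            {
                "variable": "cd4_recent_median_iqr", "category": "",
                "cohort_cell": f"{round_half_up(a.median(), 0):.0f} ({round_half_up(a.quantile(.75) - a.quantile(.25), 0):.0f})",
                "non_cohort_cell": f"{round_half_up(b.median(), 0):.0f} ({round_half_up(b.quantile(.75) - b.quantile(.25), 0):.0f})",
                "p_value": format_p(p),
            }
        )

    rows.append(binary_row("ever_suppressed_2011_2017", "ever_suppressed_2011_2017"))
    rows.append(binary_row("suppressed_last_lab_2017", "suppressed_last_lab_2017"))
    rows.append(binary_row("suppressed_any_2017", "suppressed_any_2017"))

    tts = model_frame.loc[model_frame["tts_category"].notna()]
    if not tts.empty:
        for row in table_rows(build_table(tts, "tts_category", categories=TTS_CATEGORIES)):
            # percentages over the full group denominators, matching the
            # published convention for this panel
            for g in ("cohort", "non_cohort"):
                denom = int((model_frame["group"] == g).sum())
                row[f"{g}_pct"] = column_percent(row[f"{g}_n"], denom)
                row[f"{g}_cell"] = format_cell(row[f"{g}_n"], row[f"{g}_pct"])
            rows.append(row)
    return _finish(rows)


def render_apr_table(model_results: pd.DataFrame) -> pd.DataFrame:
    """Adjusted prevalence ratios formatted '1.24 (1.21-1.28)'."""
    out = model_results.copy()

    def fmt(row) -> str:
        if not row["converged"] or row["apr"] is None or pd.isna(row["apr"]):
            return "not converged"
        return (
            f"{round_half_up(row['apr'], 2):.2f} "
            f"({round_half_up(row['ci_low'], 2):.2f}-{round_half_up(row['ci_high'], 2):.2f})"
        )

    out["apr_ci"] = out.apply(fmt, axis=1)
    return out[["model", "outcome", "apr_ci", "method", "n", "converged"]]
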