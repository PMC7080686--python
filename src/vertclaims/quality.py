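"""Claims-based quality indicators.

Five measures: all-cause 30-day readmission among hospitalized members, and
four HEDIS-style process measures — HbA1c testing, LDL testing and retinal
examination for members with diabetes, and screening mammography for women
aged 50–64.  The measurement window is the calendar year; events are detected
from procedure codes on claims, never from generator flags.
"""

from __future__ import annotations

import pandas as pd

from .codesets import QUALITY_CODES

READMIT_WINDOW_DAYS = 30  # "within 30 days" read as <= 30


class QualityError(ValueError):
    pass


def _merge_stays(stays: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping / same-day-transfer inpatient stays per member."""
    bad = stays["discharge_date"] < stays["admit_date"]
    if bad.any():
        raise QualityError(
            f"{int(bad.sum())} inpatient claim(s) with discharge before admission"
        )
    s = stays.sort_values(["member_id", "admit_date", "discharge_date"], kind="mergesort")
    merged_rows = []
    for member, grp in s.groupby("member_id", sort=False):
        cur_a = cur_d = None
        for a, d in zip(grp["admit_date"], grp["discharge_date"]):
            if cur_a is None:
                cur_a, cur_d = a, d
            elif a <= cur_d:  # overlap or transfer on the discharge day
                cur_d = max(cur_d, d)
            else:
                merged_rows.append((member, cur_a, cur_d))
                cur_a, cur_d = a, d
        merged_rows.append((member, cur_a, cur_d))
    return pd.DataFrame(merged_rows, columns=["member_id", "admit_date", "discharge_date"])


def readmissions(inpatient_claims: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """30-day all-cause readmission records, one per cohort member-year.

    Eligible member-years have at least one (merged) inpatient discharge in the
    year; the numerator is true when any later stay admits within the half-open
    interval (discharge, discharge + 30 days].
    """
    stays = inpatient_claims.dropna(subset=["admit_date", "discharge_date"])
    records = cohort[["member_id", "year"]].drop_duplicates().copy()
    records["measure"] = "readmit_30d"
    records["eligible"] = False
    records["numerator"] = False
    if len(stays) == 0:
        return records
    merged = _merge_stays(stays[["member_id", "admit_date", "discharge_date"]])
    merged["year"] = merged["discharge_date"].dt.year

    elig = set(map(tuple, merged[["member_id", "year"]].values))
    readmitted: set[tuple[str, int]] = set()
    for member, grp in merged.groupby("member_id", sort=False):
        admits = grp["admit_date"].values
        for _, row in grp.iterrows():
            d = row["discharge_date"]
            lim = d + pd.Timedelta(days=READMIT_WINDOW_DAYS)
            if ((admits > d.to_datetime64()) & (admits <= lim.to_datetime64())).any():
                readmitted.add((member, int(row["year"])))

    keys = list(map(tuple, records[["member_id", "year"]].values))
    records["eligible"] = [k in elig for k in keys]
    records["numerator"] = [k in readmitted for k in keys]
    return records


def diabetes_measures(
    claims: pd.DataFrame, cohort: pd.DataFrame,
    code_sets: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """HbA1c, LDL and retinal-exam records for members with diabetes.

    The diabetic denominator is any claim flagged with a diabetes diagnosis in
    the measurement year; numerators need at least one claim bearing a code
    from the measure's code set in the same year.
    """
    if code_sets is None:
        code_sets = QUALITY_CODES
    c = claims.copy()
    c["year"] = c["service_date"].dt.year
    keys = cohort[["member_id", "year"]].drop_duplicates()
    c = c.merge(keys, on=["member_id", "year"], how="inner")

    diabetic = set(
        map(tuple, c.loc[c["dx_diabetes"].astype(bool), ["member_id", "year"]].values)
    )
    out = []
    for measure in ("hba1c", "ldl", "retinal_exam"):
        codes = code_sets[measure]
        hit = set(map(tuple, c.loc[c["hcpcs"].isin(codes), ["member_id", "year"]].values))
        rec = keys.copy()
        rec["measure"] = measure
        k = list(map(tuple, rec[["member_id", "year"]].values))
        rec["eligible"] = [t in diabetic for t in k]
        rec["numerator"] = [t in diabetic and t in hit for t in k]
        out.append(rec)
    return pd.concat(out, ignore_index=True)


def mammography(
    claims: pd.DataFrame, cohort: pd.DataFrame,
    code_sets: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Screening mammography records for women aged 50–64."""
    if code_sets is None:
        code_sets = QUALITY_CODES
    rec = cohort[["member_id", "year", "sex", "age"]].drop_duplicates(["member_id", "year"]).copy()
    rec["measure"] = "mammography"
    rec["eligible"] = (rec["sex"] == "F") & (rec["age"] >= 50) & (rec["age"] <= 64)
    c = claims.copy()
    c["year"] = c["service_date"].dt.year
    hit = set(
        map(tuple, c.loc[c["hcpcs"].isin(code_sets["mammography"]), ["member_id", "year"]].values)
    )
    k = list(map(tuple, rec[["member_id", "year"]].values))
    rec["numerator"] = rec["eligible"].values & pd.Series([t in hit for t in k]).values
    return rec[["member_id", "year", "measure", "eligible", "numerator"]]


def quality_records(
    claims: pd.DataFrame, cohort: pd.DataFrame,
    code_sets: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """All five measures stacked; one record per member-year-measure."""
    inpat = claims[claims["setting"] == "inpatient_facility"]
    parts = [
        readmissions(inpat, cohort),
        diabetes_measures(claims, cohort, code_sets),
        mammography(claims, cohort, code_sets),
    ]
    cols = ["member_id", "year", "measure", "eligible", "numerator"]
    return pd.concat([p[cols] for p in parts], ignore_index=True)
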