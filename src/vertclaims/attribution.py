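"""Cohort filters and attribution of member-years to physician organizations.

A member-year enters the cohort if the member is 19–64, continuously enrolled,
and has at most $100,000 of raw (pre-standardization) annual allowed spending
(strictly greater is excluded).  Attribution then assigns each retained
member-year to the primary-care physician — and hence the organization —
accounting for the plurality of evaluation-and-management visits in a 24-month
window: the calendar year plus a symmetric flank of months on either side
(six by default, i.e. 1 July of the prior year through 30 June of the next).
Ties are broken by most recent visit date, then lexicographically smallest
PCP id.
"""

from __future__ import annotations

import pandas as pd

from .codesets import (
    COHORT_AGE_MAX,
    COHORT_AGE_MIN,
    PCP_SPECIALTIES,
    PRACTICE_SIZE_BOUNDS,
    SPEND_CAP_CENTS,
)


class AttributionError(ValueError):
    pass


def filter_cohort(
    members: pd.DataFrame, annual_spend_totals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the age / enrollment / spending-cap filters.

    Parameters
    ----------
    members : member-year table with age, continuously_enrolled.
    annual_spend_totals : frame with member_id, year, total_cents computed from
        raw claims; every member-year must be covered (zero-claim member-years
        carry an explicit zero).

    Returns (kept member-years, exclusion log with one reason per dropped row).
    Reasons are assigned with a fixed precedence (age, enrollment, cap) so they
    partition the dropped rows.
    """
    if len(members) == 0:
        return members.copy(), pd.DataFrame(columns=["member_id", "year", "exclusion_reason"])
    merged = members.merge(annual_spend_totals, on=["member_id", "year"], how="left")
    missing = merged[merged["total_cents"].isna()]
    if len(missing):
        ids = missing[["member_id", "year"]].head(20).to_records(index=False).tolist()
        raise AttributionError(
            f"missing precomputed spend totals for {len(missing)} member-year(s), e.g. {ids}"
        )
    age_bad = (merged["age"] < COHORT_AGE_MIN) | (merged["age"] > COHORT_AGE_MAX)
    enroll_bad = ~merged["continuously_enrolled"].astype(bool)
    cap_bad = merged["total_cents"] > SPEND_CAP_CENTS

    reason = pd.Series("none", index=merged.index, dtype=object)
    reason[cap_bad] = "spend_over_cap"
    reason[enroll_bad] = "not_continuously_enrolled"
    reason[age_bad] = "age_out_of_range"

    kept = members.loc[(reason == "none").values].copy()
    log = merged.loc[(reason != "none").values, ["member_id", "year"]].copy()
    log["exclusion_reason"] = reason[reason != "none"].values
    return kept, log.reset_index(drop=True)


def _pcp_visits(
    claims: pd.DataFrame, crosswalk: pd.DataFrame, pcp_specialties: frozenset[str]
) -> pd.DataFrame:
    """Professional evaluation-and-management claims rendered by a PCP."""
    cat = claims["hcpcs"].map(crosswalk.set_index("hcpcs")["betos_category"])
    mask = (
        (claims["setting"] == "professional")
        & claims["pcp_id"].notna()
        & claims["specialty"].isin(pcp_specialties)
        & (cat == "evaluation_management")
    )
    return claims.loc[mask, ["member_id", "pcp_id", "org_id", "service_date"]]


def attribute(
    members: pd.DataFrame,
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    pcp_specialties: frozenset[str] = PCP_SPECIALTIES,
    crosswalk: pd.DataFrame | None = None,
    flank_months: tuple[int, int] = (6, 6),
) -> pd.DataFrame:
    """Attribute each cohort member-year to one organization by visit plurality.

    Returns a frame with member_id, year, pcp_id, org_id, ownership,
    pcp_specialty and exclusion_reason ('none' or 'no_pcp_visits').
    """
    from .codesets import betos_crosswalk_frame

    if crosswalk is None:
        crosswalk = betos_crosswalk_frame()
    visits = _pcp_visits(claims, crosswalk, pcp_specialties)

    org_of_pcp = roster.drop_duplicates("pcp_id").set_index("pcp_id")["org_id"]
    orphans = sorted(set(visits["pcp_id"]) - set(org_of_pcp.index))
    if orphans:
        raise AttributionError(f"PCP id(s) on claims absent from roster: {orphans[:20]}")
    own_of_org = roster.drop_duplicates("org_id").set_index("org_id")["ownership"]

    results = []
    for year, myear in members.groupby("year"):
        start = pd.Timestamp(year, 1, 1) - pd.DateOffset(months=flank_months[0])
        end = pd.Timestamp(year, 12, 31) + pd.DateOffset(months=flank_months[1])
        inwin = visits[
            (visits["service_date"] >= start)
            & (visits["service_date"] <= end)
            & visits["member_id"].isin(myear["member_id"])
        ]
        if len(inwin):
            per_pcp = (
                inwin.groupby(["member_id", "pcp_id"])
                .agg(n_visits=("service_date", "size"), last_visit=("service_date", "max"))
                .reset_index()
            )
            # plurality; ties: most recent visit, then smallest pcp_id
            per_pcp = per_pcp.sort_values(
                ["member_id", "n_visits", "last_visit", "pcp_id"],
                ascending=[True, False, False, True],
                kind="mergesort",
            )
            winner = per_pcp.drop_duplicates("member_id", keep="first")
            # org of the winning PCP = org on that PCP's most recent in-window claim
            last_claim = (
                inwin.sort_values(["service_date", "org_id"], kind="mergesort")
                .drop_duplicates(["member_id", "pcp_id"], keep="last")
                .set_index(["member_id", "pcp_id"])["org_id"]
            )
            winner = winner.assign(
                org_id=last_claim.loc[
                    pd.MultiIndex.from_frame(winner[["member_id", "pcp_id"]])
                ].values
            )
        else:
            winner = pd.DataFrame(columns=["member_id", "pcp_id", "org_id"])
        res = myear[["member_id", "year"]].merge(
            winner[["member_id", "pcp_id", "org_id"]], on="member_id", how="left"
        )
        res["exclusion_reason"] = res["org_id"].map(lambda v: "none" if pd.notna(v) else "no_pcp_visits")
        results.append(res)
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame(
        columns=["member_id", "year", "pcp_id", "org_id", "exclusion_reason"]
    )
    out["ownership"] = out["org_id"].map(own_of_org)
    spec_of_visit = (
        claims.loc[claims["pcp_id"].notna(), ["pcp_id", "specialty"]]
        .drop_duplicates("pcp_id")
        .set_index("pcp_id")["specialty"]
    )
    out["pcp_specialty"] = out["pcp_id"].map(spec_of_visit)
    return out.sort_values(["member_id", "year"], kind="mergesort").reset_index(drop=True)


def attribution_table(
    members: pd.DataFrame,
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    annual_spend_totals: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Cohort filters + attribution, one row per input member-year.

    The exclusion reasons are mutually exclusive and, with 'none', exhaustive.
    """
    kept, log = filter_cohort(members, annual_spend_totals)
    attributed = attribute(kept, claims, roster, **kwargs)
    log = log.assign(pcp_id=None, org_id=None, ownership=None, pcp_specialty=None)
    cols = ["member_id", "year", "pcp_id", "org_id", "ownership", "pcp_specialty",
            "exclusion_reason"]
    full = pd.concat([attributed[cols], log[cols]], ignore_index=True)
    return full.sort_values(["member_id", "year"], kind="mergesort").reset_index(drop=True)


def practice_size_category(attribution: pd.DataFrame) -> pd.DataFrame:
    """Practice-size category per organization-year from attributed counts.

    Categories: 1 = up to 500 patients, 2 = 501–10,000, 3 = 10,001–15,000,
    4 = 15,001+ (boundaries closed as printed).
    """
    ok = attribution[attribution["exclusion_reason"] == "none"]
    counts = ok.groupby(["org_id", "year"]).size().rename("n_attributed").reset_index()
    counts["size_category"] = counts["n_attributed"].map(size_category)
    return counts


def size_category(n_attributed: int) -> int:
    """Practice-size category for an attributed patient count (0 counts as 1)."""
    b1, b2, b3 = PRACTICE_SIZE_BOUNDS
    if n_attributed <= b1:
        return 1
    if n_attributed <= b2:
        return 2
    if n_attributed <= b3:
        return 3
    return 4
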