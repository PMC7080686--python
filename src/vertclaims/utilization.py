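"""Claims-per-member rates and outpatient-setting shares for crosswalkable tests.

For each test family (chemistry, x-ray, CT, MRI, ultrasound) a claim is
"matched" when its professional CPT code or its outpatient revenue code
belongs to the family's crosswalk; claims carrying both are classified by
their setting field.  Rates are claims per attributed member; the outpatient
share is outpatient-matched / (outpatient-matched + professional-matched).
Rate differences use a two-sample z test on per-member counts; setting shares
use a two-proportion z test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .codesets import TEST_FAMILY_CROSSWALK


class UtilizationError(ValueError):
    pass


def validate_crosswalk(crosswalk: dict[str, dict[str, frozenset[str]]]) -> None:
    """Code sets must be disjoint across families (within each code system)."""
    for key in ("professional_codes", "outpatient_revenue_codes"):
        seen: dict[str, str] = {}
        for fam, entry in crosswalk.items():
            for code in entry[key]:
                if code in seen:
                    raise UtilizationError(
                        f"code {code} appears in both '{seen[code]}' and '{fam}'"
                    )
                seen[code] = fam


def match_claims(
    claims: pd.DataFrame,
    crosswalk: dict[str, dict[str, frozenset[str]]] | None = None,
) -> pd.DataFrame:
    """Matched claims with a ``family`` column; each claim in ≤1 family."""
    if crosswalk is None:
        crosswalk = TEST_FAMILY_CROSSWALK
    validate_crosswalk(crosswalk)
    fam = pd.Series(None, index=claims.index, dtype=object)
    for family, entry in crosswalk.items():
        prof = claims["hcpcs"].isin(entry["professional_codes"]) & (
            claims["setting"] == "professional"
        )
        fac = claims["revenue_code"].isin(entry["outpatient_revenue_codes"]) & (
            claims["setting"] == "outpatient_facility"
        )
        fam[prof | fac] = family
    out = claims.loc[fam.notna()].copy()
    out["family"] = fam[fam.notna()]
    return out


def _rate_test(counts1: np.ndarray, counts0: np.ndarray) -> float:
    """Two-sided z test of mean per-member counts (unequal variances)."""
    m1, m0 = counts1.mean(), counts0.mean()
    v = counts1.var(ddof=1) / len(counts1) + counts0.var(ddof=1) / len(counts0)
    if v <= 0:
        return 1.0 if m1 == m0 else 0.0
    z = (m1 - m0) / np.sqrt(v)
    return float(2 * stats.norm.sf(abs(z)))


def claims_per_member(
    claims: pd.DataFrame,
    attribution: pd.DataFrame,
    crosswalk: dict[str, dict[str, frozenset[str]]] | None = None,
) -> pd.DataFrame:
    """Matched claims per attributed member, by family × ownership group."""
    if crosswalk is None:
        crosswalk = TEST_FAMILY_CROSSWALK
    ok = attribution[attribution["exclusion_reason"] == "none"].copy()
    ok["group"] = np.where(ok["ownership"] == "physician_owned", "physician", "hospital")
    matched = match_claims(claims, crosswalk)
    matched["year"] = matched["service_date"].dt.year
    merged = matched.merge(
        ok[["member_id", "year", "group"]], on=["member_id", "year"], how="inner"
    )
    rows = []
    for family in crosswalk:
        rec: dict[str, object] = {"family": family}
        per_group_counts = {}
        for g in ("hospital", "physician"):
            members_g = ok.loc[ok["group"] == g, ["member_id", "year"]]
            n_members = len(members_g)
            rec[f"n_members_{g}"] = n_members
            if n_members == 0:
                rec[f"claims_per_member_{g}"] = np.nan
                continue
            fam_claims = merged[(merged["family"] == family) & (merged["group"] == g)]
            counts = (
                members_g.merge(
                    fam_claims.groupby(["member_id", "year"]).size().rename("k").reset_index(),
                    on=["member_id", "year"], how="left",
                )["k"].fillna(0).to_numpy()
            )
            per_group_counts[g] = counts
            rec[f"claims_per_member_{g}"] = float(counts.mean())
        if len(per_group_counts) == 2:
            rec["p_value"] = _rate_test(per_group_counts["hospital"], per_group_counts["physician"])
            rec["flag"] = ""
        else:
            rec["p_value"] = np.nan
            rec["flag"] = "empty_group"
        rows.append(rec)
    return pd.DataFrame(rows)


def percent_outpatient(
    claims: pd.DataFrame,
    attribution: pd.DataFrame,
    crosswalk: dict[str, dict[str, frozenset[str]]] | None = None,
) -> pd.DataFrame:
    """Percent of matched claims billed in the outpatient-facility setting."""
    from statsmodels.stats.proportion import proportions_ztest

    if crosswalk is None:
        crosswalk = TEST_FAMILY_CROSSWALK
    ok = attribution[attribution["exclusion_reason"] == "none"].copy()
    ok["group"] = np.where(ok["ownership"] == "physician_owned", "physician", "hospital")
    matched = match_claims(claims, crosswalk)
    matched["year"] = matched["service_date"].dt.year
    merged = matched.merge(
        ok[["member_id", "year", "group"]], on=["member_id", "year"], how="inner"
    )
    rows = []
    for family in crosswalk:
        rec: dict[str, object] = {"family": family}
        counts, nobs = [], []
        for g in ("hospital", "physician"):
            sub = merged[(merged["family"] == family) & (merged["group"] == g)]
            n_out = int((sub["setting"] == "outpatient_facility").sum())
            n_tot = len(sub)
            rec[f"pct_outpatient_{g}"] = 100.0 * n_out / n_tot if n_tot else np.nan
            rec[f"n_matched_{g}"] = n_tot
            counts.append(n_out)
            nobs.append(n_tot)
        if min(nobs) == 0:
            rec["p_value"] = np.nan
            rec["flag"] = "no_matched_claims"
        elif sum(counts) in (0, sum(nobs)):
            rec["p_value"] = 1.0
            rec["flag"] = ""
        else:
            _, p = proportions_ztest(counts, nobs, alternative="two-sided")
            rec["p_value"] = float(p)
            rec["flag"] = ""
        rows.append(rec)
    return pd.DataFrame(rows)


def utilization_table(
    claims: pd.DataFrame,
    attribution: pd.DataFrame,
    crosswalk: dict[str, dict[str, frozenset[str]]] | None = None,
) -> pd.DataFrame:
    """Combined per-family rates and outpatient shares by ownership group."""
    a = claims_per_member(claims, attribution, crosswalk)
    b = percent_outpatient(claims, attribution, crosswalk)
    return a.merge(b, on="family", suffixes=("_rate", "_setting"))
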