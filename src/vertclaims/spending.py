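"""Annual spending aggregation, BETOS/site decomposition and price standardization.

All arithmetic runs in integer cents so that the conservation identities
(total = Σ BETOS categories = Σ settings) are bit-exact.  Median-standardized
amounts are cents that may carry an exact .5 fraction (even-count medians);
0.5 is exactly representable, so standardized sums are still exact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codesets import BETOS_CATEGORIES, REVENUE_TO_BETOS, SETTINGS

logger = logging.getLogger(__name__)


class SpendingError(ValueError):
    pass


BETOS_COLS = [f"betos_{c}_cents" for c in BETOS_CATEGORIES]
SETTING_COLS = [f"setting_{s}_cents" for s in SETTINGS]
STD_BETOS_COLS = [f"std_betos_{c}_cents" for c in BETOS_CATEGORIES]


def categorize_claims(
    claims: pd.DataFrame,
    crosswalk: pd.DataFrame,
    revenue_map: dict[str, str] | None = None,
) -> pd.Series:
    """BETOS category per claim line.

    Professional claims map through the HCPCS crosswalk (unmapped codes fall to
    ``unclassified`` with a logged warning); facility claims without a HCPCS
    map through the revenue-code table, with unmapped revenue centers likewise
    falling to ``unclassified``.
    """
    if revenue_map is None:
        revenue_map = REVENUE_TO_BETOS
    xw = crosswalk.set_index("hcpcs")["betos_category"]
    cat = claims["hcpcs"].map(xw)
    no_hcpcs = claims["hcpcs"].isna()
    cat[no_hcpcs] = claims.loc[no_hcpcs, "revenue_code"].map(revenue_map)
    unmapped = cat.isna()
    if unmapped.any():
        bad = claims.loc[unmapped & ~no_hcpcs, "hcpcs"].dropna().unique()[:10]
        logger.warning(
            "%d claim(s) with unmapped codes assigned to 'unclassified' (e.g. %s)",
            int(unmapped.sum()), list(bad),
        )
        cat[unmapped] = "unclassified"
    return cat.astype(object)


def _claims_cents(claims: pd.DataFrame) -> np.ndarray:
    amt = claims["allowed_amount"].to_numpy(dtype=float)
    if (amt < 0).any():
        n = int((amt < 0).sum())
        raise SpendingError(f"{n} claim(s) with negative allowed_amount; adjustments unsupported")
    return np.round(amt * 100).astype(np.int64)


def raw_totals(claims: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Raw annual total cents per member-year (zero rows for claimless years).

    These pre-standardization totals feed the cohort spending-cap filter.
    """
    cents = _claims_cents(claims)
    t = (
        pd.DataFrame(
            {
                "member_id": claims["member_id"].values,
                "year": claims["service_date"].dt.year.values,
                "cents": cents,
            }
        )
        .groupby(["member_id", "year"], as_index=False)["cents"]
        .sum()
        .rename(columns={"cents": "total_cents"})
    )
    base = members[["member_id", "year"]].drop_duplicates()
    out = base.merge(t, on=["member_id", "year"], how="left")
    out["total_cents"] = out["total_cents"].fillna(0).astype(np.int64)
    return out


def _cohort_claims(claims: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    c = claims.copy()
    c["year"] = c["service_date"].dt.year
    keys = cohort[["member_id", "year"]].drop_duplicates()
    return c.merge(keys, on=["member_id", "year"], how="inner")


def aggregate(
    claims: pd.DataFrame, crosswalk: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """One wide AnnualSpend row per cohort member-year (integer cents).

    Claims of non-cohort member-years are ignored; members without claims get
    all-zero rows.  total = Σ BETOS = Σ setting holds exactly.
    """
    c = _cohort_claims(claims, cohort)
    c["cents"] = _claims_cents(c)
    c["betos"] = categorize_claims(c, crosswalk).values

    idx = cohort[["member_id", "year"]].drop_duplicates().set_index(["member_id", "year"]).index
    by_betos = (
        c.pivot_table(index=["member_id", "year"], columns="betos", values="cents",
                      aggfunc="sum", fill_value=0)
        .reindex(idx, fill_value=0)
        .reindex(columns=list(BETOS_CATEGORIES), fill_value=0)
        .astype(np.int64)
    )
    by_setting = (
        c.pivot_table(index=["member_id", "year"], columns="setting", values="cents",
                      aggfunc="sum", fill_value=0)
        .reindex(idx, fill_value=0)
        .reindex(columns=list(SETTINGS), fill_value=0)
        .astype(np.int64)
    )
    out = pd.DataFrame(index=idx)
    for cat in BETOS_CATEGORIES:
        out[f"betos_{cat}_cents"] = by_betos[cat]
    for s in SETTINGS:
        out[f"setting_{s}_cents"] = by_setting[s]
    out["total_cents"] = by_betos.sum(axis=1)
    assert (out["total_cents"].values == by_setting.sum(axis=1).values).all()
    return out.reset_index()


def build_median_prices(claims: pd.DataFrame, crosswalk: pd.DataFrame) -> pd.DataFrame:
    """Median allowed amount (cents) per BETOS category × year, pooled across
    ownership types; even-count medians are the mean of the central pair."""
    if len(claims) == 0:
        raise SpendingError("cannot build a median-price table from an empty claim set")
    c = claims.copy()
    c["year"] = c["service_date"].dt.year
    c["cents"] = _claims_cents(c)
    c["betos"] = categorize_claims(c, crosswalk).values
    table = (
        c.groupby(["betos", "year"])["cents"].median().rename("median_cents").reset_index()
    )
    return table.rename(columns={"betos": "betos_category"})


def standardize(
    claims: pd.DataFrame, table: pd.DataFrame, crosswalk: pd.DataFrame,
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Re-aggregate with each claim's price replaced by its category-year median.

    Claim counts are untouched, so two members with identical claim-count
    profiles get identical standardized totals regardless of their actual
    prices.  Standardized cents are exact multiples of 0.5.
    """
    c = _cohort_claims(claims, cohort)
    _claims_cents(c)  # validates non-negative amounts
    c["betos"] = categorize_claims(c, crosswalk).values
    med = table.set_index(["betos_category", "year"])["median_cents"]
    key = pd.MultiIndex.from_frame(c[["betos", "year"]])
    missing = ~key.isin(med.index)
    if missing.any():
        pairs = sorted(set(map(tuple, c.loc[missing, ["betos", "year"]].values)))[:10]
        raise SpendingError(f"median-price table missing category-year(s): {pairs}")
    c["std_cents"] = med.loc[key].values

    idx = cohort[["member_id", "year"]].drop_duplicates().set_index(["member_id", "year"]).index
    by_betos = (
        c.pivot_table(index=["member_id", "year"], columns="betos", values="std_cents",
                      aggfunc="sum", fill_value=0.0)
        .reindex(idx, fill_value=0.0)
        .reindex(columns=list(BETOS_CATEGORIES), fill_value=0.0)
    )
    out = pd.DataFrame(index=idx)
    for cat in BETOS_CATEGORIES:
        out[f"std_betos_{cat}_cents"] = by_betos[cat]
    out["std_total_cents"] = by_betos.sum(axis=1)
    return out.reset_index()


def annual_spend_table(
    claims: pd.DataFrame, crosswalk: pd.DataFrame, cohort: pd.DataFrame,
    median_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Actual + standardized AnnualSpend, and the median-price table used."""
    actual = aggregate(claims, crosswalk, cohort)
    if median_table is None:
        median_table = build_median_prices(_cohort_claims(claims, cohort), crosswalk)
    std = standardize(claims, median_table, crosswalk, cohort)
    return actual.merge(std, on=["member_id", "year"]), median_table


def positive_spending_shares(
    spend: pd.DataFrame, attribution: pd.DataFrame
) -> pd.DataFrame:
    """Share of members with positive spending per category, hospital-pooled
    vs physician-owned, with a two-sided two-proportion z-test per category."""
    from statsmodels.stats.proportion import proportions_ztest

    ok = attribution[attribution["exclusion_reason"] == "none"]
    merged = spend.merge(ok[["member_id", "year", "ownership"]], on=["member_id", "year"])
    merged["group"] = np.where(merged["ownership"] == "physician_owned", "physician", "hospital")
    rows = []
    cats = BETOS_COLS + SETTING_COLS + ["total_cents"]
    for col in cats:
        pos = merged[col] > 0
        rec: dict[str, object] = {"category": col.replace("_cents", "")}
        counts, nobs = [], []
        for g in ("hospital", "physician"):
            sel = merged["group"] == g
            n = int(sel.sum())
            rec[f"n_{g}"] = n
            rec[f"share_{g}"] = float(pos[sel].mean()) if n else np.nan
            counts.append(int(pos[sel].sum()))
            nobs.append(n)
        if min(nobs) == 0:
            rec["p_value"] = np.nan
            rec["flag"] = "empty_group"
        else:
            if counts[0] + counts[1] in (0, sum(nobs)):
                rec["p_value"] = 1.0  # no variation; difference trivially zero
            else:
                _, p = proportions_ztest(counts, nobs, alternative="two-sided")
                rec["p_value"] = float(p)
            rec["flag"] = ""
        rows.append(rec)
    return pd.DataFrame(rows)
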