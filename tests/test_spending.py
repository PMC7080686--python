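"""Spending aggregation, conservation, median prices and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertclaims.codesets import BETOS_CATEGORIES, betos_crosswalk_frame
from vertclaims.spending import (
    SpendingError,
    aggregate,
    build_median_prices,
    positive_spending_shares,
    standardize,
)
from conftest import make_claims

XW = betos_crosswalk_frame()
COHORT1 = pd.DataFrame({"member_id": ["M1"], "year": [2015]})


def test_two_claim_arithmetic():
    claims = make_claims(
        [
            {"hcpcs": "70450", "allowed_amount": 100.0},  # imaging
            {"hcpcs": "80048", "allowed_amount": 50.0},   # test
        ]
    )
    out = aggregate(claims, XW, COHORT1)
    row = out.iloc[0]
    assert row["total_cents"] == 15000
    assert row["betos_imaging_cents"] == 10000
    assert row["betos_test_cents"] == 5000


def test_zero_claim_member_gets_zero_row():
    claims = make_claims([{"member_id": "M2"}])
    out = aggregate(claims, XW, COHORT1)  # M1 has no claims
    assert len(out) == 1
    assert out.iloc[0]["total_cents"] == 0
    assert (out.filter(like="betos_").iloc[0] == 0).all()


def test_non_cohort_claims_ignored():
    claims = make_claims([{"member_id": "M2", "allowed_amount": 999.0},
                          {"member_id": "M1", "allowed_amount": 10.0}])
    out = aggregate(claims, XW, COHORT1)
    assert out["total_cents"].sum() == 1000


def test_negative_amount_errors():
    claims = make_claims([{"allowed_amount": -5.0}])
    with pytest.raises(SpendingError, match="negative"):
        aggregate(claims, XW, COHORT1)


def test_unmapped_hcpcs_goes_to_unclassified(caplog):
    claims = make_claims([{"hcpcs": "ZZZZZ", "allowed_amount": 42.0}])
    with caplog.at_level("WARNING"):
        out = aggregate(claims, XW, COHORT1)
    assert out.iloc[0]["betos_unclassified_cents"] == 4200
    assert out.iloc[0]["total_cents"] == 4200
    assert "unmapped" in caplog.text


def test_conservation_on_generated_data(small_study, small_data):
    attr, spend, *_ = small_study
    betos = spend[[f"betos_{c}_cents" for c in BETOS_CATEGORIES]].sum(axis=1)
    setting = spend.filter(like="setting_").sum(axis=1)
    assert (spend["total_cents"] == betos).all()
    assert (spend["total_cents"] == setting).all()
    # independent oracle: direct claim sum per cohort member-year
    c = small_data.claims.copy()
    c["year"] = c["service_date"].dt.year
    c["cents"] = np.round(c["allowed_amount"] * 100).astype(np.int64)
    cohort = set(zip(spend["member_id"], spend["year"]))
    mask = [k in cohort for k in zip(c["member_id"], c["year"])]
    assert spend["total_cents"].sum() == c.loc[mask, "cents"].sum()


class TestMedianPrices:
    def test_odd_count(self):
        claims = make_claims(
            [{"hcpcs": "70450", "allowed_amount": a} for a in (10, 20, 30)]
        )
        t = build_median_prices(claims, XW)
        assert t.set_index(["betos_category", "year"]).loc[("imaging", 2015), "median_cents"] == 2000

    def test_even_count_mean_of_central_pair(self):
        claims = make_claims(
            [{"hcpcs": "70450", "allowed_amount": a} for a in (10, 20)]
        )
        t = build_median_prices(claims, XW)
        assert t["median_cents"].iloc[0] == 1500

    def test_empty_errors(self):
        with pytest.raises(SpendingError, match="empty"):
            build_median_prices(make_claims([{}]).iloc[:0], XW)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=60))
    def test_matches_sort_oracle(self, cents):
        claims = make_claims(
            [{"hcpcs": "70450", "allowed_amount": c / 100} for c in cents]
        )
        t = build_median_prices(claims, XW)
        s = sorted(cents)
        n = len(s)
        oracle = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert t["median_cents"].iloc[0] == oracle


class TestStandardize:
    def test_fixed_point_when_prices_equal_median(self):
        claims = make_claims(
            [{"hcpcs": "70450", "allowed_amount": 25.0} for _ in range(3)]
        )
        t = build_median_prices(claims, XW)
        out = standardize(claims, t, XW, COHORT1)
        assert out.iloc[0]["std_total_cents"] == 7500

    def test_identical_count_profiles_identical_totals(self):
        cohort = pd.DataFrame({"member_id": ["M1", "M2"], "year": [2015, 2015]})
        claims = make_claims(
            [
                {"member_id": "M1", "hcpcs": "70450", "allowed_amount": 10.0},
                {"member_id": "M1", "hcpcs": "80048", "allowed_amount": 99.0},
                {"member_id": "M2", "hcpcs": "70450", "allowed_amount": 500.0},
                {"member_id": "M2", "hcpcs": "80048", "allowed_amount": 1.0},
            ]
        )
        t = build_median_prices(claims, XW)
        out = standardize(claims, t, XW, cohort).set_index("member_id")
        assert out.loc["M1", "std_total_cents"] == out.loc["M2", "std_total_cents"]

    def test_permuting_prices_within_category_year_is_invariant(self, small_data, small_study):
        attr, spend, med, _ = small_study
        cohort = spend[["member_id", "year"]]
        rng = np.random.default_rng(0)
        c = small_data.claims.copy()
        c["year"] = c["service_date"].dt.year
        from vertclaims.spending import categorize_claims

        c["betos"] = categorize_claims(c, small_data.crosswalk).values
        permuted = c.copy()
        for (cat, yr), grp in c.groupby(["betos", "year"]):
            permuted.loc[grp.index, "allowed_amount"] = rng.permutation(
                grp["allowed_amount"].values
            )
        out1 = standardize(small_data.claims, med, small_data.crosswalk, cohort)
        out2 = standardize(permuted.drop(columns=["year", "betos"]), med,
                           small_data.crosswalk, cohort)
        pd.testing.assert_frame_equal(out1, out2)

    def test_idempotent(self):
        claims = make_claims(
            [{"hcpcs": "70450", "allowed_amount": a} for a in (10.0, 30.0, 80.0)]
        )
        t1 = build_median_prices(claims, XW)
        once = standardize(claims, t1, XW, COHORT1)
        std_claims = claims.copy()
        std_claims["allowed_amount"] = t1["median_cents"].iloc[0] / 100
        t2 = build_median_prices(std_claims, XW)
        twice = standardize(std_claims, t2, XW, COHORT1)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_table_entry_errors(self):
        claims = make_claims([{"hcpcs": "70450"}])
        empty = pd.DataFrame({"betos_category": ["test"], "year": [2015],
                              "median_cents": [100.0]})
        with pytest.raises(SpendingError, match="imaging"):
            standardize(claims, empty, XW, COHORT1)


class TestPositiveShares:
    @staticmethod
    def _fixture(n=50, seed=5):
        rng = np.random.default_rng(seed)
        member_id = [f"M{i}" for i in range(n)]
        spend = pd.DataFrame({"member_id": member_id, "year": 2015})
        for c in BETOS_CATEGORIES:
            spend[f"betos_{c}_cents"] = rng.integers(0, 2, n) * rng.integers(1, 500, n)
        for s in ("professional", "outpatient_facility", "inpatient_facility"):
            spend[f"setting_{s}_cents"] = rng.integers(0, 2, n) * rng.integers(1, 500, n)
        spend["total_cents"] = spend.filter(like="betos_").sum(axis=1)
        attr = pd.DataFrame(
            {
                "member_id": member_id, "year": 2015,
                "ownership": np.where(rng.random(n) < 0.5, "physician_owned",
                                      "local_hospital_owned"),
                "exclusion_reason": "none",
            }
        )
        return spend, attr

    def test_matches_binomial_count_oracle(self):
        spend, attr = self._fixture()
        out = positive_spending_shares(spend, attr).set_index("category")
        merged = spend.merge(attr, on=["member_id", "year"])
        hosp = merged["ownership"] != "physician_owned"
        for c in BETOS_CATEGORIES:
            col = f"betos_{c}_cents"
            assert out.loc[f"betos_{c}", "share_hospital"] == pytest.approx(
                (merged.loc[hosp, col] > 0).mean()
            )
            assert out.loc[f"betos_{c}", "share_physician"] == pytest.approx(
                (merged.loc[~hosp, col] > 0).mean()
            )

    def test_all_positive_gives_share_one(self):
        spend, attr = self._fixture()
        spend["betos_imaging_cents"] = 100
        out = positive_spending_shares(spend, attr).set_index("category")
        assert out.loc["betos_imaging", "share_hospital"] == 1.0
        assert out.loc["betos_imaging", "share_physician"] == 1.0
        assert out.loc["betos_imaging", "p_value"] == 1.0

    def test_equal_shares_null(self):
        spend, attr = self._fixture()
        # force identical patterns in both groups => z statistic 0
        merged = spend.merge(attr, on=["member_id", "year"])
        spend["betos_test_cents"] = 0
        idx_h = merged.index[merged["ownership"] != "physician_owned"][:5]
        idx_p = merged.index[merged["ownership"] == "physician_owned"][:5]
        # not necessarily equal group sizes; use proportions directly
        nh = (merged["ownership"] != "physician_owned").sum()
        npy = len(merged) - nh
        spend.loc[merged.index[merged["ownership"] != "physician_owned"][: nh // 2],
                  "betos_test_cents"] = 100
        spend.loc[merged.index[merged["ownership"] == "physician_owned"][: npy // 2],
                  "betos_test_cents"] = 100
        out = positive_spending_shares(spend, attr).set_index("category")
        row = out.loc["betos_test"]
        if row["share_hospital"] == row["share_physician"]:
            assert row["p_value"] > 0.99

    def test_empty_group_flagged(self):
        spend, attr = self._fixture()
        attr["ownership"] = "physician_owned"
        out = positive_spending_shares(spend, attr)
        assert (out["flag"] == "empty_group").all()
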