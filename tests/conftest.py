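import numpy as np
import pandas as pd
import pytest

from vertclaims import SimConfig, generate
from vertclaims.attribution import attribution_table, practice_size_category
from vertclaims.estimation import assemble_analytic, build_design, fit_glm_log
from vertclaims.spending import annual_spend_table, raw_totals


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_members=300, seed=42)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def medium_config():
    return SimConfig(n_members=3000, years=(2015,), seed=123)


@pytest.fixture(scope="session")
def medium_data(medium_config):
    return generate(medium_config)


def run_study(data):
    """Attribution + spending aggregation for a generated dataset."""
    totals = raw_totals(data.claims, data.members)
    attr = attribution_table(data.members, data.claims, data.roster, totals)
    cohort = attr[attr["exclusion_reason"] == "none"][["member_id", "year"]]
    spend, med = annual_spend_table(data.claims, data.crosswalk, cohort)
    sizes = practice_size_category(attr)
    return attr, spend, med, sizes


@pytest.fixture(scope="session")
def medium_study(medium_data):
    return run_study(medium_data)


@pytest.fixture(scope="session")
def small_study(small_data):
    return run_study(small_data)


def fit_total_effect(cfg, standardized=False):
    """Full generate→attribute→aggregate→GLM path; returns effect estimate(s)."""
    data = generate(cfg)
    attr, spend, med, sizes = run_study(data)
    analytic = assemble_analytic(attr, spend, data.members, data.wage_index, sizes)
    analytic["total_dollars"] = analytic["total_cents"] / 100.0
    design = build_design(analytic, "total_dollars")
    est, _ = fit_glm_log(design)
    if not standardized:
        return est
    analytic["std_total_dollars"] = analytic["std_total_cents"] / 100.0
    est_std, _ = fit_glm_log(build_design(analytic, "std_total_dollars"))
    return est, est_std


def make_claims(rows):
    """Hand-built claims frame; rows are dicts with partial fields."""
    defaults = {
        "claim_id": None, "member_id": "M1", "service_date": "2015-06-01",
        "org_id": "OA", "pcp_id": None, "setting": "professional",
        "hcpcs": "99213", "revenue_code": None, "allowed_amount": 100.0,
        "specialty": "internal_medicine", "admit_date": None,
        "discharge_date": None, "dx_diabetes": False,
    }
    recs = []
    for i, r in enumerate(rows):
        rec = {**defaults, **r}
        if rec["claim_id"] is None:
            rec["claim_id"] = f"C{i:04d}"
        recs.append(rec)
    df = pd.DataFrame(recs, columns=list(defaults))
    for col in ("service_date", "admit_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_members(rows):
    defaults = {
        "member_id": "M1", "year": 2015, "age": 40, "sex": "F", "msa": "austin",
        "cdhp_flag": False, "risk_score": 1.0, "continuously_enrolled": True,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
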