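"""Synthetic claims generator with known ground-truth ownership effects.

The generator emulates the structure a claims-based spending/quality comparison
needs: members enrolled in one of several metropolitan areas, assigned to a
primary-care physician inside a physician organization of known ownership
type; per-member annual spending built bottom-up from claim counts (Poisson,
scaled by a lognormal concurrent risk score and an MSA×year level shift) and
per-claim prices (lognormal, with calendar-year price growth).  The hospital
ownership effect is multiplicative on expected spending: a configured share
``price_share`` of the log effect multiplies per-claim prices and the
remainder multiplies expected claim counts, which makes the downstream
price/utilization decomposition identifiable by construction.

Quality events (HbA1c, LDL, retinal-exam, mammography claims and 30-day
readmissions) are emitted as claims with real procedure / revenue codes, so
measure logic must find them the same way it would in production data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codesets import (
    BETOS_CATEGORIES,
    OWNERSHIP_TYPES,
    PCP_SPECIALTIES,
    QUALITY_CODES,
    TEST_FAMILY_CROSSWALK,
    betos_crosswalk_frame,
)
from .config import SimConfig

CLAIM_COLUMNS = [
    "claim_id", "member_id", "service_date", "org_id", "pcp_id", "setting",
    "hcpcs", "revenue_code", "allowed_amount", "specialty",
    "admit_date", "discharge_date", "dx_diabetes",
]

_PCP_SPECIALTY_LIST = sorted(PCP_SPECIALTIES)
_IMAGING_FAMILIES = ("xray", "ct", "mri", "ultrasound")
_IMAGING_FAMILY_P = (0.45, 0.20, 0.15, 0.20)
_FAMILY_REV = {
    "xray": "0320", "ct": "0350", "mri": "0610", "ultrasound": "0402",
    "chemistry": "0300",
}


@dataclass
class SimData:
    """In-memory bundle of every table the pipeline consumes."""

    members: pd.DataFrame
    roster: pd.DataFrame
    claims: pd.DataFrame
    crosswalk: pd.DataFrame
    wage_index: pd.DataFrame
    truth: pd.DataFrame


def _odds_shift(base: np.ndarray | float, odds_ratio: float) -> float | np.ndarray:
    """Probability obtained by multiplying the odds of ``base`` by ``odds_ratio``."""
    base = np.asarray(base, dtype=float)
    odds = base / np.clip(1.0 - base, 1e-12, None)
    shifted = odds * odds_ratio
    return np.where(base >= 1.0, 1.0, shifted / (1.0 + shifted))


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Lognormal draws with expected value ``mean``."""
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size)


def _build_orgs(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = {
        "physician_owned": cfg.n_phys_orgs,
        "local_hospital_owned": cfg.n_hosp_local_orgs,
        "multi_hospital_system_owned": cfg.n_hosp_system_orgs,
    }
    pcps_per_org = {
        "physician_owned": 3,
        "local_hospital_owned": 8,
        "multi_hospital_system_owned": 14,
    }
    org_rows, pcp_rows = [], []
    org_i = pcp_i = 0
    for own in OWNERSHIP_TYPES:
        for j in range(counts[own]):
            org_id = f"O{org_i:04d}"
            msa = cfg.msas[j % len(cfg.msas)]
            org_rows.append((org_id, own, msa))
            for _ in range(pcps_per_org[own]):
                pcp_rows.append((f"P{pcp_i:05d}", org_id))
                pcp_i += 1
            org_i += 1
    orgs = pd.DataFrame(org_rows, columns=["org_id", "ownership", "msa"])
    pcps = pd.DataFrame(pcp_rows, columns=["pcp_id", "org_id"])
    return orgs, pcps


def generate(config: SimConfig) -> SimData:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    cfg = config.validate()
    streams = np.random.SeedSequence(int(cfg.seed)).spawn(5)
    r_mem, r_org, r_clm, r_qual, r_inp = (np.random.default_rng(s) for s in streams)

    years = list(cfg.years)
    y0 = years[0]
    msas = list(cfg.msas)
    n = cfg.n_members

    orgs, pcps = _build_orgs(cfg)
    pcp_spec = pd.Series(
        r_org.choice(_PCP_SPECIALTY_LIST, size=len(pcps)), index=pcps["pcp_id"].values
    )

    # ---------------------------------------------------------------- members
    member_id = np.array([f"M{i:07d}" for i in range(n)])
    if cfg.msa_weights is not None:
        msa_p = np.asarray(cfg.msa_weights, dtype=float)
    else:  # uneven metro populations by default
        msa_p = np.arange(2.0, 2.0 + len(msas))
    msa_p = msa_p / msa_p.sum()
    msa = r_mem.choice(msas, size=n, p=msa_p)
    sex = np.where(r_mem.random(n) < 0.52, "F", "M")
    cdhp = r_mem.random(n) < cfg.cdhp_prob
    diabetic = r_mem.random(n) < cfg.diabetes_prev
    age0 = r_mem.integers(19, 65, size=n)

    own_idx = r_mem.choice(3, size=n, p=list(cfg.ownership_member_shares))
    ownership = np.array(OWNERSHIP_TYPES)[own_idx]
    org_of_member = np.empty(n, dtype=object)
    for m in msas:
        in_msa = msa == m
        for own in OWNERSHIP_TYPES:
            sel = in_msa & (ownership == own)
            if not sel.any():
                continue
            cand = orgs.loc[(orgs["msa"] == m) & (orgs["ownership"] == own), "org_id"].values
            if len(cand) == 0:  # fall back to any org in the MSA
                cand = orgs.loc[orgs["msa"] == m, "org_id"].values
            # right-skewed organization sizes (rank-weighted choice)
            w = (1.0 + np.arange(len(cand))) ** cfg.org_size_skew
            org_of_member[sel] = r_mem.choice(cand, size=int(sel.sum()), p=w / w.sum())
    own_of_org = orgs.set_index("org_id")["ownership"]
    ownership = own_of_org.loc[org_of_member].values  # after fallback
    pcp_of_member = np.empty(n, dtype=object)
    pcp_by_org = pcps.groupby("org_id")["pcp_id"].apply(list)
    for org_id, idx in pd.Series(np.arange(n)).groupby(pd.Series(org_of_member)):
        plist = pcp_by_org[org_id]
        pcp_of_member[idx.values] = np.array(plist, dtype=object)[
            r_mem.integers(0, len(plist), size=len(idx))
        ]

    # ------------------------------------------------------------ member-years
    ny = len(years)
    my = pd.DataFrame(
        {
            "member_id": np.repeat(member_id, ny),
            "year": np.tile(years, n),
            "msa": np.repeat(msa, ny),
            "sex": np.repeat(sex, ny),
            "cdhp_flag": np.repeat(cdhp, ny),
            "diabetic": np.repeat(diabetic, ny),
            "org_id": np.repeat(org_of_member, ny),
            "ownership": np.repeat(ownership, ny),
            "pcp_id": np.repeat(pcp_of_member, ny),
        }
    )
    my["age"] = np.repeat(age0, ny) + (my["year"].values - y0)
    my["pcp_specialty"] = pcp_spec.loc[my["pcp_id"].values].values
    my["continuously_enrolled"] = r_mem.random(len(my)) < cfg.enroll_prob
    is_hosp = (my["ownership"] != "physician_owned").values

    rd = cfg.risk_distribution
    mu = np.log(rd["mean"]) - 0.5 * rd["sigma"] ** 2 + cfg.risk_ownership_corr * is_hosp
    my["risk_score"] = np.exp(r_mem.normal(mu, rd["sigma"], size=len(my)))

    msa_i = pd.Series(np.arange(len(msas)), index=msas)
    shift = cfg.msa_year_shift_scale * (
        ((msa_i.loc[my["msa"]].values + (my["year"].values - y0)) % 3) - 1
    )
    e = cfg.ownership_log_effect
    u_mult = np.where(is_hosp, np.exp((1.0 - cfg.price_share) * e), 1.0)
    p_mult = np.where(is_hosp, np.exp(cfg.price_share * e), 1.0)
    util_base = my["risk_score"].values * np.exp(shift) * u_mult
    infl = (1.0 + cfg.annual_price_growth) ** (my["year"].values - y0)

    # ------------------------------------------------------------ claim streams
    nrow = len(my)
    parts: list[pd.DataFrame] = []

    def _emit(idx, *, stream, setting, amount, hcpcs=None, revenue=None,
              specialty="other", day=None, pcp=False, admit=None, discharge=None):
        k = len(idx)
        if k == 0:
            return
        df = pd.DataFrame(
            {
                "row": idx,
                "stream": stream,
                "setting": setting,
                "hcpcs": hcpcs if hcpcs is not None else np.full(k, None, dtype=object),
                "revenue_code": revenue if revenue is not None else np.full(k, None, dtype=object),
                "allowed_amount": np.round(amount, 2),
                "specialty": specialty,
                "service_day": day if day is not None else r_clm.integers(0, 365, size=k),
                "is_pcp": pcp,
                "admit_day": admit if admit is not None else np.full(k, -1),
                "discharge_day": discharge if discharge is not None else np.full(k, -1),
            }
        )
        parts.append(df)

    mix = cfg.betos_mix

    # evaluation & management: guaranteed >=1 visit to the member's own PCP so
    # attribution is always possible; expectation preserved via the 1+Poisson(λ-1)
    # construction except for the (rare) clamp at λ < 1.
    lam_em = mix["evaluation_management"]["rate"] * util_base
    n_em = 1 + r_clm.poisson(np.maximum(lam_em - 1.0, 0.0))
    em_idx = np.repeat(np.arange(nrow), n_em)
    em_codes = sorted(
        c for c, cat in betos_crosswalk_frame().values if cat == "evaluation_management"
    )
    _emit(
        em_idx, stream=0, setting="professional",
        amount=_lognormal_mean(r_clm, 1.0, mix["evaluation_management"]["price_sigma"], len(em_idx))
        * mix["evaluation_management"]["price_mean"] * infl[em_idx] * p_mult[em_idx],
        hcpcs=r_clm.choice(em_codes, size=len(em_idx)),
        specialty=my["pcp_specialty"].values[em_idx],
        pcp=True,
    )

    def _simple_stream(cat, stream, codes, specialty, route_prob=None, family=None):
        lam = mix[cat]["rate"] * util_base
        cnt = r_clm.poisson(lam)
        idx = np.repeat(np.arange(nrow), cnt)
        if len(idx) == 0:
            return
        amt = (
            _lognormal_mean(r_clm, 1.0, mix[cat]["price_sigma"], len(idx))
            * mix[cat]["price_mean"] * infl[idx] * p_mult[idx]
        )
        if family is not None:  # imaging: pick a modality family per claim
            fam = r_clm.choice(_IMAGING_FAMILIES, size=len(idx), p=_IMAGING_FAMILY_P)
        if route_prob is not None:
            route_p = np.where(is_hosp[idx],
                               cfg.outpatient_routing["hospital"],
                               cfg.outpatient_routing["physician_owned"])
            routed = r_clm.random(len(idx)) < route_p
        else:
            routed = np.zeros(len(idx), dtype=bool)
        # professional lines carry a HCPCS; routed lines become facility claims
        # identified by revenue center only.
        if family is not None:
            code_arr = np.empty(len(idx), dtype=object)
            rev_arr = np.empty(len(idx), dtype=object)
            for f in _IMAGING_FAMILIES:
                fsel = fam == f
                fam_codes = sorted(TEST_FAMILY_CROSSWALK[f]["professional_codes"])
                code_arr[fsel] = np.array(fam_codes, dtype=object)[
                    r_clm.integers(0, len(fam_codes), size=int(fsel.sum()))
                ]
                rev_arr[fsel] = _FAMILY_REV[f]
        else:
            code_arr = r_clm.choice(codes, size=len(idx)).astype(object)
            rev_arr = np.full(len(idx), _FAMILY_REV.get("chemistry"), dtype=object)
        hcpcs = np.where(routed, None, code_arr)
        revenue = np.where(routed, rev_arr, None)
        setting = np.where(routed, "outpatient_facility", "professional")
        df_idx = idx
        _emit(df_idx, stream=stream, setting=setting, amount=amt,
              hcpcs=hcpcs, revenue=revenue, specialty=specialty)

    proc_codes = sorted(c for c, cat in betos_crosswalk_frame().values if cat == "procedures")
    _simple_stream("procedures", 1, proc_codes, "surgery")
    _simple_stream("imaging", 2, None, "radiology",
                   route_prob=True, family=True)
    chem_codes = sorted(TEST_FAMILY_CROSSWALK["chemistry"]["professional_codes"] - {"80061", "83036"})
    _simple_stream("test", 3, chem_codes, "pathology", route_prob=True)
    dme_codes = sorted(c for c, cat in betos_crosswalk_frame().values
                       if cat == "durable_medical_equipment")
    _simple_stream("durable_medical_equipment", 4, dme_codes, "dme_supplier")

    # "other": mostly professional therapy/psych; ~10% emergency-room facility lines
    lam_o = mix["other"]["rate"] * util_base
    cnt_o = r_clm.poisson(lam_o)
    idx_o = np.repeat(np.arange(nrow), cnt_o)
    if len(idx_o):
        amt_o = (_lognormal_mean(r_clm, 1.0, mix["other"]["price_sigma"], len(idx_o))
                 * mix["other"]["price_mean"] * infl[idx_o] * p_mult[idx_o])
        er = r_clm.random(len(idx_o)) < 0.10
        other_codes = np.array(["97110", "97140", "90837", "94010", "95810"], dtype=object)
        _emit(idx_o, stream=5,
              setting=np.where(er, "outpatient_facility", "professional"),
              amount=amt_o,
              hcpcs=np.where(er, None, other_codes[r_clm.integers(0, len(other_codes), len(idx_o))]),
              revenue=np.where(er, "0450", None),
              specialty=np.where(er, "emergency", "therapy"))

    # unclassified: operating/recovery-room facility lines (no HCPCS)
    lam_u = mix["unclassified"]["rate"] * util_base
    cnt_u = r_clm.poisson(lam_u)
    idx_u = np.repeat(np.arange(nrow), cnt_u)
    if len(idx_u):
        rev_u = np.array(["0360", "0370", "0710"], dtype=object)
        _emit(idx_u, stream=6, setting="outpatient_facility",
              amount=_lognormal_mean(r_clm, 1.0, mix["unclassified"]["price_sigma"], len(idx_u))
              * mix["unclassified"]["price_mean"] * infl[idx_u] * p_mult[idx_u],
              revenue=rev_u[r_clm.integers(0, 3, len(idx_u))],
              specialty="facility")

    # ------------------------------------------------------- inpatient stays
    p_index = np.clip(cfg.inpatient_rate * util_base, 0.0, 0.95)
    has_index = r_inp.random(nrow) < p_index
    inp_rows = np.flatnonzero(has_index)
    if len(inp_rows):
        admit = r_inp.integers(0, 241, size=len(inp_rows))
        los = 1 + np.minimum(r_inp.poisson(2, size=len(inp_rows)), 13)
        disch = admit + los
        amt = (_lognormal_mean(r_inp, 1.0, cfg.inpatient_price_sigma, len(inp_rows))
               * cfg.inpatient_price_mean * infl[inp_rows] * p_mult[inp_rows])
        _emit(inp_rows, stream=7, setting="inpatient_facility", amount=amt,
              revenue=np.full(len(inp_rows), "0100", dtype=object),
              specialty="hospital", day=admit, admit=admit, discharge=disch)

        qr = cfg.quality_rates["readmit_30d"]
        p_re = np.where(is_hosp[inp_rows],
                        _odds_shift(qr["base"], qr["hospital_odds_ratio"]), qr["base"])
        readmit = r_inp.random(len(inp_rows)) < p_re
        re_rows = inp_rows[readmit]
        if len(re_rows):
            gap = r_inp.integers(1, 31, size=len(re_rows))
            admit2 = disch[readmit] + gap
            los2 = 1 + np.minimum(r_inp.poisson(2, size=len(re_rows)), 13)
            amt2 = 0.8 * (_lognormal_mean(r_inp, 1.0, cfg.inpatient_price_sigma, len(re_rows))
                          * cfg.inpatient_price_mean * infl[re_rows] * p_mult[re_rows])
            _emit(re_rows, stream=8, setting="inpatient_facility", amount=amt2,
                  revenue=np.full(len(re_rows), "0100", dtype=object),
                  specialty="hospital", day=admit2, admit=admit2,
                  discharge=admit2 + los2)
        # occasional later stay well beyond the 30-day boundary (never a readmission)
        late = (~readmit) & (r_inp.random(len(inp_rows)) < cfg.late_stay_prob)
        lt_rows = inp_rows[late]
        if len(lt_rows):
            gap = r_inp.integers(40, 91, size=len(lt_rows))
            admit3 = disch[late] + gap
            los3 = 1 + np.minimum(r_inp.poisson(2, size=len(lt_rows)), 13)
            amt3 = 0.8 * (_lognormal_mean(r_inp, 1.0, cfg.inpatient_price_sigma, len(lt_rows))
                          * cfg.inpatient_price_mean * infl[lt_rows] * p_mult[lt_rows])
            _emit(lt_rows, stream=9, setting="inpatient_facility", amount=amt3,
                  revenue=np.full(len(lt_rows), "0100", dtype=object),
                  specialty="hospital", day=admit3, admit=admit3,
                  discharge=admit3 + los3)

    # ------------------------------------------------------- quality claims
    diab_rows = np.flatnonzero(my["diabetic"].values)
    q_streams = {
        "hba1c": (10, sorted(QUALITY_CODES["hba1c"])[0], 15.0, "pathology"),
        "ldl": (11, sorted(QUALITY_CODES["ldl"])[0], 20.0, "pathology"),
        "retinal_exam": (12, sorted(QUALITY_CODES["retinal_exam"])[0], 80.0, "ophthalmology"),
    }
    for measure, (stream, code, price, spec) in q_streams.items():
        qr = cfg.quality_rates[measure]
        p = np.where(is_hosp[diab_rows],
                     _odds_shift(qr["base"], qr["hospital_odds_ratio"]), qr["base"])
        hit = diab_rows[r_qual.random(len(diab_rows)) < p]
        if len(hit):
            _emit(hit, stream=stream, setting="professional",
                  amount=price * infl[hit] * np.ones(len(hit)),
                  hcpcs=np.full(len(hit), code, dtype=object), specialty=spec)

    mam_rows = np.flatnonzero(
        (my["sex"].values == "F") & (my["age"].values >= 50) & (my["age"].values <= 64)
    )
    qr = cfg.quality_rates["mammography"]
    p = np.where(is_hosp[mam_rows], _odds_shift(qr["base"], qr["hospital_odds_ratio"]), qr["base"])
    hit = mam_rows[r_qual.random(len(mam_rows)) < p]
    if len(hit):
        _emit(hit, stream=13, setting="professional",
              amount=150.0 * infl[hit] * np.ones(len(hit)),
              hcpcs=np.full(len(hit), sorted(QUALITY_CODES["mammography"])[0], dtype=object),
              specialty="radiology")

    # ---------------------------------------------------------- finalize claims
    claims = pd.concat(parts, ignore_index=True)
    claims = claims.sort_values(
        ["row", "service_day", "stream"], kind="mergesort"
    ).reset_index(drop=True)
    row = claims["row"].values
    claims["member_id"] = my["member_id"].values[row]
    claims["org_id"] = my["org_id"].values[row]
    yr = my["year"].values[row]
    base = (yr - 1970).astype("datetime64[Y]").astype("datetime64[D]")
    claims["service_date"] = pd.to_datetime(base + claims["service_day"].values.astype("timedelta64[D]"))
    has_stay = claims["admit_day"].values >= 0
    admit_dates = pd.Series(pd.NaT, index=claims.index, dtype="datetime64[ns]")
    disch_dates = pd.Series(pd.NaT, index=claims.index, dtype="datetime64[ns]")
    admit_dates[has_stay] = pd.to_datetime(
        base[has_stay] + claims.loc[has_stay, "admit_day"].values.astype("timedelta64[D]")
    )
    disch_dates[has_stay] = pd.to_datetime(
        base[has_stay] + claims.loc[has_stay, "discharge_day"].values.astype("timedelta64[D]")
    )
    claims["admit_date"] = admit_dates
    claims["discharge_date"] = disch_dates
    claims["pcp_id"] = np.where(claims["is_pcp"].values, my["pcp_id"].values[row], None)
    diabetic_row = my["diabetic"].values[row]
    claims["dx_diabetes"] = diabetic_row & (
        claims["is_pcp"].values | claims["stream"].isin([10, 11, 12]).values
    )
    claims["claim_id"] = [f"C{i:08d}" for i in range(len(claims))]
    claims = claims[CLAIM_COLUMNS + ["row"]]

    # ------------------------------------------------------------ side tables
    members = my[
        ["member_id", "year", "age", "sex", "msa", "cdhp_flag", "risk_score",
         "continuously_enrolled"]
    ].copy()

    roster = (
        pcps.merge(orgs, on="org_id")[["org_id", "ownership", "msa", "pcp_id"]]
        .sort_values(["org_id", "pcp_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    wage_rows = []
    for i, m in enumerate(msas):
        for y in years:
            w = 0.92 + 0.03 * i + 0.005 * (y - y0) * (1 if i % 2 == 0 else -1)
            wage_rows.append((m, y, round(w, 4)))
    wage_index = pd.DataFrame(wage_rows, columns=["msa", "year", "wage_index"])

    cents = np.round(claims["allowed_amount"].values * 100).astype(np.int64)
    truth = (
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
    truth = truth.merge(
        my[["member_id", "year", "org_id", "ownership", "pcp_id"]],
        on=["member_id", "year"], how="left",
    )

    claims = claims.drop(columns=["row"])
    return SimData(members, roster, claims, crosswalk=betos_crosswalk_frame(),
                   wage_index=wage_index, truth=truth)


# ---------------------------------------------------------------------- I/O

def write_dataset(
    members: pd.DataFrame,
    roster: pd.DataFrame,
    claims: pd.DataFrame,
    crosswalk: pd.DataFrame,
    wage_index: pd.DataFrame,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the delimited-file dataset; refuses empty collections."""
    for name, df in (("members", members), ("roster", roster), ("claims", claims),
                     ("crosswalk", crosswalk), ("wage_index", wage_index)):
        if df is None or len(df) == 0:
            raise ValueError(f"refusing to write empty {name} table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    m = members.copy()
    m["risk_score"] = m["risk_score"].map(lambda v: f"{v:.6f}")
    paths["members"] = out / "members.csv"
    m.to_csv(paths["members"], index=False)

    c = claims.copy()
    for col in ("service_date", "admit_date", "discharge_date"):
        c[col] = pd.to_datetime(c[col]).dt.strftime("%Y-%m-%d")
    c["allowed_amount"] = c["allowed_amount"].map(lambda v: f"{v:.2f}")
    paths["claims"] = out / "claims.csv"
    c.to_csv(paths["claims"], index=False)

    paths["roster"] = out / "roster.csv"
    roster.to_csv(paths["roster"], index=False)
    paths["crosswalk"] = out / "betos_crosswalk.csv"
    crosswalk.to_csv(paths["crosswalk"], index=False)
    w = wage_index.copy()
    w["wage_index"] = w["wage_index"].map(lambda v: f"{v:.4f}")
    paths["wage_index"] = out / "wage_index.csv"
    w.to_csv(paths["wage_index"], index=False)
    if truth is not None and len(truth):
        paths["truth"] = out / "truth.csv"
        truth.to_csv(paths["truth"], index=False)
    return paths


def read_dataset(in_dir: str | Path) -> SimData:
    """Read a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    members = pd.read_csv(d / "members.csv", dtype={"member_id": str, "msa": str, "sex": str})
    claims = pd.read_csv(
        d / "claims.csv",
        dtype={
            "claim_id": str, "member_id": str, "org_id": str, "pcp_id": str,
            "setting": str, "hcpcs": str, "revenue_code": str, "specialty": str,
        },
        parse_dates=["service_date", "admit_date", "discharge_date"],
    )
    claims["hcpcs"] = claims["hcpcs"].where(claims["hcpcs"].notna(), None)
    claims["revenue_code"] = claims["revenue_code"].where(claims["revenue_code"].notna(), None)
    claims["pcp_id"] = claims["pcp_id"].where(claims["pcp_id"].notna(), None)
    roster = pd.read_csv(d / "roster.csv", dtype=str)
    crosswalk = pd.read_csv(d / "betos_crosswalk.csv", dtype=str)
    wage_index = pd.read_csv(d / "wage_index.csv", dtype={"msa": str})
    truth_path = d / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return SimData(members, roster, claims, crosswalk, wage_index, truth)
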