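"""End-to-end pipeline orchestration and table rendering.

``run_pipeline`` executes simulate → attribute → aggregate → quality →
estimate → report, writes the four analysis tables (descriptives; adjusted
spending differences overall / by BETOS category / by setting; claims-per-
member comparison; quality odds ratios) plus the stage output files and a run
manifest.  Every number in a rendered table is recomputable from the stage
output files; the renderer only formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import attribution_table, practice_size_category
from .codesets import BETOS_CATEGORIES, OWNERSHIP_TYPES, QUALITY_MEASURES, SETTINGS
from .config import SimConfig
from .estimation import (
    EstimationError,
    SeparationError,
    assemble_analytic,
    build_design,
    fit_glm_log,
    fit_linear_dollars,
    fit_logistic_quality,
    price_utilization_decomposition,
)
from .quality import quality_records
from .simulate import generate, write_dataset
from .spending import annual_spend_table, positive_spending_shares, raw_totals
from .utilization import utilization_table

logger = logging.getLogger(__name__)

MIN_ELIGIBLE_FOR_LOGIT = 50


def patients_per_org(n_patients: int, n_orgs: int) -> int:
    """Mean attributed patients per organization, rounded to nearest integer."""
    if n_orgs <= 0:
        raise ValueError("n_orgs must be positive")
    return int(round(n_patients / n_orgs))


def percent_of(diff: float, base: float, digits: int = 1) -> float:
    """A dollar difference expressed as a percent of a base, display-rounded."""
    return round(diff / base * 100.0, digits)


def descriptive_table(
    attribution: pd.DataFrame, spend: pd.DataFrame, members: pd.DataFrame
) -> pd.DataFrame:
    """Per-ownership descriptives: organizations, patients, patients per
    organization (mean / min / max), risk score, spending, age."""
    ok = attribution[attribution["exclusion_reason"] == "none"]
    df = (
        ok.merge(members, on=["member_id", "year"])
        .merge(spend[["member_id", "year", "total_cents"]], on=["member_id", "year"])
    )
    rows = []
    for own in OWNERSHIP_TYPES:
        sub = df[df["ownership"] == own]
        if len(sub) == 0:
            continue
        per_org = sub.groupby("org_id").size()
        rows.append(
            {
                "ownership": own,
                "n_orgs": int(per_org.size),
                "n_patients": int(len(sub)),
                "patients_per_org_mean": patients_per_org(len(sub), per_org.size),
                "patients_per_org_min": int(per_org.min()),
                "patients_per_org_max": int(per_org.max()),
                "risk_score_mean": float(sub["risk_score"].mean()),
                "risk_score_min": float(sub["risk_score"].min()),
                "risk_score_max": float(sub["risk_score"].max()),
                "allowed_spending_mean": round(float(sub["total_cents"].mean()) / 100.0),
                "age_mean": round(float(sub["age"].mean()), 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    data: object
    attribution: pd.DataFrame
    spend: pd.DataFrame
    median_prices: pd.DataFrame
    quality: pd.DataFrame
    estimates: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    manifest: dict


def _fit_spending_rows(analytic, response_col, label, notes_sink):
    rows = []
    design = build_design(analytic, response_col)
    try:
        est, _ = fit_glm_log(design)
        rows.append({"model": f"glm_log:{label}", **est.to_dict()})
    except EstimationError as exc:
        rows.append({"model": f"glm_log:{label}", "estimand": "percent_diff",
                     "point": np.nan, "note": str(exc)})
    notes_sink.extend(design.notes)
    return rows, design


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated dataset and write all outputs."""
    if not isinstance(config, SimConfig):
        config = SimConfig.from_file(config)
    if seed is not None:
        config = config.replace(seed=int(seed))
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        data = generate(config)
        write_dataset(data.members, data.roster, data.claims, data.crosswalk,
                      data.wage_index, out / "dataset", truth=data.truth)

        stage("attribute")
        totals = raw_totals(data.claims, data.members)
        attribution = attribution_table(
            data.members, data.claims, data.roster, totals
        )
        attribution.to_csv(out / "attribution.csv", index=False)
        excl = attribution["exclusion_reason"].value_counts()
        (out / "exclusions.log").write_text(
            "\n".join(f"{k}: {v}" for k, v in excl.items()) + "\n"
        )
        cohort_attr = attribution[attribution["exclusion_reason"] == "none"]
        sizes = practice_size_category(attribution)

        stage("aggregate")
        cohort = cohort_attr[["member_id", "year"]]
        spend, med = annual_spend_table(data.claims, data.crosswalk, cohort)
        spend_out = spend.copy()
        spend_out.to_csv(out / "annual_spend.csv", index=False)
        med.to_csv(out / "median_prices.csv", index=False)

        stage("quality")
        cohort_demo = cohort.merge(data.members, on=["member_id", "year"])
        qrec = quality_records(data.claims, cohort_demo)
        qrec.to_csv(out / "quality_records.csv", index=False)

        stage("estimate")
        analytic = assemble_analytic(attribution, spend, data.members,
                                     data.wage_index, sizes)
        analytic["total_dollars"] = analytic["total_cents"] / 100.0
        analytic["std_total_dollars"] = analytic["std_total_cents"] / 100.0
        notes: list[str] = []
        est_rows: list[dict] = []

        rows, design_total = _fit_spending_rows(analytic, "total_dollars", "total", notes)
        est_rows += rows
        design_std = build_design(analytic, "std_total_dollars")
        est_std, _ = fit_glm_log(design_std)
        est_rows.append({"model": "glm_log:total_standardized", **est_std.to_dict()})
        est_total = next(r for r in est_rows if r["model"] == "glm_log:total")
        decomp = None
        if np.isfinite(est_total.get("point", np.nan)):
            from .estimation import EffectEstimate

            act = EffectEstimate(**{k: est_total[k] for k in (
                "estimand", "point", "ci_low", "ci_high", "p_value", "n_obs",
                "n_clusters", "coef", "se")})
            decomp = price_utilization_decomposition(act, est_std, design_total, design_std)

        est_dollar, _ = fit_linear_dollars(design_total)
        est_rows.append({"model": "ols_dollars:total", **est_dollar.to_dict()})

        for cat in BETOS_CATEGORIES:
            analytic[f"{cat}_dollars"] = analytic[f"betos_{cat}_cents"] / 100.0
            rows, _ = _fit_spending_rows(analytic, f"{cat}_dollars", f"betos_{cat}", notes)
            est_rows += rows
        for s in SETTINGS:
            analytic[f"{s}_dollars"] = analytic[f"setting_{s}_cents"] / 100.0
            rows, _ = _fit_spending_rows(analytic, f"{s}_dollars", f"setting_{s}", notes)
            est_rows += rows

        # quality odds ratios (MSA + year mains + wage index, per the reduced
        # covariate list quality models use)
        qual_rows = []
        for measure in QUALITY_MEASURES:
            sub = qrec[(qrec["measure"] == measure) & qrec["eligible"]]
            merged = sub.merge(analytic, on=["member_id", "year"], how="inner")
            rec = {"model": f"logit:{measure}", "estimand": "odds_ratio"}
            if len(merged) < MIN_ELIGIBLE_FOR_LOGIT:
                rec.update({"point": np.nan, "note": f"only {len(merged)} eligible rows"})
            else:
                try:
                    d = build_design(merged, merged["numerator"].astype(float),
                                     msa_year_interaction=False)
                    est, _ = fit_logistic_quality(d)
                    rec.update(est.to_dict())
                except (SeparationError, EstimationError) as exc:
                    rec.update({"point": np.nan, "note": str(exc)})
            qual_rows.append(rec)
        est_rows += qual_rows

        estimates = pd.DataFrame(est_rows)
        estimates.to_csv(out / "estimates.csv", index=False)
        (out / "model_card.txt").write_text(
            "variance: quasi-poisson (var ∝ mean)\n"
            "cluster covariance: CR2 (Bell-McCaffrey) sandwich over physician "
            "organizations, Satterthwaite df; CR0 with G/(G-1) and t(G-1) "
            "available via cluster_correction='cr0'\n"
            "ownership contrast: physician_owned (ref) vs pooled hospital\n"
            "median prices: per BETOS category x calendar year, pooled across "
            "ownership types (not pooled across years)\n"
            "references: first MSA:year cell, youngest age band, decile 1, size cat 1\n"
            + "\n".join(sorted(set(notes))) + "\n"
        )

        stage("report")
        table1 = descriptive_table(attribution, spend, data.members)

        unadj = (
            analytic.groupby("hosp")["total_dollars"].mean().rename(
                {0: "physician_owned", 1: "hospital_owned"})
        )
        t2_rows = []
        for _, r in estimates.iterrows():
            if str(r["model"]).startswith(("glm_log:", "ols_dollars:")):
                t2_rows.append({
                    "model": r["model"],
                    "estimand": r.get("estimand"),
                    "point": round(r["point"], 2) if pd.notna(r.get("point")) else np.nan,
                    "ci_low": round(r["ci_low"], 2) if pd.notna(r.get("ci_low")) else np.nan,
                    "ci_high": round(r["ci_high"], 2) if pd.notna(r.get("ci_high")) else np.nan,
                    "p_value": r.get("p_value"),
                })
        table2 = pd.DataFrame(t2_rows)
        table2.attrs["unadjusted_mean_physician"] = float(unadj.get("physician_owned", np.nan))
        table2.attrs["unadjusted_mean_hospital"] = float(unadj.get("hospital_owned", np.nan))

        table3 = utilization_table(data.claims, attribution)
        table4 = pd.DataFrame(
            [
                {
                    "measure": r["model"].split(":", 1)[1],
                    "odds_ratio": round(r["point"], 2) if pd.notna(r.get("point")) else np.nan,
                    "ci_low": round(r["ci_low"], 2) if pd.notna(r.get("ci_low")) else np.nan,
                    "ci_high": round(r["ci_high"], 2) if pd.notna(r.get("ci_high")) else np.nan,
                    "note": r.get("note", ""),
                }
                for r in qual_rows
            ]
        )
        shares = positive_spending_shares(spend, attribution)
        shares.to_csv(out / "positive_spending_shares.csv", index=False)

        tables = {"table1": table1, "table2": table2, "table3": table3, "table4": table4}
        for name, t in tables.items():
            t.to_csv(out / f"{name}.csv", index=False)

        manifest = {
            "config_hash": config.config_hash(),
            "seed": int(config.seed),
            "package_version": __version__,
            "file_digests": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.glob("*.csv"))
            },
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        }
        if decomp is not None:
            manifest["decomposition"] = decomp.to_dict()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

        return PipelineResult(
            data=data, attribution=attribution, spend=spend, median_prices=med,
            quality=qrec, estimates=estimates, tables=tables, manifest=manifest,
        )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{current['stage']}' failed: {exc}"
        ) from exc
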