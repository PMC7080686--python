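"""Headline quantities recomputed from scratch at the configured study
conditions; used by the ``accept`` CLI subcommand and scripts/acceptance.py."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .reporting import run_pipeline


def run_acceptance(seed: int, out_path: str | Path, n_members: int = 20000) -> dict:
    """Run the full pipeline on a fresh simulated population and report the
    main computed quantities as {name: {"value": ..., "n": ...}}."""
    import tempfile

    cfg = SimConfig(n_members=n_members, seed=int(seed) % (2**31))
    with tempfile.TemporaryDirectory() as td:
        res = run_pipeline(cfg, td)

    est = res.estimates.set_index("model")
    results: dict[str, dict] = {}

    def put(name, value, n):
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            return
        results[name] = {"value": round(float(value), 4), "n": int(n)}

    total = est.loc["glm_log:total"]
    put("adjusted_spending_pct_diff", total["point"], total["n_obs"])
    std = est.loc["glm_log:total_standardized"]
    put("standardized_spending_pct_diff", std["point"], std["n_obs"])
    put("price_effect_pct", total["point"] - std["point"], total["n_obs"])
    dollars = est.loc["ols_dollars:total"]
    put("adjusted_spending_dollar_diff", dollars["point"], dollars["n_obs"])

    for measure in ("readmit_30d", "hba1c", "ldl", "retinal_exam", "mammography"):
        key = f"logit:{measure}"
        if key in est.index and pd.notna(est.loc[key, "point"]):
            put(f"quality_odds_ratio_{measure}", est.loc[key, "point"],
                est.loc[key, "n_obs"])

    t1 = res.tables["table1"].set_index("ownership")
    for own in t1.index:
        put(f"patients_per_org_{own}", t1.loc[own, "patients_per_org_mean"],
            t1.loc[own, "n_patients"])

    from .spending import positive_spending_shares

    sh = positive_spending_shares(res.spend, res.attribution).set_index("category")
    row = sh.loc["setting_outpatient_facility"]
    put("pct_positive_outpatient_facility_hospital", 100 * row["share_hospital"],
        row["n_hospital"])
    put("pct_positive_outpatient_facility_physician", 100 * row["share_physician"],
        row["n_physician"])

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(results, indent=2) + "\n")
    return results
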