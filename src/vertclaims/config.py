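"""Simulation scenario configuration.

The default :class:`SimConfig` encodes the study conditions the package is
exercised under: a 2014–2016 commercial PPO population in four metropolitan
areas, a multiplicative hospital-ownership spending effect of 0.058 on the log
scale of which ~15.5% operates through per-claim prices, right-skewed
risk-scaled annual spending partitioned across BETOS categories, and
claims-detectable quality events whose rates differ between ownership types by
fixed odds ratios.  Organization counts are scaled to desk size.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .codesets import BETOS_CATEGORIES, QUALITY_MEASURES


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def _default_betos_mix() -> dict[str, dict[str, float]]:
    # rate = expected claims per member-year at risk score 1.0;
    # price_mean in dollars, price_sigma = lognormal sigma of per-claim price.
    return {
        "evaluation_management": {"rate": 4.2, "price_mean": 180.0, "price_sigma": 0.30},
        "procedures": {"rate": 1.2, "price_mean": 650.0, "price_sigma": 0.55},
        "imaging": {"rate": 1.5, "price_mean": 430.0, "price_sigma": 0.55},
        "test": {"rate": 4.0, "price_mean": 140.0, "price_sigma": 0.50},
        "durable_medical_equipment": {"rate": 0.4, "price_mean": 800.0, "price_sigma": 0.60},
        "other": {"rate": 0.8, "price_mean": 350.0, "price_sigma": 0.55},
        "unclassified": {"rate": 0.35, "price_mean": 1300.0, "price_sigma": 0.60},
    }


def _default_quality_rates() -> dict[str, dict[str, float]]:
    # base = event probability in physician-owned practices;
    # hospital_odds_ratio shifts the probability for hospital-owned practices.
    return {
        "readmit_30d": {"base": 0.095, "hospital_odds_ratio": 1.04},
        "hba1c": {"base": 0.55, "hospital_odds_ratio": 0.96},
        "ldl": {"base": 0.50, "hospital_odds_ratio": 0.85},
        "retinal_exam": {"base": 0.25, "hospital_odds_ratio": 1.08},
        "mammography": {"base": 0.60, "hospital_odds_ratio": 1.13},
    }


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic claims generator."""

    n_members: int = 5000
    n_phys_orgs: int = 60
    n_hosp_local_orgs: int = 8
    n_hosp_system_orgs: int = 4
    years: tuple[int, ...] = (2014, 2015, 2016)
    msas: tuple[str, ...] = ("austin", "dallas", "houston", "san_antonio")
    ownership_log_effect: float = 0.058
    price_share: float = 0.155
    betos_mix: dict[str, dict[str, float]] = field(default_factory=_default_betos_mix)
    risk_distribution: dict[str, float] = field(
        default_factory=lambda: {"mean": 1.25, "sigma": 0.6}
    )
    cdhp_prob: float = 0.25
    quality_rates: dict[str, dict[str, float]] = field(default_factory=_default_quality_rates)
    seed: int = 0

    # population mix / event-stream knobs
    ownership_member_shares: tuple[float, float, float] = (0.77, 0.11, 0.12)
    diabetes_prev: float = 0.10
    inpatient_rate: float = 0.04
    inpatient_price_mean: float = 9000.0
    inpatient_price_sigma: float = 0.50
    late_stay_prob: float = 0.04
    outpatient_routing: dict[str, float] = field(
        default_factory=lambda: {"physician_owned": 0.20, "hospital": 0.30}
    )
    enroll_prob: float = 0.97
    msa_weights: tuple[float, ...] | None = None  # None -> ramp over msas
    org_size_skew: float = 2.0  # rank-weight exponent for org sizes within MSA/type
    annual_price_growth: float = 0.025
    msa_year_shift_scale: float = 0.05
    risk_ownership_corr: float = 0.0  # optional confounding knob; 0 = independence

    # ------------------------------------------------------------------ utils
    def validate(self) -> "SimConfig":
        if self.n_members < 1:
            raise ConfigError("n_members: must be >= 1")
        for f in ("n_phys_orgs", "n_hosp_local_orgs", "n_hosp_system_orgs"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{f}: must be >= 1")
        if not self.years:
            raise ConfigError("years: must be non-empty")
        ys = list(self.years)
        if ys != list(range(ys[0], ys[0] + len(ys))):
            raise ConfigError("years: must be consecutive calendar years")
        if not self.msas:
            raise ConfigError("msas: must be non-empty")
        if not math.isfinite(self.ownership_log_effect):
            raise ConfigError("ownership_log_effect: must be finite")
        if not 0.0 <= self.price_share <= 1.0:
            raise ConfigError("price_share: must be in [0, 1]")
        for f in ("cdhp_prob", "diabetes_prev", "inpatient_rate", "late_stay_prob",
                  "enroll_prob"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f}: must be a probability in [0, 1]")
        if set(self.betos_mix) != set(BETOS_CATEGORIES):
            raise ConfigError("betos_mix: must define exactly the seven BETOS categories")
        for cat, mix in self.betos_mix.items():
            for k in ("rate", "price_mean", "price_sigma"):
                if k not in mix or mix[k] < 0:
                    raise ConfigError(f"betos_mix[{cat}].{k}: must be present and >= 0")
        if self.risk_distribution.get("mean", 0) <= 0 or self.risk_distribution.get("sigma", -1) < 0:
            raise ConfigError("risk_distribution: needs mean > 0 and sigma >= 0")
        for m in QUALITY_MEASURES:
            if m not in self.quality_rates:
                raise ConfigError(f"quality_rates[{m}]: missing measure")
            r = self.quality_rates[m]
            if not 0.0 <= r.get("base", -1) <= 1.0:
                raise ConfigError(f"quality_rates[{m}].base: must be in [0, 1]")
            if r.get("hospital_odds_ratio", 0) <= 0:
                raise ConfigError(f"quality_rates[{m}].hospital_odds_ratio: must be > 0")
        shares = self.ownership_member_shares
        if len(shares) != 3 or any(s < 0 for s in shares) or abs(sum(shares) - 1) > 1e-9:
            raise ConfigError("ownership_member_shares: three non-negative values summing to 1")
        for k, v in self.outpatient_routing.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"outpatient_routing[{k}]: must be in [0, 1]")
        if self.msa_weights is not None:
            w = self.msa_weights
            if len(w) != len(self.msas) or any(x < 0 for x in w) or sum(w) <= 0:
                raise ConfigError("msa_weights: one non-negative weight per MSA")
        if self.org_size_skew < 0:
            raise ConfigError("org_size_skew: must be >= 0")
        if int(self.seed) != self.seed:
            raise ConfigError("seed: must be an integer")
        return self

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["msas"] = list(self.msas)
        d["ownership_member_shares"] = list(self.ownership_member_shares)
        if self.msa_weights is not None:
            d["msa_weights"] = list(self.msa_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        for tup in ("years", "msas", "ownership_member_shares", "msa_weights"):
            if tup in d and d[tup] is not None:
                d[tup] = tuple(d[tup])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a YAML or JSON scenario file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path}: expected a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
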