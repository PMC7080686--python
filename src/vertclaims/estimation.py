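"""Cluster-robust regression models for spending and quality.

Three estimator families, all scikit-learn style (``fit``, ``get_params``,
fitted attributes with trailing underscores) and all sharing one inference
convention:

* :class:`QuasiPoissonGLM` — log-link quasi-likelihood GLM for non-negative
  annual spending with a point mass at zero.  Variance ∝ mean by default
  (quasi-Poisson); a variance ∝ mean² option (gamma family) is exposed.
* :class:`ClusterRobustOLS` — the same comparison on the dollar scale.
* :class:`ClusterRobustLogit` — logistic models for the binary quality
  numerators among eligible members.

Standard errors use the CR0 cluster sandwich A⁻¹ (Σ_g s_g s_gᵀ) A⁻¹ with a
G/(G−1) small-sample factor and t(G−1) reference distribution, clustering on
the attributed physician organization (held constant across years).  When every
observation is its own cluster and the small-sample factor is off, this is
exactly heteroscedasticity-robust HC0.

The design builder assembles the covariate set — ownership contrast, MSA×year
cells, age bands, sex, in-sample risk-score deciles, CDHP, wage index and its
square, practice-size categories and attributed-PCP specialty — and prunes
exactly collinear columns with a log of what was dropped and why.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .codesets import AGE_BAND_EDGES, AGE_BAND_LABELS


class EstimationError(ValueError):
    pass


class SeparationError(EstimationError):
    """Perfect separation in a logistic fit; penalization is off by default."""


# --------------------------------------------------------------------- design

@dataclass
class Design:
    """Design matrix bundle handed to the estimators."""

    X: pd.DataFrame              # no intercept column; estimators add it
    y: np.ndarray
    clusters: np.ndarray
    ownership_terms: list[str]   # column name(s) of the ownership contrast
    dropped: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    sample_key: int = 0          # fingerprint of the member-year sample

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))


@dataclass
class EffectEstimate:
    estimand: str                # percent_diff | dollar_diff | odds_ratio
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_clusters: int
    coef: float = float("nan")   # raw coefficient on the model scale
    se: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand, "point": self.point, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value, "n_obs": self.n_obs,
            "n_clusters": self.n_clusters, "coef": self.coef, "se": self.se,
        }


def assemble_analytic(
    attribution: pd.DataFrame,
    spend: pd.DataFrame,
    members: pd.DataFrame,
    wage_index: pd.DataFrame,
    size_categories: pd.DataFrame,
) -> pd.DataFrame:
    """Join attribution, spending, demographics, wage index and practice size
    into one analytic frame; errors on unjoinable member-years."""
    ok = attribution[attribution["exclusion_reason"] == "none"]
    df = ok.merge(members, on=["member_id", "year"], how="left")
    bad = df[df["risk_score"].isna()]
    if len(bad):
        ids = bad[["member_id", "year"]].head(10).to_records(index=False).tolist()
        raise EstimationError(f"member-years missing demographics: {ids}")
    df = df.merge(spend, on=["member_id", "year"], how="left")
    if df["total_cents"].isna().any():
        n = int(df["total_cents"].isna().sum())
        raise EstimationError(f"{n} attributed member-year(s) missing spending rows")
    df = df.merge(wage_index, on=["msa", "year"], how="left")
    if df["wage_index"].isna().any():
        raise EstimationError("wage index table does not cover every MSA-year")
    df = df.merge(
        size_categories[["org_id", "year", "n_attributed", "size_category"]],
        on=["org_id", "year"], how="left",
    )
    df["hosp"] = (df["ownership"] != "physician_owned").astype(int)
    return df


def _dummies(s: pd.Series, prefix: str, notes: list[str]) -> pd.DataFrame:
    cats = sorted(s.dropna().unique())
    if len(cats) < 2:
        notes.append(f"{prefix}: single level ({cats}); no columns emitted")
        return pd.DataFrame(index=s.index)
    ref = cats[0]
    notes.append(f"{prefix}: reference level '{ref}'")
    return pd.DataFrame(
        {f"{prefix}[{c}]": (s == c).astype(float) for c in cats[1:]}, index=s.index
    )


def _prune_collinear(
    X: pd.DataFrame, protected: list[str], notes: list[str], tol: float = 1e-8
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right pruning of columns exactly collinear with the
    intercept and the columns kept before them (protected columns first)."""
    order = protected + [c for c in X.columns if c not in protected]
    n = len(X)
    kept: list[str] = []
    dropped: list[str] = []
    Q = np.ones((n, 1)) / np.sqrt(n)
    for col in order:
        v = X[col].to_numpy(dtype=float)
        resid = v - Q @ (Q.T @ v)
        if np.linalg.norm(resid) <= tol * (np.linalg.norm(v) + 1.0):
            if col in protected:
                raise EstimationError(f"ownership column '{col}' is degenerate in this sample")
            dropped.append(col)
            notes.append(f"dropped collinear column: {col}")
            continue
        kept.append(col)
        Q = np.hstack([Q, (resid / np.linalg.norm(resid))[:, None]])
    return X[kept], dropped


def build_design(
    analytic: pd.DataFrame,
    response: str | pd.Series,
    *,
    ownership: str = "pooled",            # "pooled" | "three_level"
    msa_year_interaction: bool = True,
    age_spec: str = "bands",              # "bands" | "quadratic"
    size_bins: str = "standard",          # "standard" | "decile"
    include_wage: bool = True,
    n_risk_deciles: int = 10,
    drop_collinear: bool = True,
) -> Design:
    """Build the regression design for a spending or quality response.

    Risk-score decile cut points are computed on the estimation sample passed
    in.  The MSA×year interaction is a single combined factor (its cells absorb
    the MSA and year main effects); with it off, separate MSA and year
    indicator blocks are used.
    """
    notes: list[str] = []
    df = analytic.reset_index(drop=True)
    parts: list[pd.DataFrame] = []

    if ownership == "pooled":
        own = pd.DataFrame({"hospital_owned": df["hosp"].astype(float)})
        own_terms = ["hospital_owned"]
    elif ownership == "three_level":
        own = pd.DataFrame(
            {
                "local_hospital_owned": (df["ownership"] == "local_hospital_owned").astype(float),
                "multi_hospital_system_owned": (
                    df["ownership"] == "multi_hospital_system_owned"
                ).astype(float),
            }
        )
        own_terms = list(own.columns)
    else:
        raise EstimationError(f"unknown ownership coding '{ownership}'")
    parts.append(own)

    if msa_year_interaction:
        cell = df["msa"].astype(str) + ":" + df["year"].astype(str)
        parts.append(_dummies(cell, "msa_year", notes))
    else:
        parts.append(_dummies(df["msa"].astype(str), "msa", notes))
        parts.append(_dummies(df["year"].astype(str), "year", notes))

    if age_spec == "bands":
        band = pd.cut(
            df["age"], bins=list(AGE_BAND_EDGES), labels=AGE_BAND_LABELS,
            right=False, include_lowest=True,
        ).astype(str)
        parts.append(_dummies(band, "age_band", notes))
    elif age_spec == "quadratic":
        parts.append(pd.DataFrame({"age": df["age"].astype(float),
                                   "age_sq": df["age"].astype(float) ** 2}))
    else:
        raise EstimationError(f"unknown age_spec '{age_spec}'")

    parts.append(pd.DataFrame({"sex_F": (df["sex"] == "F").astype(float)}))

    try:
        dec = pd.qcut(df["risk_score"], q=n_risk_deciles, labels=False, duplicates="drop")
        parts.append(_dummies(pd.Series(dec, index=df.index).map(lambda d: f"d{int(d)+1:02d}"),
                              "risk_decile", notes))
    except ValueError:
        notes.append("risk_decile: could not form bins; omitted")

    parts.append(pd.DataFrame({"cdhp": df["cdhp_flag"].astype(float)}))

    if include_wage:
        parts.append(pd.DataFrame({"wage_index": df["wage_index"].astype(float),
                                   "wage_index_sq": df["wage_index"].astype(float) ** 2}))

    if size_bins == "standard":
        parts.append(_dummies(df["size_category"].map(lambda v: f"c{int(v)}"), "practice_size", notes))
    elif size_bins == "decile":
        dec = pd.qcut(df["n_attributed"], q=10, labels=False, duplicates="drop")
        parts.append(_dummies(pd.Series(dec, index=df.index).map(lambda d: f"d{int(d)+1:02d}"),
                              "practice_size", notes))
    else:
        raise EstimationError(f"unknown size_bins '{size_bins}'")

    parts.append(_dummies(df["pcp_specialty"].astype(str), "specialty", notes))

    X = pd.concat(parts, axis=1)
    dropped: list[str] = []
    if drop_collinear:
        X, dropped = _prune_collinear(X, own_terms, notes)

    y = (df[response] if isinstance(response, str) else pd.Series(response).reset_index(drop=True))
    y = y.to_numpy(dtype=float)
    clusters = df["org_id"].to_numpy()
    key = int(pd.util.hash_pandas_object(
        df[["member_id", "year"]].astype(str).agg("|".join, axis=1)
    ).sum() % (2**63))
    return Design(X=X, y=y, clusters=clusters, ownership_terms=own_terms,
                  dropped=dropped, notes=notes, sample_key=key)


# ------------------------------------------------------------------ sandwich

def cluster_sandwich(
    X: np.ndarray,
    scores: np.ndarray,
    bread_weights: np.ndarray,
    clusters: np.ndarray,
    small_sample: bool = True,
) -> np.ndarray:
    """CR0 sandwich A⁻¹ B A⁻¹ with A = Xᵀ diag(w) X and B the sum of
    per-cluster score outer products; optional G/(G−1) factor."""
    A = X.T @ (X * bread_weights[:, None])
    frame = pd.DataFrame(X * scores[:, None])
    frame["__g"] = clusters
    S = frame.groupby("__g").sum().to_numpy()
    B = S.T @ S
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv
    G = len(np.unique(clusters))
    if small_sample and G > 1:
        V = V * (G / (G - 1))
    return V


def _cr2_pieces(X: np.ndarray, resid_score: np.ndarray, bread_w: np.ndarray,
                clusters: np.ndarray):
    """CR2 (Bell–McCaffrey) adjusted cluster scores and Satterthwaite pieces.

    Uses the working-weight inner product: with C = W^{1/2}X and
    D_g = C_g A^{-1/2}, the within-cluster leverage H_gg = D_g D_gᵀ has rank
    ≤ k, so (I − H_gg)^{-1/2} is applied through a thin SVD of D_g in
    O(n_g·k²).  Returns the adjusted score sum per cluster and, per cluster,
    the k×k matrix T_g with a_g(c) = cᵀT_g c feeding the Satterthwaite df
    (Σa)²/Σa² for any contrast c.
    """
    sqw = np.sqrt(bread_w)
    C = X * sqw[:, None]
    A = C.T @ C
    evals, evecs = np.linalg.eigh(A)
    evals = np.clip(evals, 1e-12 * evals.max(), None)
    A_invhalf = evecs @ np.diag(evals**-0.5) @ evecs.T
    ehat = resid_score / np.where(sqw > 0, sqw, 1.0)

    order = np.argsort(clusters, kind="mergesort")
    sorted_cl = clusters[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_cl[1:] != sorted_cl[:-1], True])
    S_rows, T_list = [], []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        idx = order[b0:b1]
        D = C[idx] @ A_invhalf
        U, s, _ = np.linalg.svd(D, full_matrices=False)
        factor = (1.0 / np.sqrt(np.clip(1.0 - s**2, 1e-12, None))) - 1.0
        adj_e = ehat[idx] + U @ (factor * (U.T @ ehat[idx]))
        S_rows.append(C[idx].T @ adj_e)
        Q = D + U @ (factor[:, None] * (U.T @ D))  # (I-H)^{-1/2} D_g
        QA = Q @ A_invhalf
        T_list.append(QA.T @ QA)
    S = np.vstack(S_rows)
    B = S.T @ S
    A_inv = A_invhalf @ A_invhalf
    V = A_inv @ B @ A_inv
    return V, T_list


class _ClusterModelBase(BaseEstimator):
    """Shared fit/inference plumbing for the cluster-robust estimators."""

    def __init__(self, fit_intercept: bool = True, small_sample: bool = True,
                 cluster_correction: str = "cr2", alpha: float = 0.05):
        self.fit_intercept = fit_intercept
        self.small_sample = small_sample
        self.cluster_correction = cluster_correction
        self.alpha = alpha

    # subclasses implement _point_fit(X, y) -> params and
    # _score_weights(X, y, params) -> (score residual s_i, bread weight w_i)

    def _prepare(self, X, y, clusters):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float)
        if self.fit_intercept:
            Xa = np.hstack([np.ones((len(ya), 1)), Xa])
            names = ["const"] + names
        if clusters is None:
            cl = np.arange(len(ya))
        else:
            cl = np.asarray(clusters)
        return Xa, ya, names, cl

    def _finish(self, Xa, ya, names, cl, params):
        resid_score, bread_w = self._score_weights(Xa, ya, params)
        if self.cluster_correction == "cr2":
            V, self._satt_T_ = _cr2_pieces(Xa, resid_score, bread_w, cl)
        elif self.cluster_correction == "cr0":
            V = cluster_sandwich(Xa, resid_score, bread_w, cl, self.small_sample)
            self._satt_T_ = None
        else:
            raise EstimationError(
                f"unknown cluster_correction '{self.cluster_correction}'"
            )
        self.feature_names_ = names
        self.params_ = params
        self.coef_ = params[1:] if self.fit_intercept else params
        self.intercept_ = params[0] if self.fit_intercept else 0.0
        self.cov_ = V
        self.se_ = np.sqrt(np.clip(np.diag(V), 0, None))
        self.n_obs_ = len(ya)
        self.n_clusters_ = len(np.unique(cl))
        self.df_inference_ = max(self.n_clusters_ - 1, 1)
        return self

    def fit(self, X, y, clusters=None):
        Xa, ya, names, cl = self._prepare(X, y, clusters)
        params = self._point_fit(Xa, ya)
        return self._finish(Xa, ya, names, cl, params)

    # ------------------------------------------------------------- inference
    def _idx(self, term: str | int) -> int:
        if isinstance(term, int):
            return term
        return self.feature_names_.index(term)

    def _df_for(self, c: np.ndarray) -> float:
        """Reference-t degrees of freedom for contrast c: Satterthwaite under
        CR2, G−1 under CR0."""
        if self._satt_T_ is None:
            return float(self.df_inference_)
        a = np.array([float(c @ T @ c) for T in self._satt_T_])
        tot, sq = a.sum(), (a**2).sum()
        if not np.isfinite(tot) or sq <= 0:
            return float(self.df_inference_)
        df = tot**2 / sq
        return float(max(df, 1.0))

    def _unit(self, i: int) -> np.ndarray:
        c = np.zeros(len(self.params_))
        c[i] = 1.0
        return c

    def term_test(self, term: str | int) -> tuple[float, float, float, float]:
        """(coef, se, t, two-sided p) for one term."""
        i = self._idx(term)
        b, se = self.params_[i], self.se_[i]
        df = self._df_for(self._unit(i))
        t = b / se if se > 0 else np.inf * np.sign(b) if b else 0.0
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        return b, se, t, p

    def conf_int(self, term: str | int, alpha: float | None = None) -> tuple[float, float]:
        i = self._idx(term)
        a = self.alpha if alpha is None else alpha
        crit = stats.t.ppf(1 - a / 2, self._df_for(self._unit(i)))
        b, se = self.params_[i], self.se_[i]
        return b - crit * se, b + crit * se

    def wald_equal(self, term_a: str, term_b: str) -> tuple[float, float]:
        """Wald test of coefficient equality (t form)."""
        i, j = self._idx(term_a), self._idx(term_b)
        c = self._unit(i) - self._unit(j)
        d = self.params_[i] - self.params_[j]
        v = float(c @ self.cov_ @ c)
        t = d / np.sqrt(v) if v > 0 else np.inf
        p = 2 * stats.t.sf(abs(t), self._df_for(c))
        return float(t), float(p)


class QuasiPoissonGLM(_ClusterModelBase):
    """Log-link quasi-likelihood GLM; variance ∝ mean ("mean") or ∝ mean²
    ("mean_squared", i.e. gamma).  IRLS until the relative deviance change is
    below ``tol`` (default 1e-8) with at most ``max_iter`` iterations."""

    def __init__(self, variance: str = "mean", tol: float = 1e-8, max_iter: int = 100,
                 fit_intercept: bool = True, small_sample: bool = True,
                 cluster_correction: str = "cr2", alpha: float = 0.05):
        super().__init__(fit_intercept=fit_intercept, small_sample=small_sample,
                         cluster_correction=cluster_correction, alpha=alpha)
        self.variance = variance
        self.tol = tol
        self.max_iter = max_iter

    def _family(self):
        if self.variance == "mean":
            return sm.families.Poisson()
        if self.variance == "mean_squared":
            return sm.families.Gamma(link=sm.families.links.Log())
        raise EstimationError(f"unknown variance spec '{self.variance}'")

    def _point_fit(self, Xa, ya):
        if (ya < 0).any():
            raise EstimationError("log-link GLM requires a non-negative response")
        if not (ya > 0).any():
            raise EstimationError("all-zero response; mean is not identified on the log scale")
        if self.variance == "mean_squared" and (ya == 0).any():
            raise EstimationError("gamma variance requires strictly positive response")
        model = sm.GLM(ya, Xa, family=self._family())
        res = model.fit(maxiter=self.max_iter, tol=self.tol)
        self.n_iter_ = res.fit_history.get("iteration", len(res.fit_history.get("deviance", [])))
        dev = res.fit_history.get("deviance", [])
        if len(dev) >= self.max_iter + 1:
            last = dev[-1]
            prev = dev[-2]
            if abs(prev - last) > self.tol * (abs(last) + 0.1):
                raise EstimationError(
                    f"IRLS failed to converge in {self.max_iter} iterations; "
                    f"deviance trace tail: {[float(v) for v in dev[-5:]]}"
                )
        self.deviance_ = float(res.deviance)
        return np.asarray(res.params)

    def _score_weights(self, Xa, ya, params):
        mu = np.exp(Xa @ params)
        if self.variance == "mean":
            return ya - mu, mu           # score x(y−μ); bread XᵀWX with W=μ
        return (ya - mu) / mu, np.ones_like(mu)  # gamma/log: score x(y−μ)/μ; W=1

    def predict(self, X):
        Xa = np.asarray(X, dtype=float)
        if self.fit_intercept:
            Xa = np.hstack([np.ones((len(Xa), 1)), Xa])
        return np.exp(Xa @ self.params_)


class ClusterRobustOLS(_ClusterModelBase):
    """OLS on the dollar scale with the shared cluster-robust inference."""

    def _point_fit(self, Xa, ya):
        rank = np.linalg.matrix_rank(Xa)
        if rank < Xa.shape[1]:
            bad = self._collinear_names(Xa)
            raise EstimationError(f"rank-deficient design; collinear column(s): {bad}")
        res = sm.OLS(ya, Xa).fit()
        self.resid_ = np.asarray(res.resid)
        return np.asarray(res.params)

    def _collinear_names(self, Xa):
        names = getattr(self, "_pending_names", None)
        bad = []
        Q = np.zeros((Xa.shape[0], 0))
        for j in range(Xa.shape[1]):
            v = Xa[:, j]
            r = v - Q @ (Q.T @ v)
            if np.linalg.norm(r) <= 1e-8 * (np.linalg.norm(v) + 1):
                bad.append(names[j] if names else f"col{j}")
            else:
                Q = np.hstack([Q, (r / np.linalg.norm(r))[:, None]])
        return bad

    def fit(self, X, y, clusters=None):
        Xa, ya, names, cl = self._prepare(X, y, clusters)
        self._pending_names = names
        params = self._point_fit(Xa, ya)
        return self._finish(Xa, ya, names, cl, params)

    def _score_weights(self, Xa, ya, params):
        return ya - Xa @ params, np.ones(len(ya))

    def predict(self, X):
        Xa = np.asarray(X, dtype=float)
        if self.fit_intercept:
            Xa = np.hstack([np.ones((len(Xa), 1)), Xa])
        return Xa @ self.params_


class ClusterRobustLogit(_ClusterModelBase):
    """Maximum-likelihood logistic regression; cluster-robust odds-ratio CIs.

    Raises :class:`SeparationError` when the fit walks to a separating
    hyperplane (fitted probabilities numerically 0/1)."""

    def __init__(self, tol: float = 1e-10, max_iter: int = 200,
                 fit_intercept: bool = True, small_sample: bool = True,
                 cluster_correction: str = "cr2", alpha: float = 0.05):
        super().__init__(fit_intercept=fit_intercept, small_sample=small_sample,
                         cluster_correction=cluster_correction, alpha=alpha)
        self.tol = tol
        self.max_iter = max_iter

    def _point_fit(self, Xa, ya):
        if not np.isin(ya, (0.0, 1.0)).all():
            raise EstimationError("logistic response must be binary 0/1")
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            res = sm.GLM(ya, Xa, family=sm.families.Binomial()).fit(
                maxiter=self.max_iter, tol=self.tol
            )
        except PerfectSeparationError as exc:
            raise SeparationError(
                "perfect separation detected; consider penalization (off by default)"
            ) from exc
        params = np.asarray(res.params)
        if np.abs(Xa @ params).max() > 30:
            raise SeparationError(
                "quasi-separation: fitted log-odds exceed ±30; consider penalization"
            )
        return params

    def _score_weights(self, Xa, ya, params):
        p = 1.0 / (1.0 + np.exp(-(Xa @ params)))
        return ya - p, p * (1 - p)

    def predict_proba(self, X):
        Xa = np.asarray(X, dtype=float)
        if self.fit_intercept:
            Xa = np.hstack([np.ones((len(Xa), 1)), Xa])
        p = 1.0 / (1.0 + np.exp(-(Xa @ self.params_)))
        return np.column_stack([1 - p, p])


# ------------------------------------------------------------- op wrappers

def _effect(model: _ClusterModelBase, design: Design, transform: str) -> EffectEstimate:
    term = design.ownership_terms[0]
    b, se, _, p = model.term_test(term)
    lo, hi = model.conf_int(term)
    if transform == "percent":
        point, lo_t, hi_t = (100 * (np.exp(v) - 1) for v in (b, lo, hi))
        estimand = "percent_diff"
    elif transform == "dollar":
        point, lo_t, hi_t = b, lo, hi
        estimand = "dollar_diff"
    elif transform == "odds":
        point, lo_t, hi_t = (float(np.exp(v)) for v in (b, lo, hi))
        estimand = "odds_ratio"
    else:
        raise ValueError(transform)
    return EffectEstimate(estimand, float(point), float(lo_t), float(hi_t), float(p),
                          model.n_obs_, model.n_clusters_, coef=float(b), se=float(se))


def fit_glm_log(design: Design, variance: str = "mean") -> tuple[EffectEstimate, QuasiPoissonGLM]:
    """Quasi-likelihood log-link spending model → percent difference."""
    m = QuasiPoissonGLM(variance=variance).fit(design.X, design.y, clusters=design.clusters)
    return _effect(m, design, "percent"), m


def fit_linear_dollars(design: Design) -> tuple[EffectEstimate, ClusterRobustOLS]:
    """Dollar-scale linear model → dollar difference."""
    m = ClusterRobustOLS().fit(design.X, design.y, clusters=design.clusters)
    return _effect(m, design, "dollar"), m


def fit_logistic_quality(design: Design) -> tuple[EffectEstimate, ClusterRobustLogit]:
    """Logistic quality model on eligible members → odds ratio."""
    m = ClusterRobustLogit().fit(design.X, design.y, clusters=design.clusters)
    return _effect(m, design, "odds"), m


@dataclass
class DecompositionReport:
    actual: EffectEstimate
    standardized: EffectEstimate       # utilization component
    price_effect_pct: float            # actual − standardized, percentage points

    def to_dict(self) -> dict:
        return {
            "actual_percent_diff": self.actual.point,
            "actual_ci": [self.actual.ci_low, self.actual.ci_high],
            "standardized_percent_diff": self.standardized.point,
            "standardized_ci": [self.standardized.ci_low, self.standardized.ci_high],
            "price_effect_pct": self.price_effect_pct,
        }


def price_utilization_decomposition(
    actual: EffectEstimate, standardized: EffectEstimate,
    actual_design: Design | None = None, standardized_design: Design | None = None,
) -> DecompositionReport:
    """Split the spending differential into utilization (standardized-price
    effect) and price (remainder) components; both fits must share the sample."""
    if actual.n_obs != standardized.n_obs:
        raise EstimationError(
            f"sample mismatch: {actual.n_obs} vs {standardized.n_obs} observations"
        )
    if (actual_design is not None and standardized_design is not None
            and actual_design.sample_key != standardized_design.sample_key):
        raise EstimationError("actual and standardized fits use different member-year samples")
    return DecompositionReport(
        actual=actual, standardized=standardized,
        price_effect_pct=actual.point - standardized.point,
    )
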