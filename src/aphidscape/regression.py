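"""Statistical chain relating insect metrics to landscape and weather covariates.

The chain, applied per dependent variable (insect metric):

1. listwise deletion of site-years missing the dependent or any candidate
   covariate (records with undefined cvPPT are dropped *before* the pooling
   ANOVA whenever cvPPT is a candidate);
2. year pooling: one-way ANOVA on ranks across years; if significant at α,
   Tukey HSD (Tukey–Kramer unequal-n correction) on the same ranks and
   selection of the largest mutually non-significant set of years;
3. natural-log transform of the configured dependent variables;
4. iterative VIF screen of the candidate covariates (drop the largest VIF
   above the threshold, recompute, repeat);
5. exhaustive subset OLS over the surviving candidates, ranked by AICc;
   the optimal model is the AICc minimum and the top set collects models
   with ΔAICc below the configured threshold (default 2), with per-variable
   inclusion frequencies over that set.

The OLS/AICc engine is written on numpy/scipy for speed under exhaustive
enumeration; the AICc convention counts the residual variance as a parameter:

    AICc = n ln(RSS/n) + n (1 + ln 2π) + 2p + 2p(p+1)/(n − p − 1),
    p = (number of coefficients incl. intercept) + 1.

The engine is exposed both as plain functions (:func:`fit_ols`,
:func:`exhaustive_aicc`) and as sklearn-compatible estimators
(:class:`ExhaustiveAICcRegressor`, :class:`VIFScreen`) that compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "spearman_matrix",
    "anova_on_ranks",
    "tukey_hsd_ranks",
    "PoolingDecision",
    "decide_pooling",
    "transform_dependent",
    "vif_screen",
    "VIFScreen",
    "ModelFit",
    "fit_ols",
    "aicc_from_rss",
    "exhaustive_aicc",
    "SelectionResult",
    "ExhaustiveAICcRegressor",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# correlation and year pooling


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations (midrank ties, pairwise-complete rows).

    Constant columns yield NaN cells with a warning.
    """
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                r = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = stats.spearmanr(pair[a], pair[b]).statistic
                if np.isnan(r):
                    warnings.warn(f"constant column in pair ({a}, {b}); correlation undefined")
            out.loc[a, b] = out.loc[b, a] = r
    return out


def _rank_groups(values: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    ranks = stats.rankdata(values)  # joint midranks
    return [ranks[labels == g] for g in np.unique(labels)]


def anova_on_ranks(values, labels) -> float:
    """One-way fixed-effects ANOVA F-test applied to jointly midranked values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = _rank_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [len(g) for g in groups if len(g) < 2]
    if small:
        raise ValueError("every group needs n >= 2 for ANOVA")
    return float(stats.f_oneway(*groups).pvalue)


def tukey_hsd_ranks(values, labels) -> dict[tuple, float]:
    """Tukey HSD pairwise p-values on the rank-transformed values.

    Uses the studentized-range distribution with the Tukey–Kramer unequal-n
    correction; keys are (group_a, group_b) with a < b.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    groups = _rank_groups(values, labels)
    res = stats.tukey_hsd(*groups)
    out: dict[tuple, float] = {}
    for i, a in enumerate(uniq):
        for j in range(i + 1, len(uniq)):
            out[(a, uniq[j])] = float(res.pvalue[i, j])
    return out


@dataclass(frozen=True)
class PoolingDecision:
    """Which years are combined for a metric's regression."""

    anova_p: float
    tukey_p: dict[tuple, float]
    pooled_years: tuple
    leftover_years: tuple
    all_pooled: bool


def decide_pooling(
    anova_p: float,
    tukey_p: dict[tuple, float] | None,
    years,
    alpha: float = 0.05,
) -> PoolingDecision:
    """Pool all years when the rank ANOVA is non-significant; otherwise pool the
    largest set of years that are pairwise non-significant under Tukey HSD
    (ties broken by the largest minimum pairwise p, then lexicographically)."""
    years = tuple(sorted(years))
    if anova_p >= alpha or len(years) < 2:
        return PoolingDecision(anova_p, tukey_p or {}, years, (), True)
    if tukey_p is None:
        raise ValueError("significant ANOVA requires Tukey p-values")

    def pair_p(a, b):
        key = (a, b) if (a, b) in tukey_p else (b, a)
        return tukey_p[key]

    best: tuple | None = None
    for size in range(len(years), 1, -1):
        qualifying = []
        for combo in itertools.combinations(years, size):
            ps = [pair_p(a, b) for a, b in itertools.combinations(combo, 2)]
            if all(p >= alpha for p in ps):
                qualifying.append((min(ps), combo))
        if qualifying:
            # largest minimum pairwise p wins; ties -> earliest year set
            best_min_p = max(q[0] for q in qualifying)
            best = min(c for p, c in qualifying if p == best_min_p)
            break
    if best is None:
        return PoolingDecision(anova_p, tukey_p, (), years, False)
    leftover = tuple(y for y in years if y not in best)
    return PoolingDecision(anova_p, tukey_p, tuple(best), leftover, False)


# ---------------------------------------------------------------------------
# transformation and collinearity


def transform_dependent(
    table: pd.DataFrame, log_columns: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Replace listed columns with their natural logs.

    Raises on nonpositive values, naming the offending rows; returns the
    transformed table and a {column: transform} record.
    """
    out = table.copy()
    record: dict[str, str] = {}
    for col in table.columns:
        if col in log_columns:
            vals = out[col]
            bad = vals.index[(vals <= 0) & vals.notna()]
            if len(bad):
                raise ValueError(
                    f"column {col!r}: natural-log transform needs positive values; "
                    f"nonpositive at rows {list(bad)[:10]}"
                )
            out[col] = np.log(vals)
            record[col] = "ln"
        else:
            record[col] = "identity"
    return out, record


def _vif_values(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R²_j) from regressing candidate j on the others + const."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vifs = [variance_inflation_factor(design, j + 1) for j in range(X.shape[1])]
    return pd.Series(vifs, index=X.columns)


def vif_screen(
    table: pd.DataFrame,
    candidates: list[str],
    threshold: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the largest-VIF candidate above ``threshold``.

    Returns (retained candidate names, report) where the report holds one row
    per candidate per round with its VIF and whether it was removed that round.
    """
    current = list(candidates)
    report_rows = []
    round_no = 0
    while len(current) >= 2:
        vifs = _vif_values(table[current].dropna())
        vifs = vifs.replace([np.inf], np.finfo(float).max)
        worst = vifs.idxmax()
        removed = vifs[worst] > threshold
        for name, v in vifs.items():
            report_rows.append(
                {
                    "round": round_no,
                    "candidate": name,
                    "vif": float(v),
                    "removed": bool(removed and name == worst),
                }
            )
        if not removed:
            break
        current.remove(worst)
        round_no += 1
    return current, pd.DataFrame(report_rows)


class VIFScreen(TransformerMixin, BaseEstimator):
    """sklearn transformer: drop columns until all VIF <= threshold.

    Fitted attributes: ``retained_`` (column names kept), ``dropped_``,
    ``report_`` (per-round VIF table).
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        retained, report = vif_screen(X, list(X.columns), self.threshold)
        self.retained_ = retained
        self.dropped_ = [c for c in X.columns if c not in retained]
        self.report_ = report
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]


# ---------------------------------------------------------------------------
# OLS + AICc engine


@dataclass(frozen=True)
class ModelFit:
    """One fitted OLS model over a named variable subset."""

    variables: tuple[str, ...]
    r2: float
    adj_r2: float
    f_pvalue: float
    aicc: float
    n: int
    k: int  # number of non-intercept coefficients
    params: pd.Series = None  # index: ("Intercept", *variables); None on the
    pvalues: pd.Series = None  # light-weight fits enumerated during selection
    rss: float = field(repr=False, default=np.nan)
    bse: pd.Series = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1 - alpha) confidence intervals for the coefficients."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.n - self.k - 1)
        return pd.DataFrame(
            {"lower": self.params - tcrit * self.bse, "upper": self.params + tcrit * self.bse}
        )


def aicc_from_rss(rss: float, n: int, k: int) -> float:
    """AICc with p = k + 2 parameters (coefficients + intercept + residual var)."""
    p = k + 2
    if n - p - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, p={p}")
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + n * (1 + math.log(2 * math.pi)) + 2 * p + 2 * p * (p + 1) / (
        n - p - 1
    )


def fit_ols(y: np.ndarray, X: pd.DataFrame | None, variables=None) -> ModelFit:
    """OLS with intercept; coefficient t-tests, R², adjusted R², F-test, AICc.

    ``X`` may be None/empty for the intercept-only model.  Raises on rank
    deficiency, naming the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=range(n))
    X = pd.DataFrame(X)
    if variables is None:
        variables = tuple(X.columns)
    k = len(variables)
    design = np.column_stack([np.ones(n), X[list(variables)].to_numpy(dtype=float)]) if k else np.ones((n, 1))
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design over variables {tuple(variables)}"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = n - k - 1
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    r2 = 1.0 - rss / tss if (k and tss > 0) else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if k else 0.0
    if k and r2 < 1.0:
        fstat = (r2 / k) / ((1.0 - r2) / dof)
        f_pvalue = float(stats.f.sf(fstat, k, dof))
    elif k:
        f_pvalue = 0.0
    else:
        f_pvalue = math.nan
    names = ["Intercept", *variables]
    return ModelFit(
        variables=tuple(variables),
        params=pd.Series(beta, index=names),
        pvalues=pd.Series(pvals, index=names),
        r2=r2,
        adj_r2=adj_r2 if k else 0.0,
        f_pvalue=f_pvalue,
        aicc=aicc_from_rss(rss, n, k),
        n=n,
        k=k,
        rss=rss,
        bse=pd.Series(se, index=names),
    )


@dataclass(frozen=True)
class SelectionResult:
    """Exhaustive-subset AICc selection output."""

    fits: list[ModelFit]  # ranked by (AICc, k, variables)
    optimal: ModelFit
    top_set: list[ModelFit]  # ΔAICc < threshold, optimal included
    inclusion_frequencies: pd.Series
    skipped: list[tuple[tuple[str, ...], str]]
    delta_threshold: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variables": ["+".join(f.variables) or "(intercept)" for f in self.fits],
                "k": [f.k for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta_aicc": [f.aicc - self.optimal.aicc for f in self.fits],
                "r2": [f.r2 for f in self.fits],
                "adj_r2": [f.adj_r2 for f in self.fits],
                "f_pvalue": [f.f_pvalue for f in self.fits],
            }
        )


def exhaustive_aicc(
    y: np.ndarray,
    candidates: pd.DataFrame,
    delta_threshold: float = 2.0,
    max_candidates: int = 15,
) -> SelectionResult:
    """Fit all 2^k subsets of ``candidates`` (intercept always present), rank
    by AICc, and collect the ΔAICc-below-threshold top set with per-variable
    inclusion frequencies.

    Subsets too large for the sample (n − p − 1 <= 0) or rank deficient are
    skipped with a recorded reason.  Equal-AICc ties rank the smaller model
    first, then lexicographic variable order.

    Enumeration runs on the precomputed Gram matrix (each subset solves its
    normal equations, identical to :func:`fit_ols` up to roundoff); the
    optimal model and the top set are refitted with :func:`fit_ols` so they
    carry coefficients, standard errors and t-tests, while the remaining
    enumerated fits keep only their summary statistics.
    """
    names = list(candidates.columns)
    k_all = len(names)
    if k_all > max_candidates:
        raise ValueError(f"{k_all} candidates exceed the 2^{max_candidates} cap")
    y = np.asarray(y, dtype=float)
    n = len(y)
    # center/standardize for conditioning; with the intercept present every
    # subset's RSS is invariant to these affine changes of basis
    Xr = candidates.to_numpy(dtype=float)
    if Xr.size:
        mu = Xr.mean(axis=0)
        sd = Xr.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns stay constant -> caught as singular
        Xr = (Xr - mu) / sd
    yc = y - y.mean()
    D = np.column_stack([np.ones(n), Xr])
    G = D.T @ D
    b = D.T @ yc
    yty = float(yc @ yc)
    tss = yty

    records = []  # (combo names, k, rss)
    skipped: list[tuple[tuple[str, ...], str]] = []
    for size in range(k_all + 1):
        for combo in itertools.combinations(range(k_all), size):
            combo_names = tuple(names[i] for i in combo)
            p = size + 2
            if n - p - 1 <= 0 or n <= size + 1:
                skipped.append((combo_names, f"n={n} too small for k={size}"))
                continue
            idx = np.concatenate(([0], np.asarray(combo, dtype=int) + 1))
            Gs = G[np.ix_(idx, idx)]
            bs = b[idx]
            if np.linalg.matrix_rank(Gs) < len(idx):
                skipped.append((combo_names, "rank-deficient design"))
                continue
            beta = np.linalg.solve(Gs, bs)
            rss = max(yty - float(bs @ beta), 0.0)
            records.append((combo_names, size, rss))
    if not records:
        raise ValueError("no fittable subset")
    if skipped:
        warnings.warn(f"{len(skipped)} subset(s) skipped (sample too small or singular)")

    fits: list[ModelFit] = []
    for combo_names, size, rss in records:
        dof = n - size - 1
        r2 = 1.0 - rss / tss if (size and tss > 0) else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof if size else 0.0
        if size and r2 < 1.0:
            fstat = (r2 / size) / ((1.0 - r2) / dof)
            f_p = float(stats.f.sf(fstat, size, dof))
        elif size:
            f_p = 0.0
        else:
            f_p = math.nan
        fits.append(
            ModelFit(
                variables=combo_names,
                r2=r2,
                adj_r2=adj,
                f_pvalue=f_p,
                aicc=aicc_from_rss(rss, n, size),
                n=n,
                k=size,
                rss=rss,
            )
        )
    fits.sort(key=lambda f: (f.aicc, f.k, f.variables))
    best_aicc = fits[0].aicc
    # refit the top set fully (coefficients, SEs, t-tests)
    for i, f in enumerate(fits):
        if f.aicc - best_aicc < delta_threshold:
            fits[i] = fit_ols(y, candidates, f.variables)
        else:
            break
    optimal = fits[0]
    top = [f for f in fits if f.aicc - optimal.aicc < delta_threshold]
    freq = pd.Series(
        {nm: sum(nm in f.variables for f in top) / len(top) for nm in names},
        dtype=float,
    )
    return SelectionResult(fits, optimal, top, freq, skipped, delta_threshold)


class ExhaustiveAICcRegressor(RegressorMixin, BaseEstimator):
    """sklearn estimator: exhaustive best-subset OLS under AICc.

    fit(X, y) enumerates every subset of X's columns (intercept always kept),
    ranks by AICc, and exposes:

    ``selection_``       full :class:`SelectionResult`
    ``best_model_``      the AICc-optimal :class:`ModelFit`
    ``top_models_``      the ΔAICc < ``delta_threshold`` set
    ``inclusion_frequencies_``  per-variable frequency over the top set
    ``coef_``, ``intercept_``   the optimal model's coefficients

    predict(X) evaluates the optimal model.
    """

    def __init__(self, delta_threshold: float = 2.0, max_candidates: int = 15):
        self.delta_threshold = delta_threshold
        self.max_candidates = max_candidates

    def fit(self, X, y):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        sel = exhaustive_aicc(y, X, self.delta_threshold, self.max_candidates)
        self.selection_ = sel
        self.best_model_ = sel.optimal
        self.top_models_ = sel.top_set
        self.inclusion_frequencies_ = sel.inclusion_frequencies
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        best = sel.optimal
        coef = np.zeros(X.shape[1])
        for i, name in enumerate(X.columns):
            if name in best.variables:
                coef[i] = best.params[name]
        self.coef_ = coef
        self.intercept_ = float(best.params["Intercept"])
        return self

    def predict(self, X):
        check_is_fitted(self, "best_model_")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        return self.intercept_ + X[list(self.feature_names_in_)].to_numpy(dtype=float) @ self.coef_


# ---------------------------------------------------------------------------
# end-to-end pipeline


#: the seven dependent variables analyzed on the natural-log scale
DEFAULT_LOG_METRICS = ("nSAmax", "nLBmax", "nMMmax", "rLBMMmax", "vSA", "vLB", "vMM")

_FULL_CANDIDATES = (
    "PLANDs",
    "PLANDwh",
    "PLANDc",
    "PLANDg",
    "PLANDwo",
    "PD",
    "SIDI",
    "maxTMAX",
    "sdTMAX",
    "meanPPT",
    "cvPPT",
)
_MID_CANDIDATES = ("PLANDs", "PLANDwh", "PLANDc", "PD", "SIDI", "maxTMAX", "meanPPT")

#: per-metric candidate covariates; the reduced sets track smaller samples
DEFAULT_CANDIDATE_SETS: dict[str, tuple[str, ...]] = {
    "nSAmax": _FULL_CANDIDATES,
    "nLBmax": _FULL_CANDIDATES,
    "nMMmax": _FULL_CANDIDATES,
    "rLBMMmax": _MID_CANDIDATES,
    "dtSAmax": _MID_CANDIDATES,
    "dtRespLB": ("PLANDs", "SIDI"),
    "dtRespMM": ("PLANDs", "SIDI"),
    "vSA": _MID_CANDIDATES,
    "vLB": _MID_CANDIDATES,
    "vMM": _MID_CANDIDATES,
}


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    vif_threshold: float = 10.0
    delta_aicc: float = 2.0
    log_metrics: tuple[str, ...] = DEFAULT_LOG_METRICS
    candidate_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CANDIDATE_SETS)
    )
    min_n: int = 10
    unpooled_policy: str = "drop"  # or "separate" (leftover years reported only)


@dataclass
class PipelineResult:
    """Report bundle for one run of the statistical chain."""

    pooling: pd.DataFrame
    optimal_models: pd.DataFrame
    inclusion_frequencies: pd.DataFrame
    vif_report: pd.DataFrame
    spearman: pd.DataFrame
    selections: dict[str, SelectionResult]
    skipped_metrics: dict[str, str]
    full_model_pvalues: dict[str, float]


def run_pipeline(
    insect_metrics: pd.DataFrame,
    env_covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full chain for every insect metric present in the table."""
    from .insects import METRIC_NAMES, apply_retention

    cfg = config or PipelineConfig()
    filtered = apply_retention(insect_metrics)
    merged = filtered.merge(env_covariates, on=["site_id", "year"], how="inner")

    dep_cols = [m for m in METRIC_NAMES if m in merged.columns]
    spearman = spearman_matrix(merged[dep_cols]) if len(dep_cols) >= 2 else pd.DataFrame()

    pooling_rows = []
    model_rows = []
    freq_rows = []
    vif_frames = []
    selections: dict[str, SelectionResult] = {}
    skipped: dict[str, str] = {}
    full_p: dict[str, float] = {}

    for metric in dep_cols:
        candidates = [c for c in cfg.candidate_sets.get(metric, _FULL_CANDIDATES) if c in merged.columns]
        data = merged[["site_id", "year", metric, *candidates]].dropna()
        if len(data) < cfg.min_n:
            skipped[metric] = f"n={len(data)} below minimum {cfg.min_n}"
            continue

        # year pooling on the retained, covariate-complete records
        years = sorted(data["year"].unique())
        counts = data["year"].value_counts()
        if len(years) >= 2 and (counts >= 2).all():
            anova_p = anova_on_ranks(data[metric], data["year"])
            tukey = (
                tukey_hsd_ranks(data[metric], data["year"])
                if anova_p < cfg.alpha
                else None
            )
            decision = decide_pooling(anova_p, tukey, years, cfg.alpha)
        else:
            decision = PoolingDecision(math.nan, {}, tuple(years), (), True)
        pooling_rows.append(
            {
                "metric": metric,
                "anova_p": decision.anova_p,
                "pooled_years": "+".join(str(y) for y in decision.pooled_years),
                "leftover_years": "+".join(str(y) for y in decision.leftover_years),
                **{
                    f"tukey_{a}_{b}": p
                    for (a, b), p in sorted(decision.tukey_p.items())
                },
            }
        )
        if decision.pooled_years:
            subsets = [("", data[data["year"].isin(decision.pooled_years)])]
        elif cfg.unpooled_policy == "separate":
            subsets = [
                (f" [{y}]", data[data["year"] == y])
                for y in sorted(data["year"].unique())
            ]
        else:
            subsets = []
            skipped[metric] = "no mutually non-significant year set; dropped per config"

        for suffix, sub in subsets:
            if len(sub) < cfg.min_n:
                skipped[f"{metric}{suffix}"] = (
                    f"pooled n={len(sub)} below minimum {cfg.min_n}"
                )
                continue
            sub, _ = transform_dependent(
                sub, tuple(c for c in cfg.log_metrics if c == metric)
            )
            dep_label = (
                f"ln({metric}){suffix}" if metric in cfg.log_metrics else f"{metric}{suffix}"
            )

            retained, vif_rep = vif_screen(sub, candidates, cfg.vif_threshold)
            vif_rep.insert(0, "metric", f"{metric}{suffix}")
            vif_frames.append(vif_rep)

            # full-model F-test before selection (the calibration-grade p-value)
            try:
                full_fit = fit_ols(sub[metric].to_numpy(), sub[retained])
                full_p[f"{metric}{suffix}"] = full_fit.f_pvalue
            except (ValueError, np.linalg.LinAlgError):
                full_p[f"{metric}{suffix}"] = math.nan

            sel = exhaustive_aicc(sub[metric].to_numpy(), sub[retained], cfg.delta_aicc)
            selections[f"{metric}{suffix}"] = sel
            best = sel.optimal
            for name in ["Intercept", *best.variables]:
                model_rows.append(
                    {
                        "dependent": dep_label,
                        "variable": name,
                        "coefficient": best.params[name],
                        "p_coefficient": best.pvalues[name],
                        "r2": best.r2,
                        "adj_r2": best.adj_r2,
                        "p_model": best.f_pvalue,
                        "n": best.n,
                    }
                )
            for name, f in sel.inclusion_frequencies.items():
                freq_rows.append(
                    {
                        "dependent": dep_label,
                        "variable": name,
                        "frequency": f,
                        "n_top_models": len(sel.top_set),
                    }
                )

    return PipelineResult(
        pooling=pd.DataFrame(pooling_rows),
        optimal_models=pd.DataFrame(model_rows),
        inclusion_frequencies=pd.DataFrame(freq_rows),
        vif_report=pd.concat(vif_frames, ignore_index=True) if vif_frames else pd.DataFrame(),
        spearman=spearman,
        selections=selections,
        skipped_metrics=skipped,
        full_model_pvalues=full_p,
    )
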