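"""Multivariable logistic regressions for risk-behaviour correlates.

Five binary outcomes (ever had sex with a tourist, condom use at last sex,
STI symptoms in the previous year, alcohol use in the last 30 days, drug use
in the last 3 months) are each regressed on the same eight covariates.  The
drug-use model is restricted to respondents who have ever used drugs.

Fitting is by iteratively reweighted least squares (Newton-Raphson on the
Bernoulli log-likelihood).  Before fitting, covariates whose levels perfectly
predict the outcome (complete or quasi-complete separation, under which the
MLE is non-finite) are detected and omitted with a machine-readable reason,
and rank-deficient design columns are reported by name.  Results are odds
ratios with Wald intervals and McFadden pseudo R-squared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .survey_scoring import COVARIATE_COLUMNS

__all__ = [
    "LogisticFit",
    "ORTable",
    "RegressionSpec",
    "fit_logistic_irls",
    "detect_separation",
    "build_table3",
    "REGRESSION_SPECS",
]


@dataclass(frozen=True)
class RegressionSpec:
    """One outcome model: outcome column, fixed covariate list, subset rule."""

    outcome: str
    covariates: tuple[str, ...] = tuple(COVARIATE_COLUMNS)
    subset_column: str | None = None  # restrict to rows where this column == 1


REGRESSION_SPECS: list[RegressionSpec] = [
    RegressionSpec("ever_tourist_sex"),
    RegressionSpec("condom_last_sex"),
    RegressionSpec("sti_12m"),
    RegressionSpec("alcohol_30d"),
    RegressionSpec("drugs_3m", subset_column="ever_drugs"),
]


class RankDeficientError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    vcov: np.ndarray
    loglik: float
    null_loglik: float
    n_obs: int
    n_iterations: int
    converged: bool

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.loglik / self.null_loglik if self.null_loglik != 0 else np.nan


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    add_intercept: bool = True,
) -> LogisticFit:
    """Logistic regression by IRLS to gradient max-norm below ``tol``.

    ``X`` excludes the intercept column unless ``add_intercept=False``.
    Raises :class:`RankDeficientError` naming collinear columns; flags (not
    raises) non-convergence on the returned fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["const"] + list(names)

    s = np.linalg.svd(X, compute_uv=False)
    if s.min() <= s.max() * max(X.shape) * np.finfo(float).eps:
        _, _, vt = np.linalg.svd(X)
        rank = int((s > s.max() * max(X.shape) * np.finfo(float).eps).sum())
        offending = sorted(
            {names[j] for row in vt[rank:] for j in np.where(np.abs(row) > 1e-8)[0]}
        )
        raise RankDeficientError(offending)

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
    p0 = y.mean()
    null_loglik = float(
        len(y) * (p0 * np.log(max(p0, 1e-12)) + (1 - p0) * np.log(max(1 - p0, 1e-12)))
    )
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None])
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((X.shape[1],) * 2, np.nan)
    return LogisticFit(
        names=list(names),
        coef=beta,
        vcov=vcov,
        loglik=loglik,
        null_loglik=null_loglik,
        n_obs=len(y),
        n_iterations=it,
        converged=converged,
    )


def detect_separation(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> list[str]:
    """Covariates with a level that perfectly predicts the binary outcome.

    Binary columns are flagged when the outcome is constant within either
    level (the likelihood is then monotone in that coefficient and the MLE
    non-finite).  Columns with more than two values are flagged on a perfect
    threshold split: all successes strictly above all failures or vice versa.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    flagged = []
    for j, name in enumerate(names):
        col = X[:, j]
        vals = np.unique(col)
        if len(vals) <= 1:
            continue
        if len(vals) == 2:
            for v in vals:
                sub = y[col == v]
                if len(sub) < len(y) and (sub.min() == sub.max()):
                    flagged.append(name)
                    break
        else:  # ordinal/continuous: perfect threshold split
            y1 = col[y == 1]
            y0 = col[y == 0]
            if len(y1) and len(y0) and (y1.min() > y0.max() or y1.max() < y0.min()):
                flagged.append(name)
    return flagged


@dataclass
class ORTable:
    """Odds-ratio table for one outcome model."""

    outcome: str
    table: pd.DataFrame  # index covariate; columns odds_ratio, std_error, ci_lower, ci_upper, p_value
    n_observations: int
    pseudo_r2: float
    omitted_covariates: dict[str, str] = field(default_factory=dict)  # name -> reason code
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_observations": self.n_observations,
            "pseudo_r2": self.pseudo_r2,
            "pseudo_r2_definition": "McFadden",
            "omitted_covariates": self.omitted_covariates,
            "converged": self.converged,
            "estimates": self.table.reset_index().to_dict(orient="records"),
        }

    def formatted(self) -> pd.Series:
        """Publication-style column: 'OR (SE)' with significance markers."""

        def stars(p):
            return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""

        rows = {}
        for cov, r in self.table.iterrows():
            rows[cov] = f"{r.odds_ratio:.3f}{stars(r.p_value)} ({r.std_error:.4g})"
        for cov, reason in self.omitted_covariates.items():
            rows[cov] = f"Omitted [{reason}]"
        rows["Observations"] = str(self.n_observations)
        rows["Pseudo R-squared (McFadden)"] = f"{self.pseudo_r2:.3f}"
        return pd.Series(rows, name=self.outcome)


def _or_table_from_fit(spec: RegressionSpec, fit: LogisticFit, omitted: dict[str, str],
                       level: float = 0.95) -> ORTable:
    z = norm.ppf(0.5 + level / 2)
    coef = fit.coef
    se = fit.std_errors
    or_ = np.exp(coef)
    tab = pd.DataFrame(
        {
            "coef": coef,
            "odds_ratio": or_,
            "std_error": or_ * se,  # delta-method SE on the OR scale
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p_value": 2 * norm.sf(np.abs(coef) / np.where(se > 0, se, np.nan)),
        },
        index=fit.names,
    )
    return ORTable(
        outcome=spec.outcome,
        table=tab,
        n_observations=fit.n_obs,
        pseudo_r2=fit.mcfadden_r2,
        omitted_covariates=omitted,
        converged=fit.converged,
    )


def fit_outcome_model(profiles: pd.DataFrame, spec: RegressionSpec) -> ORTable:
    """Fit one outcome regression with listwise deletion and separation handling."""
    cols = list(spec.covariates) + [spec.outcome]
    df = profiles
    if spec.subset_column is not None:
        df = df[df[spec.subset_column] == 1]
    df = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(df)
    if n < len(spec.covariates) + 1:
        raise ValueError(
            f"model {spec.outcome!r}: only {n} complete cases for {len(spec.covariates)} covariates"
        )
    y = df[spec.outcome].to_numpy(float)
    keep = list(spec.covariates)
    omitted: dict[str, str] = {}
    for name in detect_separation(df[keep].to_numpy(float), y, keep):
        keep.remove(name)
        omitted[name] = "complete_separation"
    while True:
        try:
            fit = fit_logistic_irls(df[keep].to_numpy(float), y, names=keep)
            break
        except RankDeficientError as err:
            dropped = [c for c in err.columns if c != "const"]
            if not dropped:
                raise
            for c in dropped:
                keep.remove(c)
                omitted[c] = "rank_deficient"
    return _or_table_from_fit(spec, fit, omitted)


def build_table3(profiles: pd.DataFrame, specs: list[RegressionSpec] | None = None) -> dict[str, ORTable]:
    """The five risk-correlate regressions on a scored respondent table.

    Each model applies listwise deletion over its own outcome and the eight
    covariates; the drug-use model is additionally restricted to ever-users.
    """
    specs = specs or REGRESSION_SPECS
    return {spec.outcome: fit_outcome_model(profiles, spec) for spec in specs}


def format_table3(tables: dict[str, ORTable]) -> pd.DataFrame:
    """Side-by-side text table across the five models."""
    return pd.concat([t.formatted() for t in tables.values()], axis=1)


def table3_to_json(tables: dict[str, ORTable], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: t.to_dict() for k, t in tables.items()}, indent=2))
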