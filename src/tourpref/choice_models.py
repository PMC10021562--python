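"""Random-utility choice models: multinomial logit and mixed multinomial logit.

Utility of respondent *i* for alternative *j* in choice set *c* is
``V_ijc = X_ijc' beta + eps_ijc`` with IID type-I extreme value (Gumbel)
errors, which yields the multinomial (conditional) logit choice probability
``P_ijc = exp(X_ijc' beta) / sum_J exp(X_iJc' beta)``.

The mixed multinomial logit (MMNL) relaxes IIA and preference homogeneity by
drawing respondent-level coefficients ``beta_r = b + s * z_r`` with standard
normal ``z_r``; its likelihood integral is simulated with Halton draws, panel
structured (one draw vector per respondent spanning all of their tasks).

Both log-likelihoods and their analytic gradients are implemented here; MNL
additionally has an analytic Hessian and is maximised by damped Newton steps,
MMNL by L-BFGS on the simulated log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .experimental_design import OPT_OUT_COLUMN, AttributeSpec

__all__ = [
    "ChoiceDataset",
    "UtilityParams",
    "EstimationResult",
    "ColumnMismatchError",
    "CollinearityError",
    "systematic_utility",
    "choice_probabilities",
    "mnl_loglik",
    "fit_mnl",
    "halton_sequence",
    "halton_normal_draws",
    "fit_mmnl",
    "implied_level_utilities",
]

ID_COLUMNS = ["respondent_id", "task_id", "alt_id", "chosen"]


class ColumnMismatchError(ValueError):
    """Coefficient names and data columns do not align."""


class CollinearityError(ValueError):
    """Design columns are collinear; offending columns are listed."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear coded columns: {self.columns}")


@dataclass
class UtilityParams:
    """Named utility coefficients: means ``beta`` and (MMNL) SDs ``sigma``.

    ``sigma`` entries must be nonnegative; all random coefficients are normal.
    """

    beta: dict[str, float]
    sigma: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None:
            missing = set(self.sigma) - set(self.beta)
            if missing:
                raise ColumnMismatchError(f"sigma names not in beta: {sorted(missing)}")
            if any(v < 0 for v in self.sigma.values()):
                raise ValueError("sigma entries must be >= 0")

    @property
    def names(self) -> list[str]:
        return list(self.beta)

    def beta_vector(self, columns: list[str] | None = None) -> np.ndarray:
        cols = self.names if columns is None else columns
        try:
            return np.array([self.beta[c] for c in cols], dtype=float)
        except KeyError as err:
            raise ColumnMismatchError(f"missing coefficient for column {err.args[0]!r}") from err

    def sigma_vector(self, columns: list[str] | None = None) -> np.ndarray:
        cols = self.names if columns is None else columns
        if self.sigma is None:
            return np.zeros(len(cols))
        return np.array([self.sigma.get(c, 0.0) for c in cols], dtype=float)


@dataclass
class ChoiceDataset:
    """Long-format choice data: one row per respondent x task x alternative.

    ``df`` must contain ``respondent_id, task_id, alt_id, chosen, opt_out``
    plus the coded attribute columns named in ``columns`` (which include the
    opt-out constant as its final entry when present).  Invariants enforced:
    exactly one chosen alternative per (respondent, task), a constant number
    of alternatives per task, and all-zero attribute columns on opt-out rows.
    """

    df: pd.DataFrame
    columns: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = set(ID_COLUMNS) | set(self.columns)
        missing = req - set(self.df.columns)
        if missing:
            raise ColumnMismatchError(f"dataset missing columns: {sorted(missing)}")
        grp = self.df.groupby(["respondent_id", "task_id"], sort=False)
        n_chosen = grp["chosen"].sum()
        bad = n_chosen[n_chosen != 1]
        if len(bad):
            raise ValueError(
                f"each (respondent, task) needs exactly one chosen row; violated at {bad.index.tolist()[:5]}"
            )
        sizes = grp.size()
        if sizes.nunique() != 1:
            raise ValueError("alternatives-per-task count must be constant across tasks")
        if OPT_OUT_COLUMN in self.df.columns:
            oo = self.df[self.df[OPT_OUT_COLUMN] == 1]
            attr_cols = [c for c in self.columns if c != OPT_OUT_COLUMN]
            if len(oo) and attr_cols and not np.allclose(oo[attr_cols].to_numpy(float), 0.0):
                raise ValueError("opt-out rows must carry all-zero attribute columns")

    @property
    def n_alternatives(self) -> int:
        return int(self.df.groupby(["respondent_id", "task_id"], sort=False).size().iloc[0])

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_tasks_total(self) -> int:
        return len(self.df) // self.n_alternatives

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, chosen, respondent_index) with X shaped (n_tasks_total, J, K).

        Rows are regrouped in stable (respondent, task) order; ``chosen`` holds
        the within-task index of the chosen alternative and ``respondent_index``
        a dense respondent code per task.
        """
        df = self.df.sort_values(["respondent_id", "task_id", "alt_id"], kind="stable")
        J = self.n_alternatives
        T = len(df) // J
        X = df[self.columns].to_numpy(float).reshape(T, J, len(self.columns))
        chosen_flat = df["chosen"].to_numpy(int).reshape(T, J)
        chosen = chosen_flat.argmax(axis=1)
        resp = df["respondent_id"].to_numpy()[::J]
        _, resp_ix = np.unique(resp, return_inverse=True)
        return X, chosen, resp_ix


@dataclass
class EstimationResult:
    """Fitted choice model: estimates, uncertainty, and fit diagnostics."""

    model: str  # "MNL" or "MMNL"
    names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    vcov: np.ndarray
    loglik: float
    gradient_norm: float
    converged: bool
    n_respondents: int
    n_tasks: int
    n_iterations: int = 0
    n_draws: int | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def beta(self) -> dict[str, float]:
        """Mean coefficients keyed by column name (MMNL SD entries excluded)."""
        return {n: float(v) for n, v in zip(self.names, self.estimates) if not n.startswith("sd:")}

    @property
    def sigma(self) -> dict[str, float]:
        return {
            n[3:]: abs(float(v))
            for n, v in zip(self.names, self.estimates)
            if n.startswith("sd:")
        }

    def to_params(self) -> UtilityParams:
        return UtilityParams(beta=self.beta, sigma=self.sigma or None)

    def summary(self) -> pd.DataFrame:
        z = self.estimates / np.where(self.std_errors > 0, self.std_errors, np.nan)
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.estimates, "std_error": self.std_errors, "z": z, "p_value": p},
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "names": self.names,
            "estimates": self.estimates.tolist(),
            "std_errors": self.std_errors.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "gradient_norm": self.gradient_norm,
            "converged": self.converged,
            "n_respondents": self.n_respondents,
            "n_tasks": self.n_tasks,
            "n_iterations": self.n_iterations,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, doc: dict) -> "EstimationResult":
        doc = dict(doc)
        doc["estimates"] = np.asarray(doc["estimates"], dtype=float)
        doc["std_errors"] = np.asarray(doc["std_errors"], dtype=float)
        doc["vcov"] = np.asarray(doc["vcov"], dtype=float)
        return cls(**doc)

    @classmethod
    def from_json(cls, path: str | Path) -> "EstimationResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# utilities and probabilities


def systematic_utility(params: UtilityParams, coded_row, columns: list[str] | None = None) -> float:
    """Linear systematic utility ``x' beta`` of one coded alternative."""
    if isinstance(coded_row, pd.Series):
        cols = columns or [c for c in coded_row.index if c in params.beta]
        x = coded_row[cols].to_numpy(float)
    else:
        x = np.asarray(coded_row, dtype=float)
        cols = columns or params.names
    if len(x) != len(cols):
        raise ColumnMismatchError(f"row has {len(x)} values for {len(cols)} coefficients")
    return float(x @ params.beta_vector(cols))


def choice_probabilities(params: UtilityParams, task_rows, columns: list[str] | None = None) -> np.ndarray:
    """Logit choice probabilities over one task's alternatives.

    Stabilised by max-subtraction; entries are strictly positive and sum to 1.
    """
    if isinstance(task_rows, pd.DataFrame):
        cols = columns or [c for c in task_rows.columns if c in params.beta]
        X = task_rows[cols].to_numpy(float)
    else:
        X = np.asarray(task_rows, dtype=float)
        cols = columns or params.names
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("a task needs at least 2 alternatives")
    u = X @ params.beta_vector(cols)
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


# ---------------------------------------------------------------------------
# MNL likelihood and fit


def _mnl_ll_parts(beta: np.ndarray, X: np.ndarray, chosen: np.ndarray):
    """Log-likelihood, per-task score rows, and probabilities for MNL."""
    U = X @ beta  # (T, J)
    U = U - U.max(axis=1, keepdims=True)
    expU = np.exp(U)
    denom = expU.sum(axis=1)
    P = expU / denom[:, None]
    T = X.shape[0]
    ll = float(U[np.arange(T), chosen].sum() - np.log(denom).sum())
    xbar = np.einsum("tj,tjk->tk", P, X)
    score_rows = X[np.arange(T), chosen] - xbar  # (T, K)
    return ll, score_rows, P


def mnl_loglik(params, dataset: ChoiceDataset):
    """MNL log-likelihood and its analytic gradient on a dataset.

    ``params`` may be a :class:`UtilityParams` or a bare coefficient vector
    aligned with ``dataset.columns``.
    """
    X, chosen, _ = dataset.arrays()
    if isinstance(params, UtilityParams):
        beta = params.beta_vector(dataset.columns)
    else:
        beta = np.asarray(params, dtype=float)
        if beta.shape != (len(dataset.columns),):
            raise ColumnMismatchError("coefficient vector length does not match dataset columns")
    ll, score_rows, _ = _mnl_ll_parts(beta, X, chosen)
    return ll, score_rows.sum(axis=0)


def _mnl_hessian(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    U = X @ beta
    U = U - U.max(axis=1, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=1, keepdims=True)
    xbar = np.einsum("tj,tjk->tk", P, X)
    Xc = X - xbar[:, None, :]
    return -np.einsum("tj,tjk,tjl->kl", P, Xc, Xc)


def _check_rank(X2d: np.ndarray, columns: list[str]) -> None:
    """Raise CollinearityError naming columns involved in rank deficiency."""
    s = np.linalg.svd(X2d, compute_uv=False)
    tol = s.max() * max(X2d.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < X2d.shape[1]:
        _, _, vt = np.linalg.svd(X2d)
        null = vt[rank:]
        offending = sorted(
            {columns[j] for row in null for j in np.where(np.abs(row) > 1e-8)[0]}
        )
        raise CollinearityError(offending)


def fit_mnl(
    dataset: ChoiceDataset,
    tolerance: float = 1e-6,
    max_iter: int = 100,
    start: np.ndarray | None = None,
    cluster_se: bool = False,
) -> EstimationResult:
    """Maximum-likelihood MNL fit by damped Newton iterations.

    Converged when the gradient max-norm drops below ``tolerance`` or the
    relative log-likelihood change falls below 1e-9.  Standard errors come
    from the inverse observed information; ``cluster_se`` switches to a
    respondent-clustered sandwich.  Non-convergence (e.g. separation in the
    choice data) is flagged on the result, never raised.
    """
    X, chosen, resp_ix = dataset.arrays()
    K = X.shape[2]
    X2d = X.reshape(-1, K)
    _check_rank(X2d, dataset.columns)

    beta = np.zeros(K) if start is None else np.asarray(start, dtype=float).copy()
    ll, score_rows, _ = _mnl_ll_parts(beta, X, chosen)
    grad = score_rows.sum(axis=0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tolerance:
            converged = True
            break
        H = _mnl_hessian(beta, X)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = grad  # fallback to gradient ascent on singular Hessian
        # backtracking: concave LL, so full Newton almost always accepted
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_score_rows, _ = _mnl_ll_parts(new_beta, X, chosen)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        rel_change = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta, ll, score_rows = new_beta, new_ll, new_score_rows
        grad = score_rows.sum(axis=0)
        if np.max(np.abs(grad)) < tolerance or rel_change < 1e-9:
            # either stopping rule counts as convergence; runaway coefficients
            # (separation) are caught by the divergence guard below
            converged = True
            break

    H = _mnl_hessian(beta, X)
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.full((K, K), np.nan)
    if cluster_se:
        G = np.zeros((resp_ix.max() + 1, K))
        np.add.at(G, resp_ix, score_rows)
        bread = vcov
        vcov = bread @ (G.T @ G) @ bread
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    # coefficients this large on a coded-utility scale signal separation: the
    # likelihood flattens numerically and the gradient rule can fire spuriously
    diverged = bool(np.max(np.abs(beta)) > 10)
    return EstimationResult(
        model="MNL",
        names=list(dataset.columns),
        estimates=beta,
        std_errors=se,
        vcov=vcov,
        loglik=ll,
        gradient_norm=float(np.max(np.abs(grad))),
        converged=converged and not diverged,
        n_respondents=dataset.n_respondents,
        n_tasks=dataset.n_tasks_total,
        n_iterations=it,
        metadata={
            "cluster_se": cluster_se,
            **({"divergence_suspected": True} if diverged else {}),
            **dataset.metadata,
        },
    )


# ---------------------------------------------------------------------------
# Halton draws


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n**0.5) + 1))


def _primes(k: int) -> list[int]:
    out, n = [], 2
    while len(out) < k:
        if _is_prime(n):
            out.append(n)
        n += 1
    return out


def halton_sequence(base: int, n: int, drop: int = 0) -> np.ndarray:
    """Radical-inverse Halton sequence in a prime base, values in (0, 1).

    The first ``drop`` elements are discarded (burn-in against start-up
    correlation across bases).
    """
    if not _is_prime(base):
        raise ValueError(f"Halton base must be prime, got {base}")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(drop + 1, drop + n + 1, dtype=np.int64)
    out = np.zeros(n)
    f = 1.0
    while idx.any():
        f /= base
        out += f * (idx % base)
        idx //= base
    return out


def halton_normal_draws(n_params: int, n_points: int, drop: int = 10) -> np.ndarray:
    """Standard-normal quasi-random draws, one Halton base per parameter.

    Returns shape ``(n_points, n_params)``; bases are the successive primes
    2, 3, 5, ... assigned in column order.
    """
    bases = _primes(n_params)
    u = np.stack([halton_sequence(b, n_points, drop=drop) for b in bases], axis=1)
    return norm.ppf(u)


# ---------------------------------------------------------------------------
# MMNL simulated likelihood


def _mmnl_sll_grad(theta: np.ndarray, X: np.ndarray, chosen: np.ndarray,
                   task_resp: np.ndarray, Z: np.ndarray):
    """Simulated log-likelihood and gradient for panel MMNL.

    theta = (b, s) each length K.  Z has shape (R, D, K): one draw vector per
    respondent reused across their tasks.  Probability products over tasks are
    accumulated in log space and averaged over draws with logsumexp.
    """
    K = X.shape[2]
    R, D, _ = Z.shape
    b, s = theta[:K], theta[K:]
    beta_rd = b[None, None, :] + s[None, None, :] * Z  # (R, D, K)

    # tasks of many respondents are stacked along T: evaluate each task's
    # utilities against the owning respondent's draw vectors
    T, J, _ = X.shape
    beta_task = beta_rd[task_resp]          # (T, D, K)
    U = np.einsum("tjk,tdk->tdj", X, beta_task)  # (T, D, J)
    Umax = U.max(axis=2, keepdims=True)
    logdenom = np.log(np.exp(U - Umax).sum(axis=2)) + Umax[:, :, 0]  # (T, D)
    logp_chosen = U[np.arange(T), :, chosen] - logdenom              # (T, D)

    # per-respondent per-draw log product over tasks
    logL_rd = np.zeros((R, D))
    np.add.at(logL_rd, task_resp, logp_chosen)
    m = logL_rd.max(axis=1, keepdims=True)
    w = np.exp(logL_rd - m)
    sumw = w.sum(axis=1)
    sll = float((m[:, 0] + np.log(sumw)).sum() - R * np.log(D))
    W = w / sumw[:, None]  # (R, D) posterior draw weights

    # score wrt beta per task-draw: x_chosen - sum_j p_j x_j
    P = np.exp(U - logdenom[:, :, None])  # (T, D, J)
    xbar = np.einsum("tdj,tjk->tdk", P, X)
    g = X[np.arange(T), chosen][:, None, :] - xbar  # (T, D, K)

    Wt = W[task_resp]  # (T, D)
    grad_b = np.einsum("td,tdk->k", Wt, g)
    Zt = Z[task_resp]  # (T, D, K)
    grad_s = np.einsum("td,tdk,tdk->k", Wt, g, Zt)
    return sll, np.concatenate([grad_b, grad_s])


def fit_mmnl(
    dataset: ChoiceDataset,
    n_draws: int = 1000,
    seed: int = 0,
    tolerance: float = 1e-5,
    max_iter: int = 300,
    start: np.ndarray | None = None,
    random_names: list[str] | None = None,
    drop: int = 10,
    compute_se: bool = True,
) -> EstimationResult:
    """Panel mixed-logit fit by maximum simulated likelihood with Halton draws.

    All coefficients are normally distributed by default (``random_names``
    restricts which get a nonzero SD).  Respondent draws come from a shared
    Halton sequence (successive prime bases, first ``drop`` points dropped)
    partitioned across respondents, so results are deterministic given
    ``n_draws``; ``seed`` is recorded for provenance and reserved for
    scrambled variants.  SDs are estimated unconstrained and reported as
    absolute values.
    """
    X, chosen, task_resp = dataset.arrays()
    K = X.shape[2]
    R = int(task_resp.max()) + 1
    cols = list(dataset.columns)
    if random_names is None:
        random_names = cols
    rand_mask = np.array([c in random_names for c in cols], dtype=float)

    Zall = halton_normal_draws(K, R * n_draws, drop=drop)
    Z = Zall.reshape(R, n_draws, K) * rand_mask

    if start is None:
        mnl = fit_mnl(dataset)
        start_b = mnl.estimates
    else:
        start_b = np.asarray(start, dtype=float)
    theta0 = np.concatenate([start_b, 0.1 * rand_mask])

    def negf(theta):
        sll, grad = _mmnl_sll_grad(theta, X, chosen, task_resp, Z)
        return -sll, -grad

    res = optimize.minimize(
        negf, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tolerance, "ftol": 1e-11},
    )
    theta = res.x
    sll, grad = _mmnl_sll_grad(theta, X, chosen, task_resp, Z)

    free = np.concatenate([np.ones(K, bool), rand_mask.astype(bool)])
    vcov = np.full((2 * K, 2 * K), np.nan)
    if compute_se:
        # observed-information SEs via numerically differentiated analytic gradient
        eps = 1e-5
        H = np.zeros((2 * K, 2 * K))
        for i in range(2 * K):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            _, gp = _mmnl_sll_grad(tp, X, chosen, task_resp, Z)
            _, gm = _mmnl_sll_grad(tm, X, chosen, task_resp, Z)
            H[i] = (gp - gm) / (2 * eps)
        H = (H + H.T) / 2
        try:
            vcov_free = np.linalg.inv(-H[np.ix_(free, free)])
            vcov[np.ix_(free, free)] = vcov_free
        except np.linalg.LinAlgError:
            pass
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    estimates = theta.copy()
    estimates[K:] = np.abs(estimates[K:])  # SDs reported as |s|
    names = cols + [f"sd:{c}" for c in cols]
    converged = bool(res.success and np.max(np.abs(grad[free])) < 1e-2)
    return EstimationResult(
        model="MMNL",
        names=names,
        estimates=estimates,
        std_errors=se,
        vcov=vcov,
        loglik=sll,
        gradient_norm=float(np.max(np.abs(grad[free]))),
        converged=converged,
        n_respondents=dataset.n_respondents,
        n_tasks=dataset.n_tasks_total,
        n_iterations=int(res.nit),
        n_draws=n_draws,
        seed=seed,
        metadata={"random_names": list(random_names), "halton_drop": drop, **dataset.metadata},
    )


def mmnl_simulated_loglik(params: UtilityParams, dataset: ChoiceDataset,
                          n_draws: int = 1000, drop: int = 10) -> float:
    """Simulated panel log-likelihood at fixed parameters (no fitting)."""
    X, chosen, task_resp = dataset.arrays()
    K = X.shape[2]
    R = int(task_resp.max()) + 1
    cols = list(dataset.columns)
    Z = halton_normal_draws(K, R * n_draws, drop=drop).reshape(R, n_draws, K)
    theta = np.concatenate([params.beta_vector(cols), params.sigma_vector(cols)])
    sll, _ = _mmnl_sll_grad(theta, X, chosen, task_resp, Z)
    return sll


# ---------------------------------------------------------------------------
# effects-coding bookkeeping


def implied_level_utilities(result: EstimationResult, attributes: list[AttributeSpec]) -> pd.DataFrame:
    """Per-level utilities for every effects-coded attribute, reference included.

    The reference level's utility is minus the sum of the estimated level
    coefficients, so level utilities sum to zero within each attribute.
    """
    beta = result.beta
    rows = []
    for attr in attributes:
        if attr.coding != "effects":
            continue
        names = attr.column_names()
        vals = [beta[n] for n in names]
        codes = list(attr.level_codes)
        for lv, code, v in zip(attr.levels[:-1], codes[:-1], vals):
            rows.append({"attribute": attr.name, "level": lv, "code": code, "utility": v})
        rows.append(
            {
                "attribute": attr.name,
                "level": attr.levels[-1],
                "code": codes[-1],
                "utility": -sum(vals),
            }
        )
    if OPT_OUT_COLUMN in beta:
        rows.append(
            {
                "attribute": OPT_OUT_COLUMN,
                "level": "Neither",
                "code": OPT_OUT_COLUMN,
                "utility": beta[OPT_OUT_COLUMN],
            }
        )
    return pd.DataFrame(rows)
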