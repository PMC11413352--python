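"""Undirected-network track: regularized partial-correlation networks.

Estimation follows the standard psychometric-network recipe: z-score the
variables, compute the correlation matrix, fit the graphical lasso over a
log-spaced penalty path, and select the penalty by the Extended Bayesian
Information Criterion (EBIC) with hyperparameter gamma (default 0.5).  Edge
accuracy is assessed by a nonparametric subject-level bootstrap, and node
predictability (shared variance R^2 of a node given its neighbors) gives an
absolute measure of interconnectedness.

The graphical-lasso solver is a blockwise coordinate descent over

    max_Theta  log det Theta - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

with an unpenalized diagonal, compiled with numba; stationarity (KKT) is
verified on the returned estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .core_graph import UndirectedEdgeSet

__all__ = [
    "ConvergenceError",
    "StandardizedTable",
    "GgmFit",
    "EdgeBootstrap",
    "standardize",
    "pearson_network",
    "unregularized_partial_corr",
    "glasso_solve",
    "kkt_residual",
    "ebic",
    "ebic_glasso",
    "bootstrap_edges",
    "predictability",
]


class ConvergenceError(RuntimeError):
    """Raised when the graphical-lasso solver fails its KKT tolerance."""


# ---------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizedTable:
    """n-by-p data with column means 0 and sample SDs 1 (ddof=1)."""

    values: np.ndarray
    variable_names: tuple[str, ...]
    group_label: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _as_matrix(table) -> tuple[np.ndarray, tuple[str, ...], str]:
    """Accept a SampleTable, StandardizedTable, DataFrame or ndarray."""
    if isinstance(table, StandardizedTable):
        return np.asarray(table.values, float), table.variable_names, table.group_label
    if isinstance(table, pd.DataFrame):
        num = table.select_dtypes("number")
        return num.to_numpy(float), tuple(num.columns), ""
    if hasattr(table, "values") and hasattr(table, "variable_names"):
        return (
            np.asarray(table.values, float),
            tuple(table.variable_names),
            getattr(table, "group_label", ""),
        )
    arr = np.asarray(table, float)
    return arr, tuple(f"V{i}" for i in range(arr.shape[1])), ""


def standardize(table) -> StandardizedTable:
    """Column-wise z-scores: (x - mean) / SD with sample SD (ddof=1).

    Requires complete data (listwise deletion already applied).  Raises on
    constant columns, naming the offender; warns when n < p + 1.
    """
    X, names, label = _as_matrix(table)
    if np.isnan(X).any():
        raise ValueError("missing values present; apply listwise deletion first")
    n, p = X.shape
    if n < p + 1:
        warnings.warn(f"n={n} < p+1={p + 1}: standardization/fits may be unstable")
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {names[j]!r} is constant; cannot standardize")
    Z = (X - X.mean(axis=0)) / sd
    return StandardizedTable(values=Z, variable_names=names, group_label=label)


def pearson_network(std_table) -> np.ndarray:
    """Symmetric Pearson correlation matrix with unit diagonal."""
    X, _, _ = _as_matrix(std_table)
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def unregularized_partial_corr(std_table) -> np.ndarray:
    """Partial correlations from the inverse correlation matrix.

    rho_ij = -omega_ij / sqrt(omega_ii * omega_jj); unit diagonal by
    convention.  Raises on a singular correlation matrix.
    """
    R = pearson_network(std_table)
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular") from e
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return (pc + pc.T) / 2.0


# ---------------------------------------------------------------------
# graphical lasso (blockwise coordinate descent, numba)
# ---------------------------------------------------------------------


@njit(cache=True)
def _glasso_kernel(S, lam, W, B, tol, max_sweeps):  # pragma: no cover - compiled
    """One graphical-lasso solve; W (working covariance) and B (lasso
    coefficients per column) are carried between calls for warm starts.
    Returns the final max column-update change."""
    p = S.shape[0]
    maxd = 0.0
    for _sweep in range(max_sweeps):
        maxd = 0.0
        for j in range(p):
            # inner lasso: 0.5 b'W11 b - s12'b + lam |b|_1
            for _inner in range(1000):
                maxb = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    acc = 0.0
                    for m in range(p):
                        if m != j and m != k:
                            acc += W[k, m] * B[m, j]
                    r = S[k, j] - acc
                    if r > lam:
                        bn = (r - lam) / W[k, k]
                    elif r < -lam:
                        bn = (r + lam) / W[k, k]
                    else:
                        bn = 0.0
                    d = bn - B[k, j]
                    if d < 0.0:
                        d = -d
                    if d > maxb:
                        maxb = d
                    B[k, j] = bn
                if maxb < tol * 0.1:
                    break
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for m in range(p):
                    if m != j:
                        acc += W[k, m] * B[m, j]
                d = acc - W[k, j]
                if d < 0.0:
                    d = -d
                if d > maxd:
                    maxd = d
                W[k, j] = acc
                W[j, k] = acc
        if maxd < tol:
            break
    return maxd


@njit(cache=True)
def _theta_from_wb(W, B):  # pragma: no cover - compiled
    p = W.shape[0]
    T = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for m in range(p):
            if m != j:
                acc += W[m, j] * B[m, j]
        tjj = 1.0 / (W[j, j] - acc)
        T[j, j] = tjj
        for m in range(p):
            if m != j and B[m, j] != 0.0:
                T[m, j] = -B[m, j] * tjj
    for i in range(p):
        for k in range(i + 1, p):
            if T[i, k] == 0.0 and T[k, i] == 0.0:
                continue
            v = 0.5 * (T[i, k] + T[k, i])
            T[i, k] = v
            T[k, i] = v
    return T


@njit(cache=True)
def _glasso_path_kernel(S, lambdas, n, gamma, tol, max_sweeps, count_tol):  # pragma: no cover
    """Fit the whole (descending) lambda path with warm starts; returns the
    stacked precision estimates and their EBIC values.  Entries below
    ``count_tol`` in magnitude do not count toward the EBIC edge count
    (they are numerical noise, zeroed in the final conversion too)."""
    p = S.shape[0]
    nl = lambdas.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    thetas = np.empty((nl, p, p))
    ebics = np.empty(nl)
    logp = np.log(p)
    logn = np.log(n)
    for i in range(nl):
        _glasso_kernel(S, lambdas[i], W, B, tol, max_sweeps)
        T = _theta_from_wb(W, B)
        thetas[i] = T
        L = np.linalg.cholesky(T)
        logdet = 0.0
        for k in range(p):
            logdet += 2.0 * np.log(L[k, k])
        tr = 0.0
        for a in range(p):
            for b in range(p):
                tr += S[a, b] * T[b, a]
        ll = 0.5 * n * (logdet - tr)
        E = 0
        for a in range(p):
            for b in range(a + 1, p):
                if abs(T[a, b]) > count_tol:
                    E += 1
        ebics[i] = -2.0 * ll + E * logn + 4.0 * E * gamma * logp
    return thetas, ebics


def kkt_residual(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Max stationarity violation of a graphical-lasso candidate.

    At the optimum, S - Theta^{-1} = -lambda * sign(Theta_ij) on nonzero
    off-diagonals, |S - Theta^{-1}| <= lambda on zero off-diagonals, and the
    diagonal matches exactly (unpenalized).
    """
    R = S - np.linalg.inv(theta)
    p = S.shape[0]
    resid = np.abs(np.diag(R)).max() if p else 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if theta[i, j] != 0.0:
                resid = max(resid, abs(R[i, j] + lam * np.sign(theta[i, j])))
            else:
                resid = max(resid, max(0.0, abs(R[i, j]) - lam))
    return float(resid)


def glasso_solve(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Solve the graphical lasso at one penalty; returns the precision matrix.

    The diagonal is unpenalized.  Convergence is certified by the KKT
    stationarity residual: the solver re-runs with tighter inner tolerances
    until the residual is <= ``tol`` or raises :class:`ConvergenceError`.
    """
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    W = S.copy()
    B = np.zeros_like(S)
    inner_tol = min(tol * 1e-3, 1e-7)
    resid = np.inf
    for _attempt in range(4):
        _glasso_kernel(S, lam, W, B, inner_tol, max_iter)
        theta = _theta_from_wb(W, B)
        resid = kkt_residual(S, theta, lam)
        if resid <= tol:
            return theta
        inner_tol *= 1e-2
        max_iter *= 2
    raise ConvergenceError(f"graphical lasso did not converge: KKT residual {resid:.3g}")


def ebic(precision: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """EBIC of a precision estimate: -2 L + E log n + 4 E gamma log p,
    with L = (n/2)(log det Theta - tr(S Theta)) and E the number of nonzero
    upper-triangle off-diagonal entries."""
    precision = np.asarray(precision, float)
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = precision.shape[0]
    ll = 0.5 * n * (logdet - float(np.sum(S * precision)))
    E = int(np.count_nonzero(np.triu(precision, 1)))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


# ---------------------------------------------------------------------
# EBIC model selection
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class GgmFit:
    """A selected Gaussian graphical model."""

    partial_corr: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    ebic_value: float
    edge_set: UndirectedEdgeSet
    predictability: dict[str, float]
    variable_names: tuple[str, ...]
    lambda_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    ebic_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def edge_weight(self, a: str, b: str) -> float:
        i, j = self.variable_names.index(a), self.variable_names.index(b)
        return float(self.partial_corr[i, j])

    def global_strength(self) -> float:
        """Sum of absolute partial correlations over unordered pairs."""
        return float(np.abs(np.triu(self.partial_corr, 1)).sum())

    def edge_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b in self.edge_set.sorted_pairs():
            rows.append({"node_a": a, "node_b": b, "partial_correlation": self.edge_weight(a, b)})
        return pd.DataFrame(rows, columns=["node_a", "node_b", "partial_correlation"])

    def to_graphml(self, path: str) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.variable_names)
        for a, b in self.edge_set.sorted_pairs():
            g.add_edge(a, b, weight=self.edge_weight(a, b))
        nx.write_graphml(g, path)


def _partial_from_precision(theta: np.ndarray, sparsify_tol: float) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc = (pc + pc.T) / 2.0
    pc[np.abs(pc) < sparsify_tol] = 0.0
    return pc


def _lambda_path(S: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    lam_max = float(np.abs(S - np.diag(np.diag(S))).max())
    if lam_max <= 0:
        return np.zeros(1)
    path = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)
    path[0] = lam_max  # logspace round-trips the endpoint one ulp off
    return path


def _fit_precision_path(X: np.ndarray, gamma, n_lambda, lambda_min_ratio, tol, count_tol=1e-7):
    """Correlation -> descending-lambda path -> EBIC-minimizing precision."""
    n = X.shape[0]
    S = np.corrcoef(X, rowvar=False)
    S = (S + S.T) / 2.0
    lambdas = _lambda_path(S, n_lambda, lambda_min_ratio)
    thetas, ebics = _glasso_path_kernel(S, lambdas, n, gamma, tol, 500, count_tol)
    best = int(np.argmin(ebics))
    return thetas[best], float(lambdas[best]), float(ebics[best]), S, lambdas, ebics


def ebic_glasso(
    std_table,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    sparsify_tol: float = 1e-7,
    tol: float = 1e-7,
) -> GgmFit:
    """EBIC-selected graphical lasso on standardized data.

    The penalty path is log-spaced on [lambda_max * ratio, lambda_max] with
    lambda_max the largest absolute off-diagonal correlation; the fit with
    minimum EBIC is selected and converted to partial correlations.  Entries
    with |rho| below ``sparsify_tol`` (numerical-noise level) are set to
    exactly zero and excluded from the edge set.
    """
    table = std_table if isinstance(std_table, StandardizedTable) else standardize(std_table)
    X = table.values
    theta, lam, ebic_val, S, lambdas, ebics = _fit_precision_path(
        X, gamma, n_lambda, lambda_min_ratio, tol, count_tol=sparsify_tol
    )
    resid = kkt_residual(S, theta, lam)
    if resid > 1e-4:
        theta = glasso_solve(S, lam, tol=1e-4)
    pc = _partial_from_precision(theta, sparsify_tol)
    names = table.variable_names
    pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if pc[i, j] != 0.0
    ]
    fit = GgmFit(
        partial_corr=pc,
        precision=theta,
        lambda_selected=lam,
        ebic_value=ebic_val,
        edge_set=UndirectedEdgeSet.from_pairs(names, pairs),
        predictability={},
        variable_names=names,
        lambda_path=lambdas,
        ebic_path=ebics,
    )
    return replace(fit, predictability=predictability(table, fit))


# ---------------------------------------------------------------------
# bootstrap edge accuracy
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeBootstrap:
    """Per-edge bootstrap point estimates and quantile bounds (level 0.95).

    ``point`` may fall outside [lower, upper] for regularized estimators
    under resampling; that is recorded, not enforced.
    """

    variable_names: tuple[str, ...]
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    level: float = 0.95

    def edge_dataframe(self) -> pd.DataFrame:
        names = self.variable_names
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "node_a": names[i],
                        "node_b": names[j],
                        "partial_correlation": float(self.point[i, j]),
                        "ci_lower": float(self.lower[i, j]),
                        "ci_upper": float(self.upper[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_edges(
    std_table,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    sparsify_tol: float = 1e-7,
) -> EdgeBootstrap:
    """Nonparametric subject bootstrap of the EBIC-glasso edge estimates.

    Whole rows are resampled with replacement at the original n; each
    resample is re-standardized and refit; per-edge 2.5%/97.5% quantile
    bounds are returned alongside the full-sample point estimates.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    table = std_table if isinstance(std_table, StandardizedTable) else standardize(std_table)
    X = table.values
    n, p = X.shape
    rng = np.random.default_rng(seed)
    fit = ebic_glasso(table, gamma, n_lambda, lambda_min_ratio, sparsify_tol)
    reps = np.empty((B, p, p))
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        Xb = X[rows]
        Xb = (Xb - Xb.mean(axis=0)) / Xb.std(axis=0, ddof=1)
        theta, _, _, _, _, _ = _fit_precision_path(
            Xb, gamma, n_lambda, lambda_min_ratio, 1e-7, count_tol=sparsify_tol
        )
        reps[b] = _partial_from_precision(theta, sparsify_tol)
    lower = np.quantile(reps, 0.025, axis=0)
    upper = np.quantile(reps, 0.975, axis=0)
    return EdgeBootstrap(
        variable_names=table.variable_names,
        point=fit.partial_corr,
        lower=lower,
        upper=upper,
        B=B,
    )


def predictability(std_table, ggm_fit: GgmFit) -> dict[str, float]:
    """Per-node shared variance: OLS R^2 of each node on its GGM neighbors.

    Isolated nodes get 0.  This is a reproducible, oracle-checkable reading
    of node predictability computed from the selected network itself.
    """
    table = std_table if isinstance(std_table, StandardizedTable) else standardize(std_table)
    X = table.values
    names = table.variable_names
    out: dict[str, float] = {}
    for j, v in enumerate(names):
        nb = [i for i, u in enumerate(names) if i != j and ggm_fit.partial_corr[i, j] != 0.0]
        if not nb:
            out[v] = 0.0
            continue
        y = X[:, j]
        A = np.column_stack([np.ones(len(y)), X[:, nb]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ coef) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        out[v] = 1.0 - rss / tss
    return out


def predictability_dataframe(pred: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"node": k, "r_squared": v} for k, v in pred.items()], columns=["node", "r_squared"]
    )
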