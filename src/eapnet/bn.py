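"""Directed-network track: score-based Bayesian network structure learning.

Gaussian networks are scored with the decomposable Bayesian Information
Criterion: each node contributes the maximized Gaussian log-likelihood of
its least-squares regression on its parents (ML residual variance,
denominator n) minus (k/2) log n with k = |parents| + 2 (intercept, slopes
and residual variance).  This parameter count preserves score equivalence:
Markov-equivalent DAGs receive identical scores.

Structure search is greedy hill-climbing from the empty DAG over single-arc
additions, deletions and reversals that keep the graph acyclic, with a
deterministic lexicographic tie-break on (operation, parent, child) in the
canonical column order; by default each search also runs perturbation
restarts (perturb the incumbent best DAG, re-climb, keep the better score)
because the plain greedy climb provably stalls in local optima when several
arc orientations score nearly identically.  Stability is assessed with a
subject-level bootstrap: arcs are tallied by presence (direction-blind)
and, conditional on presence, by orientation; the averaged network keeps
pairs present in at least 85% of bootstrap DAGs and oriented one way in at
least 51% of those.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core_graph import Dag, GraphInputError
from .ggm import StandardizedTable, _as_matrix, standardize

__all__ = [
    "ArcStrengthTable",
    "FittedBn",
    "local_bic_gaussian",
    "network_bic",
    "hill_climb",
    "bootstrap_arc_strength",
    "averaged_network",
    "fit_betas",
]

NEG_INF = -1e300


# ---------------------------------------------------------------------
# compiled scoring + search kernels
# ---------------------------------------------------------------------


@njit(cache=True)
def _local_score(C, n, j, adj, add_u, rem_u):  # pragma: no cover - compiled
    """BIC contribution of node j given its parents in adj[:, j], with
    optional single-parent modification (add_u / rem_u, -1 for none).
    C is the ML covariance (denominator n)."""
    p = C.shape[0]
    idx = np.empty(p, np.int64)
    k = 0
    for u in range(p):
        pa = adj[u, j] == 1
        if u == rem_u:
            pa = False
        if u == add_u:
            pa = True
        if pa and u != j:
            idx[k] = u
            k += 1
    if k == 0:
        s2 = C[j, j]
    else:
        Cxx = np.empty((k, k))
        cxy = np.empty(k)
        for a in range(k):
            cxy[a] = C[idx[a], j]
            for b in range(k):
                Cxx[a, b] = C[idx[a], idx[b]]
        beta = np.linalg.solve(Cxx, cxy)
        s2 = C[j, j]
        for a in range(k):
            s2 -= cxy[a] * beta[a]
    if s2 < 1e-12:
        return NEG_INF
    logn = np.log(n)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0) - 0.5 * (k + 2) * logn


@njit(cache=True)
def _reaches(adj, a, b):  # pragma: no cover - compiled
    """True iff a directed path a ->* b exists (including a == b)."""
    p = adj.shape[0]
    if a == b:
        return True
    stack = np.empty(p, np.int64)
    visited = np.zeros(p, np.uint8)
    top = 0
    stack[top] = a
    top += 1
    visited[a] = 1
    while top > 0:
        top -= 1
        v = stack[top]
        for c in range(p):
            if adj[v, c] == 1 and visited[c] == 0:
                if c == b:
                    return True
                visited[c] = 1
                stack[top] = c
                top += 1
    return False


@njit(cache=True)
def _hill_climb_kernel(C, n, adj, tie_tol):  # pragma: no cover - compiled
    """Greedy BIC hill-climbing from the DAG in ``adj`` (modified in place).

    Moves are scanned in lexicographic (operation, parent, child) order with
    operation order addition < deletion < reversal; a candidate replaces the
    incumbent best only on a strict improvement, so the first-scanned member
    of any exact tie wins.  ``tie_tol`` is the minimum score gain counted as
    an improvement (guards against floating-point cycling).  Returns the
    final total score.
    """
    p = C.shape[0]
    sc = np.empty(p)
    for j in range(p):
        sc[j] = _local_score(C, n, j, adj, -1, -1)
    for _step in range(10000):
        best_delta = tie_tol
        best_op = -1
        best_u = -1
        best_v = -1
        # additions
        for u in range(p):
            for v in range(p):
                if u == v or adj[u, v] == 1 or adj[v, u] == 1:
                    continue
                if _reaches(adj, v, u):
                    continue
                delta = _local_score(C, n, v, adj, u, -1) - sc[v]
                if delta > best_delta:
                    best_delta = delta
                    best_op = 0
                    best_u = u
                    best_v = v
        # deletions
        for u in range(p):
            for v in range(p):
                if adj[u, v] != 1:
                    continue
                delta = _local_score(C, n, v, adj, -1, u) - sc[v]
                if delta > best_delta:
                    best_delta = delta
                    best_op = 1
                    best_u = u
                    best_v = v
        # reversals
        for u in range(p):
            for v in range(p):
                if adj[u, v] != 1:
                    continue
                adj[u, v] = 0
                ok = not _reaches(adj, u, v)
                adj[u, v] = 1
                if not ok:
                    continue
                delta = (_local_score(C, n, v, adj, -1, u) - sc[v]) + (
                    _local_score(C, n, u, adj, v, -1) - sc[u]
                )
                if delta > best_delta:
                    best_delta = delta
                    best_op = 2
                    best_u = u
                    best_v = v
        if best_op < 0:
            break
        if best_op == 0:
            adj[best_u, best_v] = 1
            sc[best_v] = _local_score(C, n, best_v, adj, -1, -1)
        elif best_op == 1:
            adj[best_u, best_v] = 0
            sc[best_v] = _local_score(C, n, best_v, adj, -1, -1)
        else:
            adj[best_u, best_v] = 0
            adj[best_v, best_u] = 1
            sc[best_v] = _local_score(C, n, best_v, adj, -1, -1)
            sc[best_u] = _local_score(C, n, best_u, adj, -1, -1)
    total = 0.0
    for j in range(p):
        total += sc[j]
    return total


@njit(cache=True)
def _hill_climb_restarts(C, n, adj, tie_tol, restarts, perturb, seed):  # pragma: no cover
    """Hill-climbing with perturbation restarts.

    After the first climb, each restart perturbs the incumbent best DAG
    (random arc reversals/deletions/additions that keep it acyclic) and
    re-climbs, keeping the higher-scoring result.  This escapes the local
    optima that plain greedy search falls into when several orientations of
    an arc score nearly identically.  Deterministic given ``seed``.
    """
    np.random.seed(seed)
    p = C.shape[0]
    best = _hill_climb_kernel(C, n, adj, tie_tol)
    best_adj = adj.copy()
    work = np.empty_like(adj)
    for _r in range(restarts):
        work[:] = best_adj
        for _k in range(perturb):
            na = 0
            for u in range(p):
                for v in range(p):
                    if work[u, v] == 1:
                        na += 1
            if na == 0:
                break
            mode = np.random.random()
            if mode < 0.75:
                kth = int(np.random.random() * na)
                cnt = 0
                uu = -1
                vv = -1
                for u in range(p):
                    for v in range(p):
                        if work[u, v] == 1:
                            if cnt == kth:
                                uu = u
                                vv = v
                            cnt += 1
                work[uu, vv] = 0
                if mode < 0.5 and not _reaches(work, uu, vv):
                    work[vv, uu] = 1  # reverse; else plain deletion
            else:
                u = int(np.random.random() * p)
                v = int(np.random.random() * p)
                if u != v and work[u, v] == 0 and work[v, u] == 0 and not _reaches(work, v, u):
                    work[u, v] = 1
        s2 = _hill_climb_kernel(C, n, work, tie_tol)
        if s2 > best + tie_tol:
            best = s2
            best_adj[:] = work
    adj[:] = best_adj
    return best


# ---------------------------------------------------------------------
# public scoring API
# ---------------------------------------------------------------------


def _ml_cov(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / X.shape[0]


def _std_values(std_table) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(std_table, StandardizedTable):
        return std_table.values, std_table.variable_names
    table = standardize(std_table)
    return table.values, table.variable_names


def local_bic_gaussian(std_table, node: str, parent_set) -> float:
    """Gaussian BIC contribution of one node given a parent set.

    Larger is better.  Raises on collinear parents and on an (effectively)
    noise-free linear dependence, where the ML residual variance degenerates.
    """
    X, names = _std_values(std_table)
    parents = list(parent_set)
    if node in parents:
        raise ValueError("parent set may not contain the node itself")
    for v in (node, *parents):
        if v not in names:
            raise ValueError(f"unknown variable {v!r}")
    n = X.shape[0]
    j = names.index(node)
    idx = [names.index(v) for v in parents]
    if idx:
        A = X[:, idx]
        if np.linalg.matrix_rank(A - A.mean(axis=0)) < len(idx):
            raise ValueError(f"collinear parents for node {node!r}")
    C = _ml_cov(X)
    adj = np.zeros((len(names), len(names)), np.uint8)
    for i in idx:
        adj[i, j] = 1
    score = _local_score(C, float(n), j, adj, -1, -1)
    if score <= NEG_INF:
        raise ValueError(f"degenerate (near noise-free) fit for node {node!r}")
    return float(score)


def network_bic(std_table, dag: Dag) -> float:
    """Sum of local Gaussian BIC scores over all nodes; decomposable."""
    X, names = _std_values(std_table)
    if set(dag.nodes) != set(names):
        raise ValueError("DAG nodes must match table variables")
    return float(
        sum(local_bic_gaussian(std_table, v, dag.parents(v)) for v in dag.nodes)
    )


# ---------------------------------------------------------------------
# fitted networks
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class FittedBn:
    """A DAG with per-arc standardized betas and per-node Gaussian params."""

    dag: Dag
    betas: dict[tuple[str, str], float]
    intercepts: dict[str, float]
    residual_variances: dict[str, float]
    bic_total: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.dag.nodes),
                "arcs": [
                    {"parent": a, "child": b, "beta": self.betas[(a, b)]}
                    for a, b in self.dag.sorted_arcs()
                ],
                "intercepts": {k: self.intercepts[k] for k in self.dag.nodes},
                "residual_variances": {k: self.residual_variances[k] for k in self.dag.nodes},
                "bic_total": self.bic_total,
            },
            indent=2,
        )


def fit_betas(std_table, dag: Dag) -> FittedBn:
    """Refit the final DAG: per node, OLS on its parents.

    Arc betas are the parents' standardized coefficients; residual variances
    are ML (denominator n); ``bic_total`` equals ``network_bic`` on the same
    data.
    """
    X, names = _std_values(std_table)
    if set(dag.nodes) != set(names):
        raise ValueError("DAG nodes must match table variables")
    n = X.shape[0]
    col = {v: k for k, v in enumerate(names)}
    betas: dict[tuple[str, str], float] = {}
    intercepts: dict[str, float] = {}
    residvar: dict[str, float] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        y = X[:, col[v]]
        if parents:
            A = np.column_stack([np.ones(n)] + [X[:, col[u]] for u in parents])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ValueError(f"collinear parents for node {v!r}")
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            intercepts[v] = float(coef[0])
            for k, u in enumerate(parents):
                betas[(u, v)] = float(coef[1 + k])
            resid = y - A @ coef
        else:
            intercepts[v] = float(y.mean())
            resid = y - y.mean()
        residvar[v] = float(np.sum(resid**2) / n)
    return FittedBn(
        dag=dag,
        betas=betas,
        intercepts=intercepts,
        residual_variances=residvar,
        bic_total=network_bic(std_table, dag),
    )


def _adj_to_dag(adj: np.ndarray, names: tuple[str, ...]) -> Dag:
    arcs = [
        (names[u], names[v])
        for u in range(len(names))
        for v in range(len(names))
        if adj[u, v] == 1
    ]
    return Dag.from_arcs(names, arcs)


def hill_climb(
    std_table, restarts: int = 20, seed: int | None = None, perturb: int = 5
) -> FittedBn:
    """Greedy BIC hill-climbing from the empty DAG; see module docstring.

    With ``restarts`` > 0 (the default), each restart perturbs the incumbent
    best DAG by up to ``perturb`` random acyclicity-preserving arc changes
    and re-climbs, keeping the best-scoring result (the incumbent wins
    ties).  ``restarts=0`` gives the plain single greedy climb.
    Deterministic given ``seed`` (None acts as 0).
    """
    X, names = _std_values(std_table)
    n = float(X.shape[0])
    C = _ml_cov(X)
    p = len(names)
    tie_tol = 1e-9 * max(n, 1.0)
    adj = np.zeros((p, p), np.uint8)
    if restarts > 0:
        _hill_climb_restarts(C, n, adj, tie_tol, restarts, perturb, 0 if seed is None else seed)
    else:
        _hill_climb_kernel(C, n, adj, tie_tol)
    return fit_betas(std_table, _adj_to_dag(adj, names))


# ---------------------------------------------------------------------
# bootstrap arc strength and model averaging
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ArcStrengthTable:
    """Bootstrap presence and orientation frequencies per node pair.

    ``strength(a, b)``: fraction of bootstrap DAGs containing the pair in
    either direction; ``direction(a, b)``: among those DAGs, the fraction
    oriented a -> b (so direction(a, b) + direction(b, a) = 1 whenever the
    pair ever appears).
    """

    variable_names: tuple[str, ...]
    pair_counts: dict[frozenset, int] = field(default_factory=dict)
    direction_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    B: int = 0

    def strength(self, a: str, b: str) -> float:
        return self.pair_counts.get(frozenset((a, b)), 0) / self.B

    def direction(self, a: str, b: str) -> float:
        total = self.pair_counts.get(frozenset((a, b)), 0)
        if total == 0:
            return 0.0
        return self.direction_counts.get((a, b), 0) / total

    def to_dataframe(self) -> pd.DataFrame:
        """One row per observed pair, oriented by majority direction;
        columns mirror the conventional arc-strength output (from, to,
        strength, direction)."""
        order = {v: i for i, v in enumerate(self.variable_names)}
        rows = []
        for pair, cnt in self.pair_counts.items():
            if cnt == 0:
                continue
            a, b = sorted(pair, key=order.__getitem__)
            fwd = self.direction(a, b)
            frm, to = (a, b) if fwd >= 0.5 else (b, a)
            rows.append(
                {
                    "from": frm,
                    "to": to,
                    "strength": cnt / self.B,
                    "direction": self.direction(frm, to),
                }
            )
        rows.sort(key=lambda r: (order[r["from"]], order[r["to"]]))
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


def bootstrap_arc_strength(
    std_table, B: int = 1000, seed: int = 0, restarts: int = 20, perturb: int = 5
) -> ArcStrengthTable:
    """Subject-level bootstrap of hill-climbing structure learning.

    Each of the B resamples (whole rows, with replacement, at the original
    n) is re-standardized and climbed (with perturbation restarts); pair
    presence and orientation are tallied.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, names = _std_values(std_table)
    n = X.shape[0]
    p = len(names)
    tie_tol = 1e-9 * max(float(n), 1.0)
    rng = np.random.default_rng(seed)
    pair_counts: dict[frozenset, int] = {}
    direction_counts: dict[tuple[str, str], int] = {}
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        restart_seed = int(rng.integers(0, 2**31 - 1))
        Xb = X[rows]
        sd = Xb.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xb = (Xb - Xb.mean(axis=0)) / sd
        C = _ml_cov(Xb)
        adj = np.zeros((p, p), np.uint8)
        if restarts > 0:
            _hill_climb_restarts(C, float(n), adj, tie_tol, restarts, perturb, restart_seed)
        else:
            _hill_climb_kernel(C, float(n), adj, tie_tol)
        for u in range(p):
            for v in range(p):
                if adj[u, v] == 1:
                    key = frozenset((names[u], names[v]))
                    pair_counts[key] = pair_counts.get(key, 0) + 1
                    okey = (names[u], names[v])
                    direction_counts[okey] = direction_counts.get(okey, 0) + 1
    return ArcStrengthTable(
        variable_names=names,
        pair_counts=pair_counts,
        direction_counts=direction_counts,
        B=B,
    )


def averaged_network(
    arc_table: ArcStrengthTable,
    strength_threshold: float = 0.85,
    direction_threshold: float = 0.51,
) -> Dag:
    """Threshold the bootstrap tallies into a consensus DAG.

    A pair enters iff its presence frequency is >= ``strength_threshold``;
    its orientation is the majority direction, required to reach
    ``direction_threshold`` of the conditional frequency (an exact 50/50
    split therefore drops the pair).  A cyclic consensus is an error (the
    offending cycle is reported), never silently repaired.
    """
    names = arc_table.variable_names
    order = {v: i for i, v in enumerate(names)}
    arcs: list[tuple[str, str]] = []
    for pair, cnt in arc_table.pair_counts.items():
        if cnt / arc_table.B < strength_threshold:
            continue
        a, b = sorted(pair, key=order.__getitem__)
        fwd = arc_table.direction(a, b)
        if fwd >= direction_threshold:
            arcs.append((a, b))
        elif 1.0 - fwd >= direction_threshold:
            arcs.append((b, a))
        # neither orientation reaches the threshold: pair excluded
    try:
        return Dag.from_arcs(names, arcs)
    except GraphInputError as e:
        import networkx as nx

        g = nx.DiGraph(arcs)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:  # pragma: no cover - defensive
            raise e
        raise GraphInputError(
            f"thresholded arc set is cyclic: {' -> '.join(a for a, _ in cycle)}"
        ) from e
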