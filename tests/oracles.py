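"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package code it checks: exhaustive enumeration instead of greedy search,
ADMM instead of coordinate descent, moralization instead of reachability,
linear-algebra partial correlations instead of graph traversal.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from eapnet import Dag, is_acyclic


# -- DAG enumeration ---------------------------------------------------


def enumerate_dags(nodes: tuple[str, ...]) -> list[Dag]:
    """All labeled DAGs over the given nodes (25 for 3 nodes, 543 for 4)."""
    pairs = list(itertools.combinations(nodes, 2))
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        arcs = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                arcs.append((a, b))
            elif s == 2:
                arcs.append((b, a))
        if is_acyclic(nodes, arcs):
            out.append(Dag.from_arcs(nodes, arcs))
    return out


def random_dag(rng: np.random.Generator, nodes: tuple[str, ...], edge_prob: float = 0.4) -> Dag:
    order = list(rng.permutation(len(nodes)))
    arcs = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < edge_prob:
                arcs.append((nodes[order[i]], nodes[order[j]]))
    return Dag.from_arcs(nodes, arcs)


# -- d-separation by moralization -------------------------------------


def d_separated_moral(dag: Dag, x: str, y: str, z: set[str]) -> bool:
    """Classic check: ancestral subgraph of {x, y} ∪ Z, moralize, drop Z,
    then x and y are d-separated iff disconnected."""
    g = dag.to_networkx()
    keep = set()
    for v in {x, y} | set(z):
        keep |= nx.ancestors(g, v) | {v}
    sub = g.subgraph(keep)
    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes)
    moral.add_edges_from(sub.edges)
    for v in sub.nodes:
        parents = list(sub.predecessors(v))
        for a, b in itertools.combinations(parents, 2):
            moral.add_edge(a, b)
    moral.remove_nodes_from(z)
    if x not in moral or y not in moral:
        return True
    return not nx.has_path(moral, x, y)


# -- linear-Gaussian partial-correlation oracle ------------------------


def sem_covariance(dag: Dag, rng: np.random.Generator) -> np.ndarray:
    """Implied covariance of a random linear-Gaussian SEM over the DAG with
    coefficients bounded away from zero (so vanishing partial correlation
    can only come from structure, not accidental cancellation)."""
    nodes = dag.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    p = len(nodes)
    A = np.zeros((p, p))
    for a, b in dag.arcs:
        A[idx[b], idx[a]] = rng.uniform(0.4, 0.9) * rng.choice([-1.0, 1.0])
    inv = np.linalg.inv(np.eye(p) - A)
    sigma = inv @ inv.T  # unit residual variances
    return (sigma + sigma.T) / 2.0


def partial_corr_zero(sigma: np.ndarray, i: int, j: int, ks: tuple[int, ...], tol=1e-10) -> bool:
    """True iff the partial correlation of (i, j) given ks vanishes."""
    sel = [i, j, *ks]
    omega = np.linalg.inv(sigma[np.ix_(sel, sel)])
    r = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
    return abs(r) < tol


# -- graphical lasso by ADMM -------------------------------------------


def admm_glasso(S: np.ndarray, lam: float, rho: float = 1.0, iters: int = 5000, tol: float = 1e-11):
    """ADMM solver for max logdet(T) - tr(S T) - lam * ||T_offdiag||_1."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(iters):
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        d = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        theta = (V * d) @ V.T
        A = theta + U
        Z_new = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z_new, np.diag(A))
        r_primal = np.abs(theta - Z_new).max()
        r_dual = rho * np.abs(Z_new - Z).max()
        Z = Z_new
        U = U + theta - Z
        if r_primal < tol and r_dual < tol:
            break
    return Z


def glasso_objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    offdiag = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(np.linalg.slogdet(theta)[1] - np.sum(S * theta) - lam * offdiag)
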