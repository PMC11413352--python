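"""Permutation-based comparison of two groups' Gaussian graphical models.

Two invariance statistics are tested: the network-structure statistic
M = max_{ij} |edge_A(ij) - edge_B(ij)| and the global-strength statistic
S = |sum_{i<j} |edge_A(ij)| - sum_{i<j} |edge_B(ij)||, with a permutation
null built by pooling all subjects, re-splitting them into groups of the
original sizes, re-standardizing each permuted group and refitting both
networks.  Edge-wise permutation tests are Holm-adjusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ggm import _as_matrix, _fit_precision_path, _partial_from_precision

__all__ = ["NctResult", "nct", "holm_adjust"]


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class NctResult:
    """Observed invariance statistics, permutation p-values and edge tests."""

    m_statistic: float
    p_structure: float
    s_statistic: float
    p_strength: float
    edge_pvalues: dict[tuple[str, str], float]
    edge_pvalues_raw: dict[tuple[str, str], float]
    edge_differences: dict[tuple[str, str], float]
    iterations: int
    seed: int
    variable_names: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "m_statistic": self.m_statistic,
                "p_structure": self.p_structure,
                "s_statistic": self.s_statistic,
                "p_strength": self.p_strength,
                "iterations": self.iterations,
                "seed": self.seed,
                "edge_tests": [
                    {
                        "node_a": a,
                        "node_b": b,
                        "difference": self.edge_differences[(a, b)],
                        "p_raw": self.edge_pvalues_raw[(a, b)],
                        "p_holm": self.edge_pvalues[(a, b)],
                    }
                    for (a, b) in sorted(self.edge_pvalues)
                ],
            },
            indent=2,
        )

    def edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "difference": self.edge_differences[(a, b)],
                "p_raw": self.edge_pvalues_raw[(a, b)],
                "p_holm": self.edge_pvalues[(a, b)],
            }
            for (a, b) in sorted(self.edge_pvalues)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "difference", "p_raw", "p_holm"])


def _restandardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _fit_pcor(X, gamma, n_lambda, lambda_min_ratio, sparsify_tol) -> np.ndarray:
    theta, _, _, _, _, _ = _fit_precision_path(
        X, gamma, n_lambda, lambda_min_ratio, 1e-7, count_tol=sparsify_tol
    )
    return _partial_from_precision(theta, sparsify_tol)


def nct(
    tableA,
    tableB,
    iterations: int = 2000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    sparsify_tol: float = 1e-7,
) -> NctResult:
    """Network comparison test between two groups.

    Both inputs are standardized within group before fitting (the observed
    fit and every permuted refit alike).  p-values use the add-one
    convention: (#{perm >= observed} + 1) / (iterations + 1).  Edge-wise
    tests cover all unordered pairs with a nonzero observed estimate in at
    least one group and are Holm-adjusted.
    """
    XA, namesA, _ = _as_matrix(tableA)
    XB, namesB, _ = _as_matrix(tableB)
    if namesA != namesB:
        raise ValueError("both tables must have the same variables in the same order")
    names = namesA
    p = len(names)
    if XA.shape[0] <= p or XB.shape[0] <= p:
        raise ValueError("each group needs more rows than variables")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    args = (gamma, n_lambda, lambda_min_ratio, sparsify_tol)
    pcA = _fit_pcor(_restandardize(XA), *args)
    pcB = _fit_pcor(_restandardize(XB), *args)
    iu = np.triu_indices(p, 1)
    diff_obs = np.abs(pcA - pcB)[iu]
    m_obs = float(diff_obs.max())
    s_obs = float(abs(np.abs(pcA[iu]).sum() - np.abs(pcB[iu]).sum()))

    # pool rows in a canonical (lexicographically sorted) order and always
    # give the larger permuted split first, so the null — and hence every
    # p-value — is exactly invariant to relabeling the two groups; all
    # statistics are symmetric in |qA - qB|
    pooled = np.vstack([XA, XB])
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    nA = max(XA.shape[0], XB.shape[0])
    n_all = pooled.shape[0]
    rng = np.random.default_rng(seed)
    m_count = 0
    s_count = 0
    edge_counts = np.zeros(diff_obs.shape[0], dtype=np.int64)
    for _ in range(iterations):
        perm = rng.permutation(n_all)
        GA = _restandardize(pooled[perm[:nA]])
        GB = _restandardize(pooled[perm[nA:]])
        qA = _fit_pcor(GA, *args)
        qB = _fit_pcor(GB, *args)
        d = np.abs(qA - qB)[iu]
        if d.max() >= m_obs:
            m_count += 1
        if abs(np.abs(qA[iu]).sum() - np.abs(qB[iu]).sum()) >= s_obs:
            s_count += 1
        edge_counts += d >= diff_obs

    p_structure = (m_count + 1) / (iterations + 1)
    p_strength = (s_count + 1) / (iterations + 1)
    edge_p_raw_all = (edge_counts + 1) / (iterations + 1)

    # family: pairs with a nonzero observed estimate in either group
    family = [
        k
        for k in range(diff_obs.shape[0])
        if pcA[iu[0][k], iu[1][k]] != 0.0 or pcB[iu[0][k], iu[1][k]] != 0.0
    ]
    adj = holm_adjust([edge_p_raw_all[k] for k in family]) if family else np.empty(0)
    edge_pvalues: dict[tuple[str, str], float] = {}
    edge_pvalues_raw: dict[tuple[str, str], float] = {}
    edge_differences: dict[tuple[str, str], float] = {}
    for pos, k in enumerate(family):
        key = (names[iu[0][k]], names[iu[1][k]])
        edge_pvalues[key] = float(adj[pos])
        edge_pvalues_raw[key] = float(edge_p_raw_all[k])
        edge_differences[key] = float(pcA[iu[0][k], iu[1][k]] - pcB[iu[0][k], iu[1][k]])
    return NctResult(
        m_statistic=m_obs,
        p_structure=float(p_structure),
        s_statistic=s_obs,
        p_strength=float(p_strength),
        edge_pvalues=edge_pvalues,
        edge_pvalues_raw=edge_pvalues_raw,
        edge_differences=edge_differences,
        iterations=iterations,
        seed=seed,
        variable_names=names,
    )
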