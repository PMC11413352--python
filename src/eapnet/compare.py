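"""Between-group comparison of directed networks.

Arc-set similarity is a Jaccard coefficient computed direction-blind on the
two skeletons (presence is scored separately from orientation, matching the
direction-blind convention used for bootstrap arc frequency).  Orientation
is scored by the arc direction agreement: the fraction of skeleton-common
pairs oriented identically in both DAGs.  An alternative reading that
divides by one network's total arc count is also reported, since both
denominators appear in the literature.  Both metrics are bootstrapped by
resampling each group's subjects and re-learning one hill-climbing DAG per
group per iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_graph import Dag, GraphInputError, skeleton
from .bn import averaged_network, bootstrap_arc_strength, hill_climb
from .ggm import StandardizedTable, _as_matrix

__all__ = [
    "ComparisonMetrics",
    "jaccard_arcs",
    "direction_agreement",
    "bootstrap_comparison",
    "cohens_d",
]


def _check_universe(dagA: Dag, dagB: Dag) -> None:
    if set(dagA.nodes) != set(dagB.nodes):
        raise GraphInputError("DAGs must share the same node universe")


def jaccard_arcs(dagA: Dag, dagB: Dag) -> float:
    """|skeleton(A) ∩ skeleton(B)| / |skeleton(A) ∪ skeleton(B)|; 0 if the
    union is empty (convention)."""
    _check_universe(dagA, dagB)
    sa, sb = skeleton(dagA).edges, skeleton(dagB).edges
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def direction_agreement(dagA: Dag, dagB: Dag) -> float | None:
    """Fraction of skeleton-common pairs oriented identically in both DAGs.

    Returns None (undefined) when the skeletons share no pair.
    """
    _check_universe(dagA, dagB)
    common = skeleton(dagA).edges & skeleton(dagB).edges
    if not common:
        return None
    same = sum(1 for pair in common if _orientation(dagA, pair) == _orientation(dagB, pair))
    return same / len(common)


def _orientation(dag: Dag, pair: frozenset) -> tuple[str, str]:
    a, b = tuple(pair)
    return (a, b) if (a, b) in dag.arcs else (b, a)


def _direction_agreement_over_total(dagA: Dag, dagB: Dag, denominator: Dag) -> float | None:
    """Same-direction count divided by one network's total arc count."""
    common = skeleton(dagA).edges & skeleton(dagB).edges
    if len(denominator.arcs) == 0:
        return None
    same = sum(1 for pair in common if _orientation(dagA, pair) == _orientation(dagB, pair))
    return same / len(denominator.arcs)


@dataclass(frozen=True)
class ComparisonMetrics:
    """Point metrics on the averaged networks plus bootstrap replicates."""

    jaccard: float
    direction_agreement: float | None
    direction_agreement_over_arcs_a: float | None
    direction_agreement_over_arcs_b: float | None
    common_pair_count: int
    union_pair_count: int
    bootstrap_distribution: np.ndarray  # shape (B, 2): (jaccard, agreement)
    B: int
    seed: int

    def quantiles(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        jd = self.bootstrap_distribution[:, 0]
        ad = self.bootstrap_distribution[:, 1]
        out = {"jaccard": (float(np.quantile(jd, lo)), float(np.quantile(jd, hi)))}
        with np.errstate(all="ignore"):
            if np.any(~np.isnan(ad)):
                out["direction_agreement"] = (
                    float(np.nanquantile(ad, lo)),
                    float(np.nanquantile(ad, hi)),
                )
            else:
                out["direction_agreement"] = (float("nan"), float("nan"))
        return out

    def to_json(self) -> str:
        q = self.quantiles()
        return json.dumps(
            {
                "jaccard": self.jaccard,
                "direction_agreement_common_pairs": self.direction_agreement,
                "direction_agreement_over_arcs_a": self.direction_agreement_over_arcs_a,
                "direction_agreement_over_arcs_b": self.direction_agreement_over_arcs_b,
                "common_pair_count": self.common_pair_count,
                "union_pair_count": self.union_pair_count,
                "B": self.B,
                "seed": self.seed,
                "bootstrap_quantiles_95": {k: list(v) for k, v in q.items()},
            },
            indent=2,
        )


def bootstrap_comparison(
    tableA,
    tableB,
    B: int = 1000,
    seed: int = 0,
    strength_threshold: float = 0.85,
    direction_threshold: float = 0.51,
) -> ComparisonMetrics:
    """Point comparison of the two averaged networks plus a metric bootstrap.

    Point estimates come from each group's bootstrap-averaged network
    (B resamples each).  The metric bootstrap then resamples each group's
    rows and learns a single hill-climbing DAG per group per iteration (a
    tractability trade-off relative to nesting a full averaging run inside
    every iteration), recording both metrics.
    """
    XA, namesA, _ = _as_matrix(tableA)
    XB, namesB, _ = _as_matrix(tableB)
    if namesA != namesB:
        raise ValueError("both tables must have the same variables in the same order")
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    avgA = averaged_network(
        bootstrap_arc_strength(tableA, B=B, seed=seed_a),
        strength_threshold,
        direction_threshold,
    )
    avgB = averaged_network(
        bootstrap_arc_strength(tableB, B=B, seed=seed_b),
        strength_threshold,
        direction_threshold,
    )
    common = skeleton(avgA).edges & skeleton(avgB).edges
    union = skeleton(avgA).edges | skeleton(avgB).edges

    def _resample_std(X: np.ndarray, rows: np.ndarray) -> StandardizedTable:
        Xb = X[rows]
        sd = Xb.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return StandardizedTable((Xb - Xb.mean(axis=0)) / sd, namesA)

    reps = np.empty((B, 2))
    nA, nB = XA.shape[0], XB.shape[0]
    for b in range(B):
        da = hill_climb(_resample_std(XA, rng.integers(0, nA, size=nA))).dag
        db = hill_climb(_resample_std(XB, rng.integers(0, nB, size=nB))).dag
        reps[b, 0] = jaccard_arcs(da, db)
        agr = direction_agreement(da, db)
        reps[b, 1] = np.nan if agr is None else agr
    return ComparisonMetrics(
        jaccard=jaccard_arcs(avgA, avgB),
        direction_agreement=direction_agreement(avgA, avgB),
        direction_agreement_over_arcs_a=_direction_agreement_over_total(avgA, avgB, avgA),
        direction_agreement_over_arcs_b=_direction_agreement_over_total(avgA, avgB, avgB),
        common_pair_count=len(common),
        union_pair_count=len(union),
        bootstrap_distribution=reps,
        B=B,
        seed=seed,
    )


def cohens_d(valuesA, valuesB) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(valuesA, float)
    b = np.asarray(valuesB, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)
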