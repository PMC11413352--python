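"""End-to-end two-group analysis orchestration.

Given a subjects-by-measures CSV with a group column (or a pair of
synthetic generating models), runs, per group: listwise deletion →
within-group standardization → EBIC-glasso GGM → bootstrap edge accuracy →
node predictability; across groups: the permutation network comparison
test; per group: bootstrap arc strength → thresholded averaged DAG →
standardized betas; across groups: DAG comparison metrics and per-variable
Cohen's d.  Optionally repeats the directed-network track on a reduced
variable set (e.g. omitting VOLT).

Every random stage draws its seed deterministically from a single master
seed, so the whole report is a pure function of (input data, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bn as bn_mod
from . import compare as compare_mod
from . import ggm as ggm_mod
from .nct import nct as _run_nct
from .synthetic import default_specs, simulate

__all__ = ["AnalysisConfig", "AnalysisReport", "listwise_delete", "run_full_analysis"]

logger = logging.getLogger("eapnet")


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of the two-group pipeline.

    Defaults mirror the study settings: EBIC gamma 0.5, 1000 bootstrap
    samples for both tracks, 2000 permutation iterations, and 85%/51%
    averaging thresholds.  ``smoke()`` gives a reduced profile for quick
    integration runs.
    """

    input_csv: str | None = None
    synthetic: bool = True
    n_control: int = 630
    n_schizophrenia: int = 663
    group_column: str = "group"
    group_labels: tuple[str, str] | None = None  # (A, B); A - B ordering for d
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    sparsify_tol: float = 1e-7
    ggm_boot_B: int = 1000
    bn_boot_B: int = 1000
    comparison_B: int = 1000
    nct_iterations: int = 2000
    strength_threshold: float = 0.85
    direction_threshold: float = 0.51
    exclude_variables: tuple[str, ...] = ()
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("strength_threshold", "direction_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("ggm_boot_B", "bn_boot_B", "comparison_B", "nct_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def smoke(cls, **overrides) -> "AnalysisConfig":
        """Reduced-bootstrap profile (B=50, 100 permutations) for fast runs."""
        base = dict(ggm_boot_B=50, bn_boot_B=50, comparison_B=50, nct_iterations=100)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "group_labels" in d and d["group_labels"] is not None:
            d["group_labels"] = tuple(d["group_labels"])
        if "exclude_variables" in d:
            d["exclude_variables"] = tuple(d["exclude_variables"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_labels"] = list(self.group_labels) if self.group_labels else None
        d["exclude_variables"] = list(self.exclude_variables)
        return d


def listwise_delete(raw_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop every row with any missing value; report how many were dropped."""
    complete = raw_table.dropna()
    removed = len(raw_table) - len(complete)
    if len(complete) == 0:
        raise ValueError("listwise deletion removed every row")
    return complete.reset_index(drop=True), removed


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus a provenance block; JSON-serializable."""

    config: AnalysisConfig
    content: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config.to_dict(), **self.content},
            indent=2,
            sort_keys=True,
            allow_nan=True,
        )


def _load_groups(config: AnalysisConfig, seeds: list[int]) -> dict[str, pd.DataFrame]:
    """Two label -> numeric-DataFrame mappings, in (A, B) order."""
    if config.input_csv is not None:
        df = pd.read_csv(config.input_csv)
        if config.group_column not in df.columns:
            raise ValueError(f"group column {config.group_column!r} not in CSV")
        labels = config.group_labels or tuple(pd.unique(df[config.group_column]))
        if len(labels) != 2:
            raise ValueError("exactly two group labels are required")
        return {
            str(lab): df[df[config.group_column] == lab]
            .drop(columns=[config.group_column])
            .astype(float)
            for lab in labels
        }
    control_spec, sz_spec = default_specs()
    tables = {
        control_spec.group_label: simulate(control_spec, config.n_control, seeds[0]),
        sz_spec.group_label: simulate(sz_spec, config.n_schizophrenia, seeds[1]),
    }
    return {
        lab: t.to_dataframe(group_column=None) for lab, t in tables.items()
    }


def _bn_track(df_by_group, variables, config, seeds, outdir, tag="") -> dict:
    """Arc strength -> averaged DAG -> betas for each group; plus metrics."""
    out: dict = {}
    for k, (label, df) in enumerate(df_by_group.items()):
        t0 = time.perf_counter()
        std = ggm_mod.standardize(df[variables])
        arc_table = bn_mod.bootstrap_arc_strength(std, B=config.bn_boot_B, seed=seeds[k])
        avg = bn_mod.averaged_network(
            arc_table, config.strength_threshold, config.direction_threshold
        )
        fitted = bn_mod.fit_betas(std, avg)
        out[label] = {
            "arc_strength": json.loads(arc_table.to_dataframe().to_json(orient="records")),
            "averaged_arcs": [list(a) for a in avg.sorted_arcs()],
            "betas": {f"{a}->{b}": v for (a, b), v in sorted(fitted.betas.items())},
            "bic_total": fitted.bic_total,
        }
        if outdir is not None:
            arc_table.to_dataframe().to_csv(outdir / f"arc_strength_{label}{tag}.csv", index=False)
            avg.to_graphml(str(outdir / f"bn_{label}{tag}.graphml"))
            (outdir / f"bn_{label}{tag}.json").write_text(fitted.to_json())
        logger.info("BN track%s [%s]: %.1fs", tag, label, time.perf_counter() - t0)
    (labA, dfA), (labB, dfB) = df_by_group.items()
    metrics = compare_mod.bootstrap_comparison(
        ggm_mod.standardize(dfA[variables]),
        ggm_mod.standardize(dfB[variables]),
        B=config.comparison_B,
        seed=seeds[2],
        strength_threshold=config.strength_threshold,
        direction_threshold=config.direction_threshold,
    )
    out["comparison"] = json.loads(metrics.to_json())
    if outdir is not None:
        (outdir / f"bn_comparison{tag}.json").write_text(metrics.to_json())
    return out


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the complete two-group analysis; see module docstring."""
    seeds = _stage_seeds(config.master_seed, 12)
    outdir = None
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    df_by_group = _load_groups(config, seeds)
    report: dict = {"provenance": {"seeds": seeds, "rows": {}}}

    # listwise deletion + variable universe
    for label in list(df_by_group):
        before = len(df_by_group[label])
        df_by_group[label], removed = listwise_delete(df_by_group[label])
        report["provenance"]["rows"][label] = {
            "before_deletion": before,
            "after_deletion": len(df_by_group[label]),
            "removed": removed,
        }
    (labA, dfA), (labB, dfB) = df_by_group.items()
    variables = [c for c in dfA.columns]
    if list(dfB.columns) != variables:
        raise ValueError("groups disagree on variables")
    bad = set(config.exclude_variables) - set(variables)
    if bad:
        raise ValueError(f"excluded variables not in table: {sorted(bad)}")

    # --- undirected track ---
    ggm_out: dict = {}
    for k, (label, df) in enumerate(df_by_group.items()):
        t0 = time.perf_counter()
        std = ggm_mod.standardize(df)
        fit = ggm_mod.ebic_glasso(
            std, config.gamma, config.n_lambda, config.lambda_min_ratio, config.sparsify_tol
        )
        boot = ggm_mod.bootstrap_edges(
            std,
            B=config.ggm_boot_B,
            seed=seeds[2 + k],
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            sparsify_tol=config.sparsify_tol,
        )
        ggm_out[label] = {
            "lambda_selected": fit.lambda_selected,
            "ebic": fit.ebic_value,
            "edges": json.loads(boot.edge_dataframe().to_json(orient="records")),
            "global_strength": fit.global_strength(),
            "predictability": fit.predictability,
        }
        if outdir is not None:
            boot.edge_dataframe().to_csv(outdir / f"ggm_edges_{label}.csv", index=False)
            ggm_mod.predictability_dataframe(fit.predictability).to_csv(
                outdir / f"predictability_{label}.csv", index=False
            )
            fit.to_graphml(str(outdir / f"ggm_{label}.graphml"))
        logger.info("GGM track [%s]: %.1fs", label, time.perf_counter() - t0)
    report["ggm"] = ggm_out

    # --- GGM comparison ---
    t0 = time.perf_counter()
    nct_res = _run_nct(
        dfA,
        dfB,
        iterations=config.nct_iterations,
        seed=seeds[4],
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        sparsify_tol=config.sparsify_tol,
    )
    report["nct"] = json.loads(nct_res.to_json())
    if outdir is not None:
        (outdir / "nct.json").write_text(nct_res.to_json())
        nct_res.edge_dataframe().to_csv(outdir / "nct_edges.csv", index=False)
    logger.info("NCT: %.1fs", time.perf_counter() - t0)

    # --- directed track ---
    report["bn"] = _bn_track(df_by_group, variables, config, seeds[5:8], outdir)

    # --- effect sizes ---
    report["cohens_d"] = {
        v: compare_mod.cohens_d(dfA[v].to_numpy(), dfB[v].to_numpy()) for v in variables
    }
    report["cohens_d_order"] = f"{labA} - {labB}"

    # --- follow-up on reduced variable set ---
    if config.exclude_variables:
        reduced = [v for v in variables if v not in config.exclude_variables]
        report["bn_followup"] = {
            "variables": reduced,
            **_bn_track(df_by_group, reduced, config, seeds[8:11], outdir, tag="_followup"),
        }

    result = AnalysisReport(config=config, content=report)
    if outdir is not None:
        (outdir / "report.json").write_text(result.to_json())
    return result
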