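"""End-to-end orchestration of the two network-analysis workflows.

A pipeline run takes respondent-level data (raw Likert items or pre-scored
dimension scores, from CSV or from the synthetic generator), restricts it to
the node set of the requested variant (healthy music use: HMU and not UHMU;
unhealthy: the reverse), and produces the full report bundle: a descriptive
mean/SD table, the regularized partial-correlation network with node and
bridge centralities, bootstrap stability results, the bootstrapped averaged
Bayesian network, and the per-child linear models — plus a JSON manifest
with every seed and parameter so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import bayesnet, centrality, ggm, scales, stability, synthetic
from .errors import ConfigError, SchemaError

log = logging.getLogger("musenet")

#: The ten dimension-score column names, matched case-insensitively.
DIMENSIONS = ("HMU", "UHMU", "POS", "DES", "ANG", "DIF", "DDF", "EOT",
              "Anx", "Dep")


@dataclass
class PipelineConfig:
    """All parameters of one pipeline run.

    Every stochastic stage has its own seed, derived deterministically from
    ``seed`` unless set explicitly.  Bootstrap replicate counts default to
    the full-scale analysis (1,000); reduce them for quick runs.
    """

    variant: str = "healthy"
    input_csv: str | None = None        # None -> synthetic generator
    n: int = synthetic.DEFAULT_N
    seed: int = 0
    # network estimation
    transform: str = "npn"
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    # stability
    run_stability: bool = True
    edge_bootstrap_R: int = 1000
    casedrop_R: int = 1000
    casedrop_grid: tuple[float, ...] = stability.DEFAULT_DROP_GRID
    # Bayesian network
    run_bn: bool = True
    hc_restarts: int = 50
    hc_perturbations: int = 100
    bn_bootstrap_R: int = 1000
    bn_bootstrap_restarts: int = 3
    bn_bootstrap_perturbations: int = 15
    strength_threshold: float = 0.85
    direction_threshold: float = 0.5
    communities: dict[str, str] = field(
        default_factory=lambda: dict(centrality.DEFAULT_COMMUNITIES))

    def __post_init__(self):
        if self.variant not in synthetic.VARIANT_NODES:
            raise ConfigError(f"unknown variant {self.variant!r}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        offsets = {"generate": 1, "edge_bootstrap": 2, "casedrop": 3,
                   "hill_climb": 4, "bn_bootstrap": 5}
        return (self.seed * 1000 + offsets[stage]) % (2**31)


def load_dimension_scores(path: str) -> pd.DataFrame:
    """Read a CSV of dimension scores or raw items, scoring items if needed.

    Column names are matched case-insensitively: either the ten dimension
    abbreviations (HMU, UHMU, POS, DES, ANG, DIF, DDF, EOT, Anx, Dep) or the
    55 instrument items (K10_1.. etc.), which are scored first.
    """
    df = pd.read_csv(path)
    upper = {c.upper(): c for c in df.columns}
    dims = [d for d in DIMENSIONS if d.upper() in upper]
    if len(dims) == len(DIMENSIONS):
        out = df[[upper[d.upper()] for d in DIMENSIONS]]
        out.columns = list(DIMENSIONS)
        return out
    if any(c.upper().startswith("K10_") for c in df.columns):
        scored = scales.score_battery(df)
        return pd.DataFrame({
            "HMU": scored["hmu"], "UHMU": scored["uhmu"],
            "POS": scored["pos"], "DES": scored["des"],
            "ANG": scored["ang"], "DIF": scored["dif"],
            "DDF": scored["ddf"], "EOT": scored["eot"],
            "Anx": scored["anxiety"], "Dep": scored["depression"],
        })
    raise SchemaError(
        "input CSV must contain either the 10 dimension columns or the "
        "55 instrument item columns"
    )


def descriptive_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Per-dimension n, mean and SD table (the descriptive-statistics layout)."""
    return pd.DataFrame({
        "dimension": data.columns,
        "n": len(data),
        "mean": data.mean().to_numpy(),
        "sd": data.std(ddof=1).to_numpy(),
    })


def percentage_summary(counts: Mapping[str, int],
                       total: int | None = None) -> pd.DataFrame:
    """Subgroup counts with percentages of the total (1 decimal place)."""
    total = total if total is not None else sum(counts.values())
    return pd.DataFrame({
        "group": list(counts),
        "count": list(counts.values()),
        "percent": [round(100.0 * c / total, 1) for c in counts.values()],
    })


def retention_rate(n_valid: int, n_collected: int) -> float:
    """Valid-response rate as a percentage (0 decimal rounding applied
    downstream where a whole-number rate is reported)."""
    return 100.0 * n_valid / n_collected


def run_pipeline(config: PipelineConfig) -> dict:
    """Run one variant end-to-end; returns the report bundle as a dict."""
    t0 = time.time()
    nodes = synthetic.VARIANT_NODES[config.variant]
    if config.input_csv is not None:
        all_dims = load_dimension_scores(config.input_csv)
        truth = None
    else:
        all_dims, truth = synthetic.generate_dimension_scores(
            config.n, variant=config.variant,
            seed=config.stage_seed("generate"))
    missing = [v for v in nodes if v not in all_dims.columns]
    if missing:
        raise SchemaError(f"variant {config.variant!r} needs columns "
                          f"{missing}")
    data = all_dims[nodes]
    results: dict = {"config": config, "truth": truth,
                     "summary": descriptive_summary(data)}

    log.info("estimating RPCN (%s variant, n=%d)", config.variant, len(data))

    def estimator(d: pd.DataFrame) -> ggm.PartialCorrelationNetwork:
        return ggm.estimate_network(
            d, transform=config.transform, gamma=config.gamma,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio)

    network = estimator(data)
    results["network"] = network
    results["centrality"] = centrality.node_centrality(network)
    results["centrality_z"] = centrality.node_centrality(network,
                                                         zscored=True)
    results["bridge"] = centrality.bridge_centrality(network,
                                                     config.communities)
    results["bridge_z"] = centrality.bridge_centrality(
        network, config.communities, zscored=True)

    if config.run_stability:
        log.info("edge-weight bootstrap (R=%d)", config.edge_bootstrap_R)
        results["edge_bootstrap"] = stability.edge_bootstrap(
            data, estimator, R=config.edge_bootstrap_R,
            seed=config.stage_seed("edge_bootstrap"))
        log.info("case-drop bootstrap (R=%d)", config.casedrop_R)
        results["casedrop"] = stability.casedrop_cs(
            data, estimator, grid=config.casedrop_grid,
            R=config.casedrop_R, seed=config.stage_seed("casedrop"))

    if config.run_bn:
        std = ggm.zscore(data)
        log.info("hill-climbing structure learn (restarts=%d)",
                 config.hc_restarts)
        results["dag"] = bayesnet.hill_climb(
            std, restarts=config.hc_restarts,
            perturbations=config.hc_perturbations,
            seed=config.stage_seed("hill_climb"))
        log.info("bootstrap arc strengths (R=%d)", config.bn_bootstrap_R)
        conf = bayesnet.bootstrap_arcs(
            std, R=config.bn_bootstrap_R,
            restarts=config.bn_bootstrap_restarts,
            perturbations=config.bn_bootstrap_perturbations,
            seed=config.stage_seed("bn_bootstrap"))
        results["arc_confidence"] = conf
        avg = bayesnet.averaged_network(
            conf, config.strength_threshold, config.direction_threshold)
        results["averaged_network"] = avg
        results["regressions"] = bayesnet.fit_child_regressions(std, avg)

    results["elapsed_s"] = time.time() - t0
    return results


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def dot_export(avg: bayesnet.AveragedNetwork) -> str:
    """The averaged DAG in GraphViz DOT syntax."""
    lines = ["digraph averaged_network {"]
    for v in avg.labels:
        lines.append(f'  "{v}";')
    for a in avg.arcs:
        lines.append(f'  "{a.parent}" -> "{a.child}" '
                     f'[label="{a.strength:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_edge_list(network: ggm.PartialCorrelationNetwork,
                    path: Path) -> None:
    """TSV edge list (node_a, node_b, weight); header always written."""
    network.edge_list().to_csv(path, sep="\t", index=False)


def read_edge_list(path: Path, labels) -> np.ndarray:
    """Re-read a written edge list into a full symmetric weight matrix."""
    df = pd.read_csv(path, sep="\t")
    idx = {v: i for i, v in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for _, row in df.iterrows():
        i, j = idx[row.node_a], idx[row.node_b]
        w[i, j] = w[j, i] = row.weight
    return w


def write_outputs(results: dict, out_dir: str | Path) -> list[Path]:
    """Write the report bundle: CSV tables, TSV edge list, DOT, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, index=kw.pop("index", False), **kw)
        written.append(path)

    save(results["summary"], "summary.csv")
    write_edge_list(results["network"], out / "edges.tsv")
    written.append(out / "edges.tsv")
    save(results["centrality"], "centrality.csv", index=True)
    save(results["centrality_z"], "centrality_z.csv", index=True)
    save(results["bridge"], "bridge_centrality.csv", index=True)
    save(results["bridge_z"], "bridge_centrality_z.csv", index=True)
    if "edge_bootstrap" in results:
        save(results["edge_bootstrap"].table, "edge_bootstrap.csv")
    if "casedrop" in results:
        save(results["casedrop"].summary(), "cs_coefficients.csv")
    if "averaged_network" in results:
        save(results["averaged_network"].to_frame(), "bn_arcs.csv")
        (out / "averaged_network.dot").write_text(
            dot_export(results["averaged_network"]))
        written.append(out / "averaged_network.dot")
        save(bayesnet.regressions_frame(results["regressions"]),
             "bn_regressions.csv")

    config = results["config"]
    net = results["network"]
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "n_respondents": int(results["summary"]["n"].iloc[0]),
        "lambda_selected": net.lambda_selected,
        "ebic": net.ebic_value,
        "n_edges": net.n_edges,
        "stage_seeds": {s: config.stage_seed(s) for s in
                        ("generate", "edge_bootstrap", "casedrop",
                         "hill_climb", "bn_bootstrap")},
        "elapsed_s": results["elapsed_s"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    written.append(out / "manifest.json")
    return written
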