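"""Bootstrap robustness of the partial-correlation network.

Two procedures, following the standard psychometric-network workflow:

* :func:`edge_bootstrap` resamples respondents with replacement, re-estimates
  the network per resample and reports 95% percentile confidence intervals
  per edge — a precision check on the edge weights.
* :func:`casedrop_cs` drops increasing proportions of respondents without
  replacement and correlates the subsample centrality orders with the
  full-sample ones.  The correlation-stability coefficient CS(cor = 0.7) is
  the largest drop proportion at which at least 95% of subsamples still
  correlate >= 0.7 with the full sample, evaluated on a grid capped at 0.75
  (so CS = 0.75 is the best attainable level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .errors import ConfigError, EstimationError, MusenetError
from .ggm import PartialCorrelationNetwork, estimate_network

#: Default case-drop proportion grid, 5% to the 75% ceiling.
DEFAULT_DROP_GRID: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35, 0.45,
                                        0.55, 0.65, 0.75)

Estimator = Callable[[pd.DataFrame], PartialCorrelationNetwork]


@dataclass(frozen=True)
class EdgeBootstrapResult:
    """Per-edge point weights with bootstrap percentile intervals."""

    table: pd.DataFrame       # node_a, node_b, weight, lower, upper
    n_replicates: int
    n_failed: int

    def interval(self, a: str, b: str) -> tuple[float, float]:
        t = self.table
        row = t[((t.node_a == a) & (t.node_b == b))
                | ((t.node_a == b) & (t.node_b == a))]
        if row.empty:
            raise KeyError(f"no edge {a} - {b}")
        return float(row.lower.iloc[0]), float(row.upper.iloc[0])


def edge_bootstrap(data: pd.DataFrame, estimator: Estimator | None = None,
                   R: int = 1000, seed: int = 0,
                   ci: float = 0.95) -> EdgeBootstrapResult:
    """Nonparametric bootstrap confidence intervals for every edge weight.

    Rows are resampled with replacement R times and the network re-estimated
    per resample; per node pair the interval is the (2.5%, 97.5%) percentile
    of the replicate weights (at the default ``ci``).  Replicates where the
    estimator fails are dropped and counted.
    """
    if R < 100:
        raise ConfigError("R must be at least 100")
    estimator = estimator or estimate_network
    try:
        point = estimator(data)
    except MusenetError as exc:
        raise EstimationError(
            f"estimator failed on the full dataset (degenerate input?): {exc}"
        ) from exc
    p = point.n_nodes
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.full((R, p, p), np.nan)
    failed = 0
    for r in range(R):
        rows = rng.integers(n, size=n)
        try:
            net = estimator(data.iloc[rows].reset_index(drop=True))
            reps[r] = net.weights
        except MusenetError:
            failed += 1
    ok = ~np.isnan(reps[:, 0, 0])
    if not ok.any():
        raise EstimationError("every bootstrap replicate failed")
    alpha = (1.0 - ci) / 2.0
    lower = np.quantile(reps[ok], alpha, axis=0)
    upper = np.quantile(reps[ok], 1.0 - alpha, axis=0)
    rows_out = []
    for i in range(p):
        for j in range(i + 1, p):
            rows_out.append((point.labels[i], point.labels[j],
                             point.weights[i, j], lower[i, j], upper[i, j]))
    table = pd.DataFrame(rows_out, columns=["node_a", "node_b", "weight",
                                            "lower", "upper"])
    return EdgeBootstrapResult(table, int(ok.sum()), failed)


@dataclass(frozen=True)
class CaseDropResult:
    """Case-drop correlations and CS coefficients per centrality index."""

    grid: tuple[float, ...]
    #: index -> (len(grid) x R) array of Pearson correlations with the
    #: full-sample centralities; NaN marks a failed replicate.
    correlations: dict[str, np.ndarray]
    cs: dict[str, float]
    cor_threshold: float = 0.7
    proportion_threshold: float = 0.95
    skipped: tuple[float, ...] = field(default=())

    def summary(self) -> pd.DataFrame:
        rows = [{"index": k, "cs": v} for k, v in self.cs.items()]
        return pd.DataFrame(rows)


def _cs_from_correlations(cor: np.ndarray, grid: Sequence[float],
                          cor_threshold: float,
                          proportion_threshold: float) -> float:
    """Largest drop proportion up to which the stability condition holds.

    The condition at proportion q: at least ``proportion_threshold`` of the
    replicate correlations are >= ``cor_threshold`` (undefined correlations
    count as failures).  CS is the largest grid value q such that the
    condition holds at every grid proportion <= q; 0 if it fails at the
    smallest.
    """
    cs = 0.0
    for gi, q in enumerate(grid):
        row = cor[gi]
        good = np.sum(np.nan_to_num(row, nan=-np.inf) >= cor_threshold)
        if good / len(row) >= proportion_threshold:
            cs = q
        else:
            break
    return cs


def casedrop_cs(data: pd.DataFrame, estimator: Estimator | None = None,
                indices: Sequence[str] = _centrality.CENTRALITY_INDICES,
                grid: Sequence[float] = DEFAULT_DROP_GRID,
                R: int = 1000, seed: int = 0, cor_threshold: float = 0.7,
                proportion_threshold: float = 0.95) -> CaseDropResult:
    """Case-drop bootstrap of centrality stability (CS coefficient).

    For each drop proportion q on the grid, draws R subsamples of
    ceil((1 - q) n) rows without replacement, re-estimates the network, and
    correlates (Pearson) each subsample centrality index across nodes with
    the full-sample values.  Proportions whose subsample is too small for
    estimation are skipped with a warning.
    """
    if R < 100:
        raise ConfigError("R must be at least 100")
    if not all(0 < q <= 0.75 for q in grid):
        raise ConfigError("drop proportions must lie in (0, 0.75]")
    estimator = estimator or estimate_network
    full = _centrality.node_centrality(estimator(data))
    missing = [ix for ix in indices if ix not in full.columns]
    if missing:
        raise ConfigError(f"unknown centrality indices: {missing}")
    n = len(data)
    rng = np.random.default_rng(seed)
    grid = tuple(sorted(grid))
    cors = {ix: np.full((len(grid), R), np.nan) for ix in indices}
    skipped = []
    for gi, q in enumerate(grid):
        m = int(np.ceil((1.0 - q) * n))
        if m < 3:
            skipped.append(q)
            import warnings
            warnings.warn(f"drop proportion {q} leaves only {m} rows; skipped")
            continue
        for r in range(R):
            rows = rng.choice(n, size=m, replace=False)
            try:
                net = estimator(data.iloc[rows].reset_index(drop=True))
            except MusenetError:
                continue
            sub = _centrality.node_centrality(net)
            for ix in indices:
                x = full[ix].to_numpy()
                y = sub[ix].reindex(full.index).to_numpy()
                if np.std(x) == 0 or np.std(y) == 0 or np.isnan(y).any():
                    continue  # correlation undefined -> counted as failure
                cors[ix][gi, r] = np.corrcoef(x, y)[0, 1]
    effective = [q for q in grid if q not in skipped]
    cs = {
        ix: _cs_from_correlations(
            cors[ix][[grid.index(q) for q in effective]], effective,
            cor_threshold, proportion_threshold)
        for ix in indices
    }
    return CaseDropResult(grid, cors, cs, cor_threshold,
                          proportion_threshold, tuple(skipped))
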