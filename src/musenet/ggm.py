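"""Regularized partial-correlation network (Gaussian graphical model).

The estimation pipeline is the standard psychometric-network workflow:
columns are Gaussianized with the nonparanormal (copula) transformation,
a graphical-lasso regularization path is computed over a logarithmic grid
of penalties, and the network minimizing the extended Bayesian information
criterion (EBIC, default gamma = 0.5) is selected.  Edges of the selected
network are partial correlations rho_ij = -omega_ij / sqrt(omega_ii
omega_jj) from the estimated precision matrix Omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.covariance import graphical_lasso

from .errors import DegenerateDataError, EstimationError

#: Numerical threshold below which a precision entry counts as a zero edge.
EDGE_EPS = 1e-8


# ---------------------------------------------------------------------------
# Column transforms
# ---------------------------------------------------------------------------

def zscore(data: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standard scores (x - mean) / SD with sample SD (ddof=1)."""
    sd = data.std(ddof=1)
    degenerate = sd[sd <= 0]
    if len(degenerate):
        raise DegenerateDataError(
            f"constant column(s): {list(degenerate.index)}"
        )
    return (data - data.mean()) / sd


def npn_delta(n: int) -> float:
    """Winsorization level delta_n = 1 / (4 n^{1/4} sqrt(pi log n))."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def npn_transform(data: pd.DataFrame) -> pd.DataFrame:
    """Nonparanormal (shrunken-ECDF) Gaussianization of each column.

    Ranks are mapped through the empirical CDF winsorized to
    [delta_n, 1 - delta_n], then through the standard-normal quantile
    function, and finally rescaled to unit sample variance.  The transform
    depends on the data only through ranks, so it is invariant under
    strictly increasing column transformations.
    """
    n = len(data)
    if n < 2:
        raise DegenerateDataError("nonparanormal transform needs n >= 2")
    delta = npn_delta(n)
    out = {}
    for col in data.columns:
        ecdf = rankdata(data[col].to_numpy(), method="average") / n
        z = ndtri(np.clip(ecdf, delta, 1.0 - delta))
        sd = z.std(ddof=1)
        if np.ptp(z) == 0.0 or sd <= 1e-12:
            raise DegenerateDataError(f"constant column(s): [{col!r}]")
        out[col] = z / sd
    return pd.DataFrame(out, index=data.index)


# ---------------------------------------------------------------------------
# Graphical-lasso path and EBIC selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathPoint:
    """One point of the graphical-lasso regularization path."""

    lambda_: float
    precision: np.ndarray
    covariance: np.ndarray
    n_edges: int


@dataclass(frozen=True)
class PartialCorrelationNetwork:
    """Selected regularized partial-correlation network."""

    labels: tuple[str, ...]
    weights: np.ndarray          # symmetric, zero diagonal, entries in (-1, 1)
    precision: np.ndarray
    lambda_selected: float
    ebic_value: float
    gamma: float

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int((np.abs(np.triu(self.weights, 1)) > EDGE_EPS).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.labels),
                            columns=list(self.labels))

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as (node_a, node_b, weight) rows."""
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if abs(w) > EDGE_EPS:
                    rows.append((self.labels[i], self.labels[j], w))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """rho_ij = -omega_ij / sqrt(omega_ii omega_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def lambda_grid(s: np.ndarray, n_lambdas: int = 100,
                lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Decreasing logarithmic penalty grid from lambda_max down.

    lambda_max is the largest absolute off-diagonal sample covariance, the
    smallest penalty at which the graphical lasso returns an empty graph.
    """
    if n_lambdas < 2:
        raise EstimationError("need at least 2 penalty values")
    off = np.abs(s - np.diag(np.diag(s)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def glasso_path(data: pd.DataFrame, n_lambdas: int = 100,
                lambda_min_ratio: float = 0.01, tol: float = 1e-6,
                enet_tol: float = 1e-7, max_iter: int = 200
                ) -> list[PathPoint]:
    """Graphical-lasso regularization path on (standardized) data.

    Uses the empirical covariance S = X'X / n.  Penalties where the solver
    fails to converge are flagged with a warning and excluded from the path.
    """
    x = data.to_numpy(dtype=float)
    n = len(x)
    s = (x - x.mean(axis=0)).T @ (x - x.mean(axis=0)) / n
    path: list[PathPoint] = []
    for lam in lambda_grid(s, n_lambdas, lambda_min_ratio):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, prec = graphical_lasso(s, alpha=float(lam), tol=tol,
                                            enet_tol=enet_tol,
                                            max_iter=max_iter)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"graphical lasso failed at lambda={lam:.4g}: {exc}")
            continue
        n_edges = int((np.abs(np.triu(prec, 1)) > EDGE_EPS).sum())
        path.append(PathPoint(float(lam), prec, cov, n_edges))
    if not path:
        raise EstimationError("graphical lasso failed at every penalty")
    return path


def gaussian_loglik(s: np.ndarray, precision: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood n/2 (logdet O - tr(S O) - p log 2 pi)."""
    p = s.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(s @ precision) - p * np.log(2 * np.pi))


def ebic(s: np.ndarray, precision: np.ndarray, n: int,
         gamma: float = 0.5) -> float:
    """EBIC = -2 loglik + E log n + 4 gamma E log p, E = edge count."""
    p = s.shape[0]
    e = int((np.abs(np.triu(precision, 1)) > EDGE_EPS).sum())
    return (-2.0 * gaussian_loglik(s, precision, n)
            + e * np.log(n) + 4.0 * gamma * e * np.log(p))


def edge_threshold(n: int, p: int) -> float:
    """Detection bound sqrt(log(p (p-1) / 2) / n) for thresholded glasso.

    Partial correlations below this bound are indistinguishable from noise
    at sample size n; zeroing them restores sparsistency, which the plain
    EBIC-selected graphical lasso loses at large n (it admits many tiny
    spurious edges).
    """
    return float(np.sqrt(np.log(p * (p - 1) / 2.0) / n))


def select_by_ebic(data: pd.DataFrame, path: list[PathPoint],
                   gamma: float = 0.5,
                   threshold: bool = True) -> PartialCorrelationNetwork:
    """Select the path point minimizing the EBIC and return its network.

    With ``threshold=True`` (default) edges whose absolute partial
    correlation falls below :func:`edge_threshold` are removed after
    selection.
    """
    if not path:
        raise EstimationError("empty regularization path")
    x = data.to_numpy(dtype=float)
    n = len(x)
    s = (x - x.mean(axis=0)).T @ (x - x.mean(axis=0)) / n
    scores = [ebic(s, pt.precision, n, gamma) for pt in path]
    best = int(np.argmin(scores))
    pt = path[best]
    rho = partial_correlations(pt.precision)
    rho[np.abs(rho) <= EDGE_EPS] = 0.0
    if threshold:
        rho[np.abs(rho) < edge_threshold(n, s.shape[0])] = 0.0
    return PartialCorrelationNetwork(
        labels=tuple(str(c) for c in data.columns),
        weights=rho,
        precision=pt.precision,
        lambda_selected=pt.lambda_,
        ebic_value=float(scores[best]),
        gamma=gamma,
    )


def estimate_network(
    data: pd.DataFrame,
    *,
    transform: str = "npn",
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    threshold: bool = True,
) -> PartialCorrelationNetwork:
    """End-to-end RPCN estimation: transform, glasso path, EBIC selection.

    ``transform`` is one of ``"npn"`` (default; nonparanormal), ``"zscore"``,
    ``"zscore+npn"`` or ``"none"``.  ``threshold`` controls post-selection
    removal of sub-detection-bound edges (see :func:`select_by_ebic`).
    """
    if transform == "npn":
        std = npn_transform(data)
    elif transform == "zscore":
        std = zscore(data)
    elif transform == "zscore+npn":
        std = npn_transform(zscore(data))
    elif transform == "none":
        std = data
    else:
        raise EstimationError(f"unknown transform {transform!r}")
    path = glasso_path(std, n_lambdas, lambda_min_ratio)
    return select_by_ebic(std, path, gamma, threshold=threshold)
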