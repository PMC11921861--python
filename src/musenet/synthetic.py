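"""Synthetic questionnaire data with known statistical ground truth.

Three generators cover the three stages of the analysis pipeline:

* :func:`generate_dimension_scores` draws continuous dimension scores from a
  zero-mean Gaussian with a user-specified sparse precision matrix, then
  rescales each column to target means and standard deviations.  Per-column
  affine rescaling leaves the partial-correlation structure intact, so the
  precision matrix is an exact ground truth for network-recovery tests.
* :func:`sample_from_sem` simulates a linear-Gaussian structural equation
  model over a directed acyclic graph, the generating process assumed by
  Gaussian Bayesian-network structure learning.
* :func:`generate_item_responses` produces integer 1..5 Likert items from a
  per-dimension one-factor model, with factor loadings solved to approximate
  a requested Cronbach's alpha and discretization thresholds shifted so the
  scale-sum means approximate the calibration targets.

The default calibration targets are the whole-sample dimension means and
standard deviations of the study cohort (n = 16,588 Chinese college
students).  The default sparse precision matrix and default DAG are
illustrative structures that qualitatively echo the signs reported for the
empirical networks; they are not estimates of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Calibration targets: whole-sample dimension means (SDs) of the study cohort
# ---------------------------------------------------------------------------

#: Number of respondents in the study cohort.
DEFAULT_N = 16_588

#: Whole-sample mean and SD per dimension score.
TARGET_MOMENTS: dict[str, tuple[float, float]] = {
    "Anx": (7.68, 2.90),
    "Dep": (11.83, 4.47),
    "UHMU": (16.54, 5.94),
    "HMU": (16.44, 4.42),
    "DIF": (16.11, 6.31),
    "DDF": (12.83, 3.37),
    "EOT": (22.01, 3.15),
    "POS": (14.73, 3.41),
    "DES": (13.00, 3.54),
    "ANG": (13.06, 3.63),
}

#: Items per dimension (used by the Likert-item generator).
DIMENSION_ITEMS: dict[str, int] = {
    "Anx": 4, "Dep": 6, "UHMU": 8, "HMU": 5,
    "DIF": 7, "DDF": 5, "EOT": 8, "POS": 4, "DES": 4, "ANG": 4,
}

#: Node sets of the two analysis variants: the healthy-music-use networks
#: include HMU and exclude UHMU; the unhealthy variant is the reverse.
VARIANT_NODES: dict[str, list[str]] = {
    "healthy": ["HMU", "POS", "DES", "ANG", "DIF", "DDF", "EOT", "Anx", "Dep"],
    "unhealthy": ["UHMU", "POS", "DES", "ANG", "DIF", "DDF", "EOT", "Anx", "Dep"],
}


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionTruth:
    """Sparse-precision ground truth for partial-correlation networks."""

    labels: tuple[str, ...]
    precision: np.ndarray

    def __post_init__(self):
        omega = np.asarray(self.precision, dtype=float)
        if omega.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("precision shape does not match labels")
        if not np.allclose(omega, omega.T):
            raise ConfigError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise ConfigError("precision matrix must be positive definite")
        object.__setattr__(self, "precision", omega)

    @property
    def partial_correlations(self) -> np.ndarray:
        """True partial correlations rho_ij = -omega_ij / sqrt(omega_ii omega_jj)."""
        d = np.sqrt(np.diag(self.precision))
        rho = -self.precision / np.outer(d, d)
        np.fill_diagonal(rho, 0.0)
        return rho

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass(frozen=True)
class DagTruth:
    """Linear-Gaussian SEM ground truth for Bayesian-network recovery.

    ``arcs`` maps (parent, child) to the linear coefficient; ``intercepts``
    and ``noise_sd`` are per-node (defaults 0 and 1).
    """

    labels: tuple[str, ...]
    arcs: dict[tuple[str, str], float]
    intercepts: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.labels)
        for p, c in self.arcs:
            if p not in known or c not in known:
                raise ConfigError(f"arc ({p}, {c}) uses unknown label")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> list[str]:
        return [p for (p, c) in self.arcs if c == node]

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises ConfigError on a cycle."""
        indeg = {v: 0 for v in self.labels}
        for _, c in self.arcs:
            indeg[c] += 1
        order, ready = [], [v for v in self.labels if indeg[v] == 0]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for (p, c) in self.arcs:
                if p == v:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        ready.append(c)
        if len(order) != len(self.labels):
            raise ConfigError("arc set contains a directed cycle")
        return order

    @property
    def adjacencies(self) -> set[frozenset[str]]:
        return {frozenset((p, c)) for (p, c) in self.arcs}

    def implied_covariance(self) -> np.ndarray:
        """Model-implied covariance (I - B)^-1 D (I - B)^-T of the SEM."""
        idx = {v: i for i, v in enumerate(self.labels)}
        p = len(self.labels)
        b = np.zeros((p, p))
        for (par, ch), coef in self.arcs.items():
            b[idx[ch], idx[par]] = coef
        d = np.diag([self.noise_sd.get(v, 1.0) ** 2 for v in self.labels])
        inv = np.linalg.inv(np.eye(p) - b)
        return inv @ d @ inv.T


# ---------------------------------------------------------------------------
# Shipped illustrative ground truths
# ---------------------------------------------------------------------------

# Partial-correlation edge list per variant.  Signs echo the qualitative
# pattern of the reported undirected networks: a positive self-efficacy
# clique, positive alexithymia DIF-DDF with EOT attached, anxiety-depression
# comorbidity, self-efficacy protective against depression, healthy music use
# tied positively to POS and negatively to EOT, unhealthy music use tied to
# the symptom cluster.  Weights are illustrative round numbers.
_EDGES: dict[str, dict[tuple[str, str], float]] = {
    "healthy": {
        ("POS", "DES"): 0.30, ("POS", "ANG"): 0.20, ("DES", "ANG"): 0.35,
        ("DIF", "DDF"): 0.35, ("DDF", "EOT"): 0.20, ("DIF", "EOT"): -0.15,
        ("HMU", "POS"): 0.20, ("HMU", "EOT"): -0.15,
        ("DES", "Dep"): -0.25, ("ANG", "Dep"): -0.10,
        ("Anx", "Dep"): 0.40, ("DIF", "Anx"): 0.20,
    },
    "unhealthy": {
        ("POS", "DES"): 0.30, ("POS", "ANG"): 0.20, ("DES", "ANG"): 0.35,
        ("DIF", "DDF"): 0.35, ("DDF", "EOT"): 0.20, ("DIF", "EOT"): -0.15,
        ("UHMU", "POS"): -0.15, ("UHMU", "Anx"): 0.20, ("UHMU", "Dep"): 0.15,
        ("UHMU", "DIF"): 0.20,
        ("DES", "Dep"): -0.25, ("ANG", "Anx"): -0.10,
        ("Anx", "Dep"): 0.40, ("DIF", "Anx"): 0.20,
    },
}

# SEM arcs per variant, echoing the reported averaged directed networks:
# managing despondency-distress at the top, music use downstream of
# self-efficacy (healthy) or of the symptom cluster (unhealthy), externally
# oriented thinking last.  Coefficients are illustrative.
_DAG_ARCS: dict[str, dict[tuple[str, str], float]] = {
    "healthy": {
        ("DES", "ANG"): 0.6, ("DES", "POS"): 0.5, ("DES", "Dep"): -0.5,
        ("DES", "EOT"): 0.4, ("Dep", "DIF"): 0.6, ("Dep", "DDF"): 0.5,
        ("Dep", "Anx"): 0.6, ("DIF", "Anx"): 0.4,
        ("ANG", "HMU"): 0.5, ("POS", "HMU"): 0.5,
        ("HMU", "EOT"): -0.4, ("DDF", "EOT"): 0.4,
    },
    "unhealthy": {
        ("DES", "ANG"): 0.6, ("DES", "POS"): 0.5, ("DES", "Dep"): -0.5,
        ("DES", "EOT"): 0.4, ("Dep", "DIF"): 0.6, ("Dep", "DDF"): 0.5,
        ("Dep", "Anx"): 0.6, ("DIF", "Anx"): 0.4,
        ("Dep", "UHMU"): 0.5, ("Anx", "UHMU"): 0.4, ("DIF", "UHMU"): 0.4,
        ("UHMU", "EOT"): 0.4, ("POS", "EOT"): -0.4,
    },
}


def default_precision_truth(variant: str = "healthy") -> PrecisionTruth:
    """Shipped sparse 9-node precision matrix for the given variant.

    Built from the partial-correlation edge list as omega_ii = 1,
    omega_ij = -rho_ij, which is positive definite for these weights.
    """
    labels = VARIANT_NODES[variant]
    idx = {v: i for i, v in enumerate(labels)}
    omega = np.eye(len(labels))
    for (u, v), rho in _EDGES[variant].items():
        omega[idx[u], idx[v]] = omega[idx[v], idx[u]] = -rho
    return PrecisionTruth(tuple(labels), omega)


def default_dag_truth(variant: str = "healthy") -> DagTruth:
    """Shipped illustrative 9-node linear SEM for the given variant."""
    labels = VARIANT_NODES[variant]
    return DagTruth(tuple(labels), dict(_DAG_ARCS[variant]))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _targets_for(labels, target_means, target_sds):
    def pick(overrides, v, which):
        if overrides and v in overrides:
            return overrides[v]
        if v not in TARGET_MOMENTS:
            raise ConfigError(f"no calibration target for node {v!r}; "
                              f"supply target_means/target_sds")
        return TARGET_MOMENTS[v][which]

    means = np.array([pick(target_means, v, 0) for v in labels])
    sds = np.array([pick(target_sds, v, 1) for v in labels])
    if (sds <= 0).any():
        raise ConfigError("target SDs must be positive")
    return means, sds


def generate_dimension_scores(
    n: int,
    truth: PrecisionTruth | None = None,
    *,
    variant: str = "healthy",
    target_means: dict[str, float] | None = None,
    target_sds: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PrecisionTruth]:
    """Draw n respondents' dimension scores from a sparse-precision Gaussian.

    Rows are sampled from N(0, Omega^-1), each column divided by its
    population SD and affinely mapped to the target mean and SD.  The
    rescaling is per-column affine, so the partial-correlation pattern of
    ``truth`` is preserved exactly in the population.

    Returns the data frame (columns = truth labels) and the truth used.
    """
    if n < 2:
        raise ConfigError("n must be at least 2")
    if truth is None:
        truth = default_precision_truth(variant)
    means, sds = _targets_for(truth.labels, target_means, target_sds)
    rng = np.random.default_rng(seed)
    cov = truth.covariance
    z = rng.multivariate_normal(np.zeros(len(truth.labels)), cov, size=n,
                                method="cholesky")
    z /= np.sqrt(np.diag(cov))
    data = means + sds * z
    return pd.DataFrame(data, columns=list(truth.labels)), truth


def sample_from_sem(
    n: int,
    truth: DagTruth | None = None,
    *,
    variant: str = "healthy",
    seed: int = 0,
) -> tuple[pd.DataFrame, DagTruth]:
    """Simulate a linear-Gaussian SEM in topological order.

    Each node is its intercept plus the coefficient-weighted sum of its
    parents plus independent Gaussian noise.
    """
    if n < 1:
        raise ConfigError("n must be positive")
    if truth is None:
        truth = default_dag_truth(variant)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in truth.topological_order():
        x = np.full(n, truth.intercepts.get(node, 0.0))
        for (p, c), coef in truth.arcs.items():
            if c == node:
                x = x + coef * cols[p]
        sd = truth.noise_sd.get(node, 1.0)
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=n)
        cols[node] = x
    return pd.DataFrame({v: cols[v] for v in truth.labels}), truth


# ----- Likert items --------------------------------------------------------

def _loading_for_alpha(alpha: float, k: int) -> float:
    """Equal loading giving Cronbach's alpha ``alpha`` for k unit-variance items.

    With inter-item correlation r, alpha = k r / (1 + (k-1) r); inverting
    gives r = alpha / (k - alpha (k-1)) and loading sqrt(r).
    """
    if not 0 <= alpha < 1:
        raise ConfigError("alpha target must be in [0, 1)")
    r = alpha / (k - alpha * (k - 1))
    return float(np.sqrt(max(r, 0.0)))


def _shifted_thresholds(target_item_mean: float) -> np.ndarray:
    """Shift equal-probability quintile thresholds to hit a target item mean.

    Thresholds start at the standard-normal quintiles and are shifted by a
    scalar solved with Brent's method so that the expected category
    (1..5) of a unit-variance latent equals ``target_item_mean``.
    """
    base = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
    lo, hi = 1.0 + 1e-6, 5.0 - 1e-6
    target = min(max(target_item_mean, lo), hi)

    def expected_mean(shift: float) -> float:
        p = np.diff(np.concatenate(([0.0], stats.norm.cdf(base - shift), [1.0])))
        return float(p @ np.arange(1, 6))

    shift = optimize.brentq(lambda s: expected_mean(s) - target, -8.0, 8.0)
    return base - shift


def generate_item_responses(
    n: int,
    *,
    alpha_targets: dict[str, float] | None = None,
    target_means: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate integer 1..5 item responses for all four instruments.

    Per dimension, items follow a one-factor latent Gaussian model with equal
    loadings solved from the instrument's ``alpha_targets`` entry (default
    0.8 for every instrument), then are discretized through four thresholds
    shifted so the scale-sum mean approximates the dimension's calibration
    target.  Column names follow ``K10_1..`` / ``TAS_1..`` / ``RESE_1..`` /
    ``HUMS_1..``.
    """
    from . import scales  # local import to avoid cycle at import time

    if n < 2:
        raise ConfigError("n must be at least 2")
    alphas = {"K10": 0.8, "TAS": 0.8, "RESE": 0.8, "HUMS": 0.8}
    alphas.update(alpha_targets or {})
    rng = np.random.default_rng(seed)

    # dimension -> (instrument, item numbers within the instrument)
    layout: dict[str, tuple[str, tuple[int, ...]]] = {
        "Anx": ("K10", scales.K10_ANXIETY_ITEMS),
        "Dep": ("K10", scales.K10_DEPRESSION_ITEMS),
        "DIF": ("TAS", scales.TAS_FACETS["DIF"]),
        "DDF": ("TAS", scales.TAS_FACETS["DDF"]),
        "EOT": ("TAS", scales.TAS_FACETS["EOT"]),
        "POS": ("RESE", scales.RESE_DIMENSIONS["POS"]),
        "DES": ("RESE", scales.RESE_DIMENSIONS["DES"]),
        "ANG": ("RESE", scales.RESE_DIMENSIONS["ANG"]),
        "HMU": ("HUMS", scales.HUMS_HMU_ITEMS),
        "UHMU": ("HUMS", scales.HUMS_UHMU_ITEMS),
    }
    columns: dict[str, np.ndarray] = {}
    means = dict(TARGET_MOMENTS)
    for dim, (inst, items) in layout.items():
        k = len(items)
        lam = _loading_for_alpha(alphas[inst], k)
        noise_sd = np.sqrt(max(1.0 - lam**2, 0.0))
        factor = rng.normal(size=n)
        mean_target = (target_means or {}).get(dim, means[dim][0]) / k
        thresholds = _shifted_thresholds(mean_target)
        for item in items:
            latent = lam * factor + noise_sd * rng.normal(size=n)
            value = (np.digitize(latent, thresholds) + 1).astype(int)
            if inst == "TAS" and item in scales.TAS_REVERSE_ITEMS:
                # emit the raw (unrecoded) response so that scoring, which
                # recodes reverse-keyed items as 6 - x, recovers this value
                value = 6 - value
            columns[f"{inst}_{item}"] = value

    ordered = [f"{inst}_{i}" for inst, k in scales.ITEM_COUNTS.items()
               for i in range(1, k + 1)]
    return pd.DataFrame({c: columns[c] for c in ordered})
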