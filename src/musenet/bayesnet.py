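"""Gaussian Bayesian networks: hill-climbing structure learning, bootstrap
arc-strength averaging, and per-child linear models.

Structures are scored with the decomposable Gaussian BIC,

    score(G) = sum_nodes [ loglik(child | parents at OLS/MLE fit)
                           - (|parents| + 2) / 2 * log n ],

counting per node the parent coefficients, the intercept and the residual
variance (k + 2 parameters).  Hill climbing greedily applies the best
add / delete / reverse arc move until no move improves the score, with
random restarts that perturb the incumbent by a number of random legal
moves.  Local scores are computed from the Gram matrix of the data, so a
score evaluation costs O(k^3) independent of the sample size, and are
cached per (child, parent set).

Bootstrap confidence in arcs is the fraction of row-resampled structure
learns in which a node pair is adjacent (strength) and, among those, the
fraction oriented a given way (direction).  The averaged network keeps
pairs with strength >= 0.85 oriented by direction > 0.5 and resolves any
residual cycle by dropping the weakest arc in it.  Each child node of the
averaged network is then refit by ordinary least squares, reporting the
per-parent coefficient, SE and t-test p-value plus the model R^2, residual
standard error and overall F-test p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigError, EstimationError

#: Minimum score improvement for a hill-climbing move to be accepted.
SCORE_TOL = 1e-9


# ---------------------------------------------------------------------------
# DAG container
# ---------------------------------------------------------------------------

class DAG:
    """Directed acyclic graph over labeled nodes.

    Arcs are (parent, child) label pairs.  Every mutation re-checks
    acyclicity and raises :class:`ConfigError` if it would create a cycle,
    a duplicate arc or a self-loop.
    """

    def __init__(self, labels, arcs=()):
        self.labels: tuple[str, ...] = tuple(labels)
        self._index = {v: i for i, v in enumerate(self.labels)}
        self.parents: dict[str, set[str]] = {v: set() for v in self.labels}
        for p, c in arcs:
            self.add_arc(p, c)

    @property
    def arcs(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def copy(self) -> "DAG":
        new = DAG(self.labels)
        new.parents = {v: set(ps) for v, ps in self.parents.items()}
        return new

    def has_arc(self, p: str, c: str) -> bool:
        return p in self.parents[c]

    def adjacent(self, u: str, v: str) -> bool:
        return self.has_arc(u, v) or self.has_arc(v, u)

    def _reachable(self, start: str, goal: str) -> bool:
        """True if a directed path start -> ... -> goal exists."""
        stack, seen = [start], {start}
        children = {v: [] for v in self.labels}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].append(c)
        while stack:
            u = stack.pop()
            if u == goal:
                return True
            for c in children[u]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def can_add(self, p: str, c: str) -> bool:
        return (p != c and not self.adjacent(p, c)
                and not self._reachable(c, p))

    def can_reverse(self, p: str, c: str) -> bool:
        if not self.has_arc(p, c):
            return False
        self.parents[c].discard(p)
        ok = not self._reachable(p, c)
        self.parents[c].add(p)
        return ok

    def add_arc(self, p: str, c: str) -> None:
        if p == c:
            raise ConfigError(f"self-loop {p} -> {c}")
        if self.has_arc(p, c):
            raise ConfigError(f"duplicate arc {p} -> {c}")
        if self._reachable(c, p):
            raise ConfigError(f"arc {p} -> {c} would create a cycle")
        self.parents[c].add(p)

    def remove_arc(self, p: str, c: str) -> None:
        self.parents[c].discard(p)

    def reverse_arc(self, p: str, c: str) -> None:
        self.remove_arc(p, c)
        self.add_arc(c, p)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DAG) and self.labels == other.labels
                and self.parents == other.parents)

    def __repr__(self) -> str:
        arcs = sorted(self.arcs)
        return f"DAG({list(self.labels)}, arcs={arcs})"


# ---------------------------------------------------------------------------
# Gaussian BIC scorer
# ---------------------------------------------------------------------------

class GaussianBICScorer:
    """Decomposable Gaussian BIC local scores from sufficient statistics.

    The Gram matrix of [1, X] is computed once; the residual sum of squares
    of any child-on-parents OLS fit then follows from a small linear solve,
    independent of n.  Local scores are cached per (child, parent set).
    """

    def __init__(self, data: pd.DataFrame):
        self.labels = tuple(str(c) for c in data.columns)
        self._col = {v: i + 1 for i, v in enumerate(self.labels)}  # 0 = const
        x = data.to_numpy(dtype=float)
        self.n = len(x)
        if self.n < 3:
            raise ConfigError("scorer needs at least 3 rows")
        z = np.column_stack([np.ones(self.n), x])
        self.gram = z.T @ z
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def _rss(self, child: str, parents: tuple[str, ...]) -> float:
        ci = self._col[child]
        idx = [0] + [self._col[p] for p in parents]
        sxx = self.gram[np.ix_(idx, idx)]
        sxy = self.gram[idx, ci]
        syy = self.gram[ci, ci]
        try:
            beta = linalg.solve(sxx, sxy, assume_a="pos")
        except linalg.LinAlgError:
            return np.nan
        return float(syy - sxy @ beta)

    def local_score(self, child: str, parents) -> float:
        """loglik at the MLE minus (k + 2)/2 log n for one node."""
        key = (child, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        rss = self._rss(child, key[1])
        n = self.n
        if not np.isfinite(rss) or rss <= n * 1e-12:
            score = -np.inf  # singular design or perfect fit
        else:
            sigma2 = rss / n
            loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
            score = loglik - 0.5 * (len(key[1]) + 2) * np.log(n)
        self._cache[key] = score
        return score

    def score(self, dag: DAG) -> float:
        return sum(self.local_score(v, dag.parents[v]) for v in dag.labels)


def bic_g_score(data: pd.DataFrame, dag: DAG) -> float:
    """Gaussian BIC of a DAG on the data (node-wise additive)."""
    if set(dag.labels) != set(map(str, data.columns)):
        raise ConfigError("DAG labels do not match data columns")
    return GaussianBICScorer(data[list(dag.labels)]).score(dag)


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

def _legal_moves(dag: DAG):
    """All legal moves in deterministic (op, parent, child) order."""
    labels = dag.labels
    for op_rank, op in enumerate(("add", "delete", "reverse")):
        for p in labels:
            for c in labels:
                if p == c:
                    continue
                if op == "add" and dag.can_add(p, c):
                    yield op, p, c
                elif op == "delete" and dag.has_arc(p, c):
                    yield op, p, c
                elif op == "reverse" and dag.can_reverse(p, c):
                    yield op, p, c


def _move_delta(scorer: GaussianBICScorer, dag: DAG, op: str,
                p: str, c: str) -> float:
    old_c = scorer.local_score(c, dag.parents[c])
    if op == "add":
        return scorer.local_score(c, dag.parents[c] | {p}) - old_c
    if op == "delete":
        return scorer.local_score(c, dag.parents[c] - {p}) - old_c
    old_p = scorer.local_score(p, dag.parents[p])
    return (scorer.local_score(c, dag.parents[c] - {p}) - old_c
            + scorer.local_score(p, dag.parents[p] | {c}) - old_p)


def _apply(dag: DAG, op: str, p: str, c: str) -> None:
    if op == "add":
        dag.add_arc(p, c)
    elif op == "delete":
        dag.remove_arc(p, c)
    else:
        dag.reverse_arc(p, c)


def _greedy(scorer: GaussianBICScorer, dag: DAG) -> tuple[DAG, float]:
    """Steepest-ascent local search to a local optimum."""
    score = scorer.score(dag)
    while True:
        best_delta, best_move = SCORE_TOL, None
        for op, p, c in _legal_moves(dag):
            delta = _move_delta(scorer, dag, op, p, c)
            if delta > best_delta + SCORE_TOL:
                best_delta, best_move = delta, (op, p, c)
        if best_move is None:
            return dag, score
        _apply(dag, *best_move)
        score += best_delta


def _perturb(dag: DAG, n_moves: int, rng: np.random.Generator) -> DAG:
    """Apply random legal moves to diversify a restart's starting point."""
    out = dag.copy()
    for _ in range(n_moves):
        moves = list(_legal_moves(out))
        if not moves:
            break
        op, p, c = moves[rng.integers(len(moves))]
        _apply(out, op, p, c)
    return out


def hill_climb(data: pd.DataFrame, restarts: int = 50,
               perturbations: int = 100, seed: int = 0,
               scorer: GaussianBICScorer | None = None) -> DAG:
    """Greedy hill-climbing structure search with random restarts.

    Starts from the empty graph and climbs to a local optimum; each of the
    ``restarts`` additional climbs starts from the incumbent best DAG
    perturbed by ``perturbations`` random legal arc moves.  Deterministic
    given the seed; move ties are broken by (operation, parent, child)
    order.
    """
    if restarts < 0:
        raise ConfigError("restarts must be >= 0")
    if scorer is None:
        scorer = GaussianBICScorer(data)
    rng = np.random.default_rng(seed)
    best, best_score = _greedy(scorer, DAG(scorer.labels))
    for _ in range(restarts):
        start = _perturb(best, perturbations, rng)
        cand, cand_score = _greedy(scorer, start)
        if cand_score > best_score + SCORE_TOL:
            best, best_score = cand, cand_score
    return best


# ---------------------------------------------------------------------------
# Bootstrap arc confidence and the averaged network
# ---------------------------------------------------------------------------

@dataclass
class ArcConfidence:
    """Bootstrap adjacency and orientation frequencies per node pair."""

    labels: tuple[str, ...]
    n_replicates: int
    n_failed: int = 0
    #: (u, v) ordered pair -> number of replicate DAGs containing u -> v
    arc_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @classmethod
    def from_dags(cls, dags, labels=None, n_failed: int = 0
                  ) -> "ArcConfidence":
        dags = list(dags)
        if labels is None:
            labels = dags[0].labels
        counts: dict[tuple[str, str], int] = {}
        for dag in dags:
            for arc in dag.arcs:
                counts[arc] = counts.get(arc, 0) + 1
        return cls(tuple(labels), len(dags), n_failed, counts)

    def strength(self, u: str, v: str) -> float:
        """Fraction of replicates in which u and v are adjacent."""
        c = self.arc_counts.get((u, v), 0) + self.arc_counts.get((v, u), 0)
        return c / self.n_replicates

    def direction(self, u: str, v: str) -> float:
        """Among adjacency-containing replicates, fraction oriented u -> v."""
        uv = self.arc_counts.get((u, v), 0)
        vu = self.arc_counts.get((v, u), 0)
        return uv / (uv + vu) if uv + vu else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.labels):
            for v in self.labels[i + 1:]:
                s = self.strength(u, v)
                if s > 0:
                    rows.append((u, v, s, self.direction(u, v)))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "strength",
                                           "direction_a_to_b"])


def bootstrap_arcs(data: pd.DataFrame, R: int = 1000, restarts: int = 3,
                   perturbations: int = 15, seed: int = 0) -> ArcConfidence:
    """Arc confidence from R bootstrap resamples of the rows (size n).

    Each resample is structure-learned with :func:`hill_climb` (fewer
    restarts than a single final fit, configurable).  Replicates whose
    learn fails are dropped and counted.
    """
    if R < 1:
        raise ConfigError("R must be positive")
    rng = np.random.default_rng(seed)
    n = len(data)
    dags, failed = [], 0
    for _ in range(R):
        rows = rng.integers(n, size=n)
        sub = data.iloc[rows].reset_index(drop=True)
        try:
            dags.append(hill_climb(sub, restarts=restarts,
                                   perturbations=perturbations,
                                   seed=int(rng.integers(2**31))))
        except (EstimationError, ConfigError, np.linalg.LinAlgError):
            failed += 1
    if not dags:
        raise EstimationError("every bootstrap replicate failed")
    labels = tuple(str(c) for c in data.columns)
    conf = ArcConfidence.from_dags(dags, labels, n_failed=failed)
    return conf


@dataclass(frozen=True)
class AveragedArc:
    parent: str
    child: str
    strength: float
    direction: float


@dataclass(frozen=True)
class AveragedNetwork:
    """Bootstrap-thresholded consensus DAG with arc strengths/directions."""

    labels: tuple[str, ...]
    arcs: tuple[AveragedArc, ...]
    strength_threshold: float
    direction_threshold: float

    def dag(self) -> DAG:
        return DAG(self.labels, [(a.parent, a.child) for a in self.arcs])

    def parents(self, child: str) -> list[str]:
        return [a.parent for a in self.arcs if a.child == child]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.parent, a.child, a.strength, a.direction) for a in self.arcs],
            columns=["parent", "child", "strength", "direction"],
        )


def _find_cycle(arcs: list[AveragedArc]) -> list[AveragedArc] | None:
    """Return the arcs of one directed cycle, or None if acyclic."""
    children: dict[str, list[AveragedArc]] = {}
    for a in arcs:
        children.setdefault(a.parent, []).append(a)

    state: dict[str, int] = {}  # 0 unseen / 1 on stack / 2 done

    def dfs(v: str, trail: list[AveragedArc]):
        state[v] = 1
        for a in children.get(v, ()):
            if state.get(a.child, 0) == 1:
                i = next(k for k, b in enumerate(trail)
                         if b.parent == a.child)
                return trail[i:] + [a]
            if state.get(a.child, 0) == 0:
                found = dfs(a.child, trail + [a])
                if found:
                    return found
        state[v] = 2
        return None

    for a in arcs:
        if state.get(a.parent, 0) == 0:
            cycle = dfs(a.parent, [])
            if cycle:
                return cycle
    return None


def _break_cycles(arcs: list[AveragedArc], labels) -> list[AveragedArc]:
    """Drop the lowest-strength arc of each directed cycle until acyclic."""
    arcs = list(arcs)
    while True:
        cycle = _find_cycle(arcs)
        if cycle is None:
            return arcs
        weakest = min(cycle, key=lambda a: (a.strength, a.parent, a.child))
        warnings.warn(
            f"averaged network contained a cycle; dropped weakest arc "
            f"{weakest.parent} -> {weakest.child} "
            f"(strength {weakest.strength:.3f})"
        )
        arcs.remove(weakest)


def averaged_network(conf: ArcConfidence, strength_threshold: float = 0.85,
                     direction_threshold: float = 0.5) -> AveragedNetwork:
    """Consensus network keeping pairs with strength >= threshold.

    Retained pairs are oriented by direction > threshold (strict: exact
    50/50 pairs are ambiguous and excluded with a warning).  Any residual
    directed cycle is resolved by dropping its weakest arc.  Arcs are
    emitted sorted by strength descending.
    """
    if not (0 < strength_threshold < 1 and 0 < direction_threshold < 1):
        raise ConfigError("thresholds must lie in (0, 1)")
    arcs: list[AveragedArc] = []
    for i, u in enumerate(conf.labels):
        for v in conf.labels[i + 1:]:
            s = conf.strength(u, v)
            if s < strength_threshold:
                continue
            d_uv = conf.direction(u, v)
            if d_uv > direction_threshold:
                arcs.append(AveragedArc(u, v, s, d_uv))
            elif 1.0 - d_uv > direction_threshold:
                arcs.append(AveragedArc(v, u, s, 1.0 - d_uv))
            else:
                warnings.warn(f"pair {u} - {v} has ambiguous direction "
                              f"({d_uv:.2f}); excluded from averaged network")
    arcs = _break_cycles(arcs, conf.labels)
    arcs.sort(key=lambda a: (-a.strength, a.parent, a.child))
    return AveragedNetwork(conf.labels, tuple(arcs), strength_threshold,
                           direction_threshold)


# ---------------------------------------------------------------------------
# Per-child linear models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChildNodeRegression:
    """OLS fit of one child node on its averaged-network parents."""

    child: str
    parents: tuple[str, ...]
    intercept: float
    estimates: dict[str, float]      # parent -> beta
    standard_errors: dict[str, float]
    p_values: dict[str, float]       # per-parent two-sided t-test
    r_squared: float
    rse: float                       # residual standard error
    overall_p: float                 # F-test of the full model

    def to_rows(self) -> list[dict]:
        return [
            {"child": self.child, "parent": p,
             "estimate": self.estimates[p],
             "se": self.standard_errors[p], "p_value": self.p_values[p],
             "intercept": self.intercept, "r_squared": self.r_squared,
             "rse": self.rse, "overall_p": self.overall_p}
            for p in self.parents
        ]


def fit_child_regressions(data: pd.DataFrame, avg: AveragedNetwork
                          ) -> list[ChildNodeRegression]:
    """OLS of each child with >= 1 parent in the averaged network.

    Reports per-parent beta, SE and two-sided t-test p, plus model R^2,
    residual standard error RSE = sqrt(RSS / (n - k - 1)) and the overall
    F-test p-value.  Parentless nodes yield no regression.
    """
    out: list[ChildNodeRegression] = []
    n = len(data)
    for child in avg.labels:
        parents = sorted(avg.parents(child))
        if not parents:
            continue
        x = data[parents].to_numpy(dtype=float)
        y = data[child].to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), x])
        k = len(parents)
        if np.linalg.matrix_rank(design) < k + 1:
            raise EstimationError(f"collinear parents for child {child!r}: "
                                  f"{parents}")
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        dof = n - k - 1
        sigma2 = rss / dof if dof > 0 else np.nan
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        if rss <= 0 or dof <= 0:
            overall_p = 0.0
        else:
            f = (tss - rss) / k / (rss / dof)
            overall_p = float(stats.f.sf(f, k, dof))
        out.append(ChildNodeRegression(
            child=child, parents=tuple(parents), intercept=float(beta[0]),
            estimates={p: float(b) for p, b in zip(parents, beta[1:])},
            standard_errors={p: float(s) for p, s in zip(parents, se[1:])},
            p_values={p: float(v) for p, v in zip(parents, pvals[1:])},
            r_squared=float(r2), rse=float(np.sqrt(max(sigma2, 0.0))),
            overall_p=overall_p,
        ))
    return out


def regressions_frame(regs: list[ChildNodeRegression]) -> pd.DataFrame:
    rows = [row for reg in regs for row in reg.to_rows()]
    cols = ["child", "parent", "estimate", "se", "p_value", "intercept",
            "r_squared", "rse", "overall_p"]
    return pd.DataFrame(rows, columns=cols)
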