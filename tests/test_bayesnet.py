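"""Structure scoring, hill climbing, bootstrap averaging and child models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from musenet import bayesnet as bn
from musenet import ggm, synthetic
from musenet.errors import ConfigError, EstimationError


def all_dags(labels):
    """Every DAG over the labels (25 for three nodes)."""
    pairs = [(u, v) for u in labels for v in labels if u != v]
    for mask in itertools.product([False, True], repeat=len(pairs)):
        arcs = [p for p, keep in zip(pairs, mask) if keep]
        try:
            yield bn.DAG(labels, arcs)
        except ConfigError:
            continue


class TestDAG:
    def test_mutations_preserve_acyclicity(self):
        dag = bn.DAG(("A", "B", "C"))
        dag.add_arc("A", "B")
        dag.add_arc("B", "C")
        with pytest.raises(ConfigError, match="cycle"):
            dag.add_arc("C", "A")
        with pytest.raises(ConfigError, match="duplicate"):
            dag.add_arc("A", "B")
        with pytest.raises(ConfigError, match="self-loop"):
            dag.add_arc("A", "A")
        dag.reverse_arc("A", "B")
        assert dag.has_arc("B", "A")

    def test_three_node_dag_count_is_25(self):
        assert sum(1 for _ in all_dags(("A", "B", "C"))) == 25


class TestGaussianBIC:
    def test_empty_graph_matches_univariate_closed_form(self, rng):
        data = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("ABC"))
        n = len(data)
        expected = 0.0
        for col in data:
            s2 = data[col].var(ddof=0)
            expected += (-0.5 * n * (np.log(2 * np.pi * s2) + 1)
                         - np.log(n))  # (0 parents + 2)/2 * log n
        got = bn.bic_g_score(data, bn.DAG(("A", "B", "C")))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_adding_an_arc_leaves_other_local_scores_unchanged(self, rng):
        data = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("ABC"))
        scorer = bn.GaussianBICScorer(data)
        before = scorer.local_score("C", set())
        dag = bn.DAG(("A", "B", "C"), [("A", "B")])
        scorer.score(dag)
        assert scorer.local_score("C", set()) == before

    def test_score_equivalence_on_two_nodes(self, rng):
        x = rng.normal(size=300)
        y = 0.7 * x + rng.normal(size=300)
        data = pd.DataFrame({"A": x, "B": y})
        fwd = bn.bic_g_score(data, bn.DAG(("A", "B"), [("A", "B")]))
        rev = bn.bic_g_score(data, bn.DAG(("A", "B"), [("B", "A")]))
        assert fwd == pytest.approx(rev, rel=1e-10)

    def test_score_equivalence_on_three_node_markov_class(self, rng):
        # chain A->B->C, chain C->B->A and fork B->A, B->C are equivalent
        x = rng.normal(size=400)
        y = 0.8 * x + rng.normal(size=400)
        z = 0.8 * y + rng.normal(size=400)
        data = pd.DataFrame({"A": x, "B": y, "C": z})
        scores = [
            bn.bic_g_score(data, bn.DAG(("A", "B", "C"),
                                        [("A", "B"), ("B", "C")])),
            bn.bic_g_score(data, bn.DAG(("A", "B", "C"),
                                        [("C", "B"), ("B", "A")])),
            bn.bic_g_score(data, bn.DAG(("A", "B", "C"),
                                        [("B", "A"), ("B", "C")])),
        ]
        assert scores[0] == pytest.approx(scores[1], rel=1e-10)
        assert scores[0] == pytest.approx(scores[2], rel=1e-10)

    def test_singular_parent_design_scores_minus_infinity(self):
        data = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0],
                             "B": [2.0, 4.0, 6.0, 8.0],
                             "C": [1.0, 0.0, 1.0, 0.0]})
        scorer = bn.GaussianBICScorer(data)
        assert scorer.local_score("C", {"A", "B"}) == -np.inf


class TestHillClimb:
    def test_independent_noise_gives_empty_graph(self, rng):
        data = pd.DataFrame(rng.normal(size=(2000, 2)), columns=["A", "B"])
        dag = bn.hill_climb(data, restarts=3, perturbations=5, seed=0)
        assert dag.arcs == set()
        # exhaustive confirmation over the 3 two-node structures
        scorer = bn.GaussianBICScorer(data)
        best = max(all_dags(("A", "B")), key=scorer.score)
        assert best.arcs == set()

    def test_chain_data_reaches_global_optimum_of_25_dags(self):
        truth = synthetic.DagTruth(("A", "B", "C"),
                                   {("A", "B"): 0.9, ("B", "C"): 0.9})
        data, _ = synthetic.sample_from_sem(2000, truth, seed=13)
        scorer = bn.GaussianBICScorer(data)
        found = bn.hill_climb(data, restarts=5, perturbations=10, seed=1)
        best_score = max(scorer.score(d) for d in all_dags(("A", "B", "C")))
        assert scorer.score(found) == pytest.approx(best_score, rel=1e-12)

    def test_seeded_determinism(self, rng):
        data = pd.DataFrame(rng.normal(size=(300, 4)),
                            columns=list("ABCD"))
        a = bn.hill_climb(data, restarts=4, perturbations=8, seed=7)
        b = bn.hill_climb(data, restarts=4, perturbations=8, seed=7)
        assert a == b

    def test_returned_score_at_least_empty_graph_score(self, rng):
        data = pd.DataFrame(rng.normal(size=(300, 4)),
                            columns=list("ABCD"))
        scorer = bn.GaussianBICScorer(data)
        found = bn.hill_climb(data, restarts=2, perturbations=5, seed=3)
        assert scorer.score(found) >= scorer.score(bn.DAG(scorer.labels))


class TestArcConfidence:
    def test_strength_is_adjacency_frequency(self):
        labels = ("A", "B")
        dags = [bn.DAG(labels, [("A", "B")])] * 9 + [bn.DAG(labels)]
        conf = bn.ArcConfidence.from_dags(dags)
        assert conf.strength("A", "B") == pytest.approx(0.9)

    def test_direction_is_orientation_frequency_among_adjacent(self):
        labels = ("A", "B")
        dags = ([bn.DAG(labels, [("A", "B")])] * 6
                + [bn.DAG(labels, [("B", "A")])] * 3
                + [bn.DAG(labels)])
        conf = bn.ArcConfidence.from_dags(dags)
        assert conf.direction("A", "B") == pytest.approx(2 / 3)
        assert conf.direction("A", "B") + conf.direction("B", "A") == \
            pytest.approx(1.0)

    def test_independent_noise_has_low_arc_strengths(self, rng):
        data = pd.DataFrame(rng.normal(size=(1000, 3)),
                            columns=list("ABC"))
        conf = bn.bootstrap_arcs(data, R=200, restarts=1, perturbations=5,
                                 seed=11)
        for u, v in itertools.combinations("ABC", 2):
            assert conf.strength(u, v) < 0.3

    def test_bootstrap_determinism(self, rng):
        data = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("ABC"))
        a = bn.bootstrap_arcs(data, R=60, seed=5)
        b = bn.bootstrap_arcs(data, R=60, seed=5)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


class TestAveragedNetwork:
    def _conf(self, arc_counts, R=100, labels=("A", "B", "C")):
        return bn.ArcConfidence(labels, R, 0, arc_counts)

    def test_strength_below_threshold_excluded(self):
        conf = self._conf({("A", "B"): 80})
        avg = bn.averaged_network(conf)
        assert avg.arcs == ()

    def test_retained_with_orientation(self):
        conf = self._conf({("A", "B"): 90})
        avg = bn.averaged_network(conf)
        assert len(avg.arcs) == 1
        arc = avg.arcs[0]
        assert (arc.parent, arc.child) == ("A", "B")
        assert arc.strength == pytest.approx(0.9)
        assert arc.direction == pytest.approx(1.0)

    def test_exact_fifty_fifty_direction_excluded(self):
        conf = self._conf({("A", "B"): 45, ("B", "A"): 45})
        with pytest.warns(UserWarning, match="ambiguous"):
            avg = bn.averaged_network(conf)
        assert avg.arcs == ()

    def test_three_cycle_resolved_by_dropping_weakest(self):
        conf = self._conf({("A", "B"): 95, ("B", "C"): 90, ("C", "A"): 86})
        with pytest.warns(UserWarning, match="cycle"):
            avg = bn.averaged_network(conf)
        arcs = {(a.parent, a.child) for a in avg.arcs}
        assert arcs == {("A", "B"), ("B", "C")}
        avg.dag()  # acyclic by construction

    def test_arcs_sorted_by_strength_descending(self):
        conf = self._conf({("A", "B"): 86, ("B", "C"): 99})
        avg = bn.averaged_network(conf)
        strengths = [a.strength for a in avg.arcs]
        assert strengths == sorted(strengths, reverse=True)


class TestChildRegressions:
    def _avg(self, labels, arcs):
        conf = bn.ArcConfidence(tuple(labels), 1, 0,
                                {a: 1 for a in arcs})
        return bn.averaged_network(conf)

    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"A": x, "B": 2.0 * x})
        regs = bn.fit_child_regressions(data, self._avg("AB", [("A", "B")]))
        (reg,) = regs
        assert reg.estimates["A"] == pytest.approx(2.0)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.rse == pytest.approx(0.0, abs=1e-10)

    def test_parentless_node_yields_no_regression(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["A", "B"])
        regs = bn.fit_child_regressions(data, self._avg("AB", [("A", "B")]))
        assert [r.child for r in regs] == ["B"]

    def test_matches_normal_equations_oracle_on_printed_rows(self):
        # fixed 6-row dataset, child C on parents A and B
        data = pd.DataFrame({
            "A": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "B": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
            "C": [1.1, 1.9, 3.2, 3.8, 5.1, 6.2],
        })
        avg = self._avg("ABC", [("A", "C"), ("B", "C")])
        (reg,) = bn.fit_child_regressions(data, avg)

        # independent oracle: explicit normal equations
        x = np.column_stack([np.ones(6), data["A"], data["B"]])
        y = data["C"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        rss = resid @ resid
        sigma2 = rss / (6 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(x.T @ x)))
        r2 = 1 - rss / ((y - y.mean()) ** 2).sum()

        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.estimates["A"] == pytest.approx(beta[1], abs=1e-10)
        assert reg.estimates["B"] == pytest.approx(beta[2], abs=1e-10)
        assert reg.standard_errors["A"] == pytest.approx(se[1], abs=1e-10)
        assert reg.r_squared == pytest.approx(r2, abs=1e-10)
        assert reg.rse == pytest.approx(np.sqrt(sigma2), abs=1e-10)

    def test_collinear_parents_named_in_error(self):
        x = np.arange(8.0)
        data = pd.DataFrame({"A": x, "B": 2 * x, "C": x + 1})
        avg = self._avg("ABC", [("A", "C"), ("B", "C")])
        with pytest.raises(EstimationError, match="'C'"):
            bn.fit_child_regressions(data, avg)


class TestRecovery:
    def test_averaged_network_recovers_sem_structure(self):
        """Adjacency recovery on the shipped 9-node SEM (reduced R)."""
        data, truth = synthetic.sample_from_sem(5000, seed=7)
        std = ggm.zscore(data)
        conf = bn.bootstrap_arcs(std, R=60, seed=2)
        avg = bn.averaged_network(conf)
        est = {frozenset((a.parent, a.child)) for a in avg.arcs}
        true_adj = truth.adjacencies
        moral = set(true_adj)
        for v in truth.labels:
            ps = truth.parents(v)
            for a, b in itertools.combinations(ps, 2):
                moral.add(frozenset((a, b)))
        assert len(true_adj & est) / len(true_adj) >= 0.7
        assert all(pair in moral for pair in est)
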