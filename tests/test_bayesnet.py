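"""Discretization, BDe scoring, structure search and inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from modulebayes import (
    BNModel,
    DiscreteData,
    bde_score,
    bootstrap_structures,
    consensus_network,
    fit_parameters,
    hartemink_discretize,
    hill_climb,
)
from modulebayes.bayesnet import (
    _initial_bins,
    _mutual_information,
    dag_arcs,
    is_acyclic,
)

# ---------------------------------------------------------------------------
# helpers shared with the acceptance suite


def all_dags(nodes):
    """Every labelled DAG on ``nodes`` (543 for four nodes)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(1 << len(pairs)):
        arcs = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        arc_set = set(arcs)
        if any((v, u) in arc_set for u, v in arcs):
            continue
        dag = {x: frozenset(u for u, v in arcs if v == x) for x in nodes}
        if is_acyclic(dag):
            yield dag


def random_bn(nodes, arities, rng, edge_prob=0.4, conc=0.5, forbid_children_of=None):
    """Random DAG (topological order = node order) with Dirichlet CPTs."""
    parents = {n: [] for n in nodes}
    for j, v in enumerate(nodes):
        for u in nodes[:j]:
            if forbid_children_of and u in forbid_children_of:
                continue
            if rng.random() < edge_prob:
                parents[v].append(u)
    parents = {n: tuple(sorted(p)) for n, p in parents.items()}
    cpts = {}
    for n in nodes:
        r = arities[n]
        q = int(np.prod([arities[p] for p in parents[n]])) if parents[n] else 1
        cpt = rng.dirichlet([conc] * r, size=q).T  # (r, q)
        cpts[n] = np.clip(cpt, 1e-6, None)
        cpts[n] /= cpts[n].sum(axis=0, keepdims=True)
    return BNModel(nodes=list(nodes), parents=parents, arities=dict(arities),
                   cpts=cpts)


def sample_from_bn(model: BNModel, n: int, rng) -> pd.DataFrame:
    """Forward (ancestral) sampling oracle for a fitted discrete network."""
    out = {v: np.zeros(n, dtype=int) for v in model.nodes}
    from modulebayes.bayesnet import topological_order

    order = topological_order(model.dag())
    for i in range(n):
        assign = {}
        for v in order:
            j = model.parent_config_index(v, assign)
            p = model.cpts[v][:, j]
            assign[v] = int(rng.choice(model.arities[v], p=p / p.sum()))
        for v in model.nodes:
            out[v][i] = assign[v]
    return pd.DataFrame(out)


def skeleton_and_vstructs(dag):
    skel = frozenset(frozenset(a) for a in dag_arcs(dag))
    vs = set()
    for c, ps in dag.items():
        for a, b in itertools.combinations(sorted(ps), 2):
            if frozenset((a, b)) not in skel:
                vs.add((a, b, c))
    return skel, frozenset(vs)


# ---------------------------------------------------------------------------
# Hartemink discretization


class TestHarteminkDiscretize:
    def test_three_distinct_values_map_to_themselves(self):
        e = pd.DataFrame({"a": [0.0, 1.0, 5.0, 1.0, 0.0, 5.0],
                          "b": np.arange(6.0)})
        _, disc = hartemink_discretize(e, levels=3, ibreaks=20)
        assert list(disc["a"]) == [0, 1, 2, 1, 0, 2]

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(0)
        e = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        _, d1 = hartemink_discretize(e, levels=3, ibreaks=8)
        e2 = pd.DataFrame({"a": np.exp(e["a"]), "b": e["b"] ** 3,
                           "c": 5 * e["c"] - 2})
        _, d2 = hartemink_discretize(e2, levels=3, ibreaks=8)
        pd.testing.assert_frame_equal(d1, d2)

    def test_constant_variable_gets_middle_level(self):
        e = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        model, disc = hartemink_discretize(e, levels=3)
        assert (disc["a"] == 1).all()
        # replay on varying data still lands in the middle
        new = pd.DataFrame({"a": np.linspace(-3, 3, 7), "b": np.arange(7.0)})
        assert (model.transform(new)["a"] == 1).all()

    def test_replay_reproduces_training_assignment(self):
        rng = np.random.default_rng(1)
        e = pd.DataFrame(rng.normal(size=(60, 4)),
                         columns=[f"v{i}" for i in range(4)])
        model, disc = hartemink_discretize(e, levels=3, ibreaks=10)
        pd.testing.assert_frame_equal(model.transform(e), disc)

    def test_greedy_merges_match_exhaustive_search_on_tiny_instance(self):
        """On 2 variables x 12 samples with ibreaks=4 (one merge each), the
        greedy cut deletions equal the jointly optimal merge pair found by
        enumerating all merge sequences."""
        rng = np.random.default_rng(42)
        v1 = np.sort(rng.normal(size=12))
        v2 = v1 * 2.0 + rng.normal(scale=0.3, size=12)
        e = pd.DataFrame({"a": v1, "b": v2})
        model, _ = hartemink_discretize(e, levels=3, ibreaks=4)

        def z(x):
            return (x - x.mean()) / x.std(ddof=1)

        za, zb = z(v1), z(v2)
        ba, bb = _initial_bins(za, 4), _initial_bins(zb, 4)
        best = (-math.inf, None)
        for ca in range(3):
            for cb in range(3):
                ma, mb = ba - (ba > ca), bb - (bb > cb)
                mi = _mutual_information(ma, mb, 3, 3)
                if mi > best[0]:
                    best = (mi, (ca, cb))

        def deleted(zv, bins, final_cuts):
            cuts = [(zv[bins == b].max() + zv[bins == b + 1].min()) / 2
                    for b in range(bins.max())]
            return [i for i, c in enumerate(cuts) if c not in final_cuts]

        da = deleted(za, ba, model.cuts["a"])
        db = deleted(zb, bb, model.cuts["b"])
        assert (da[0], db[0]) == best[1]


# ---------------------------------------------------------------------------
# BDe score


def bde_reference(dag, frame, arities, iss=1.0):
    """Independent closed-form transcription of the BDe score (slow loops)."""
    total = 0.0
    for node, parents in dag.items():
        parents = sorted(parents)
        r = arities[node]
        q = int(np.prod([arities[p] for p in parents])) if parents else 1
        a_ijk = iss / (r * q)
        a_ij = iss / q
        configs = list(itertools.product(*[range(arities[p]) for p in parents])) or [()]
        for cfg in configs:
            sel = np.ones(len(frame), dtype=bool)
            for p, val in zip(parents, cfg):
                sel &= frame[p].to_numpy() == val
            nij = int(sel.sum())
            total += gammaln(a_ij) - gammaln(a_ij + nij)
            for k in range(r):
                nijk = int((sel & (frame[node].to_numpy() == k)).sum())
                total += gammaln(a_ijk + nijk) - gammaln(a_ijk)
    return total


def _random_discrete(n, names, arities, seed):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({v: rng.integers(0, arities[v], n) for v in names})
    return frame, DiscreteData(frame, arities)


class TestBdeScore:
    def test_matches_independent_transcription(self):
        names = ["A", "B", "C"]
        arities = {n: 2 for n in names}
        frame, data = _random_discrete(8, names, arities, seed=0)
        dag = {"A": frozenset(), "B": frozenset(["A"]), "C": frozenset(["A", "B"])}
        ref = bde_reference(dag, frame, arities)
        assert bde_score(dag, data) == pytest.approx(ref, abs=1e-10)

    def test_reversed_two_node_arcs_score_equally(self):
        names = ["X", "Y"]
        arities = {"X": 3, "Y": 2}
        _, data = _random_discrete(50, names, arities, seed=1)
        g1 = {"X": frozenset(), "Y": frozenset(["X"])}
        g2 = {"X": frozenset(["Y"]), "Y": frozenset()}
        assert bde_score(g1, data) == pytest.approx(bde_score(g2, data), abs=1e-9)

    def test_empty_graph_decomposes_into_marginal_families(self):
        names = ["A", "B", "C"]
        arities = {n: 3 for n in names}
        frame, data = _random_discrete(30, names, arities, seed=2)
        empty = {n: frozenset() for n in names}
        parts = sum(
            bde_reference({n: frozenset()}, frame, arities) for n in names
        )
        assert bde_score(empty, data) == pytest.approx(parts, abs=1e-10)

    def test_cyclic_graph_rejected(self):
        _, data = _random_discrete(10, ["A", "B"], {"A": 2, "B": 2}, seed=3)
        cyc = {"A": frozenset(["B"]), "B": frozenset(["A"])}
        with pytest.raises(ValueError, match="cycle"):
            bde_score(cyc, data)


class TestMarkovEquivalence:
    def test_equivalent_three_node_dags_score_identically(self):
        names = ["A", "B", "C"]
        arities = {n: 2 for n in names}
        _, data = _random_discrete(60, names, arities, seed=4)
        classes = {}
        for dag in all_dags(names):
            key = skeleton_and_vstructs(dag)
            classes.setdefault(key, []).append(bde_score(dag, data))
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-9


# ---------------------------------------------------------------------------
# structure search


class TestHillClimb:
    def test_full_blacklist_returns_empty_dag(self):
        names = ["A", "B", "C"]
        _, data = _random_discrete(40, names, {n: 2 for n in names}, seed=5)
        bl = {(u, v) for u in names for v in names if u != v}
        res = hill_climb(data, blacklist=bl)
        assert all(len(p) == 0 for p in res.dag.values())

    def test_independent_data_yields_empty_dag(self):
        names = ["A", "B", "C", "D"]
        _, data = _random_discrete(500, names, {n: 3 for n in names}, seed=6)
        res = hill_climb(data)
        assert all(len(p) == 0 for p in res.dag.values())

    def test_chain_attains_exhaustive_optimum(self):
        """The greedy search reaches the global BDe optimum over all 543
        four-node DAGs on chain-generated data."""
        rng = np.random.default_rng(7)
        n = 200
        x1 = rng.integers(0, 2, n)
        x2 = (x1 + (rng.random(n) < 0.15)) % 2
        x3 = (x2 + (rng.random(n) < 0.15)) % 2
        x4 = (x3 + (rng.random(n) < 0.15)) % 2
        frame = pd.DataFrame({"X1": x1, "X2": x2, "X3": x3, "X4": x4})
        data = DiscreteData(frame, {c: 2 for c in frame})
        dags = list(all_dags(["X1", "X2", "X3", "X4"]))
        assert len(dags) == 543
        best = max(bde_score(d, data) for d in dags)
        res = hill_climb(data)
        assert res.score == pytest.approx(best, abs=1e-9)

    def test_output_respects_blacklist_and_acyclicity(self):
        names = ["A", "B", "C", "E"]
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({
            "A": rng.integers(0, 2, 150),
        })
        frame["B"] = (frame["A"] + (rng.random(150) < 0.2)) % 2
        frame["C"] = rng.integers(0, 2, 150)
        frame["E"] = (frame["B"] + (rng.random(150) < 0.2)) % 2
        data = DiscreteData(frame, {n: 2 for n in names})
        bl = {("E", v) for v in names if v != "E"}
        res = hill_climb(data, blacklist=bl)
        assert is_acyclic(res.dag)
        assert all(arc not in bl for arc in dag_arcs(res.dag))


class TestBootstrapAndConsensus:
    def test_bootstrap_is_deterministic_given_seed(self):
        names = ["A", "B", "C"]
        _, data = _random_discrete(60, names, {n: 2 for n in names}, seed=9)
        b1 = bootstrap_structures(data, R=5, seed=11)
        b2 = bootstrap_structures(data, R=5, seed=11)
        assert [(d, s) for d, s in b1] == [(d, s) for d, s in b2]

    def test_planted_arcs_survive_bootstrap(self):
        """Arcs of a strongly-dependent planted 5-node structure appear
        (in some orientation) in at least 80% of bootstrap replicates."""
        rng = np.random.default_rng(10)
        n = 500
        flip = lambda v: (v + (rng.random(n) < 0.12)) % 2
        n0 = rng.integers(0, 2, n)
        frame = pd.DataFrame({"N0": n0, "N1": flip(n0), "N2": flip(n0)})
        frame["N3"] = flip(frame["N1"].to_numpy())
        frame["N4"] = flip(frame["N3"].to_numpy())
        true_arcs = [("N0", "N1"), ("N0", "N2"), ("N1", "N3"), ("N3", "N4")]
        data = DiscreteData(frame, {f"N{i}": 2 for i in range(5)})
        boot = bootstrap_structures(data, R=20, seed=1)
        for u, v in true_arcs:
            hits = sum(
                1 for dag, _ in boot
                if (u, v) in dag_arcs(dag) or (v, u) in dag_arcs(dag)
            )
            assert hits >= 0.8 * len(boot)

    def test_identical_bootstrap_networks_give_that_network(self):
        dag = {"A": frozenset(), "B": frozenset(["A"]), "C": frozenset(["B"])}
        boot = [(dag, -10.0)] * 6
        consensus, table = consensus_network(boot)
        assert consensus == dag
        assert all(s == 1.0 for s in table.strengths.values())

    def test_arc_at_forty_percent_strength_is_dropped(self):
        base = {"A": frozenset(), "B": frozenset(["A"]), "C": frozenset()}
        extra = {"A": frozenset(), "B": frozenset(["A"]), "C": frozenset(["B"])}
        boot = [(extra, -1.0)] * 2 + [(base, -1.0)] * 3
        consensus, table = consensus_network(boot, top_fraction=1.0)
        assert table.n_retained == 5
        assert table.strengths[("B", "C")] == pytest.approx(0.4)
        assert ("B", "C") not in dag_arcs(consensus)
        assert ("A", "B") in dag_arcs(consensus)

    def test_hand_traced_retention_threshold_and_acyclicity(self):
        """Six 3-node structures with hand scores: retention keeps the top
        2; arcs at strength 0.5 enter in decreasing-strength order unless
        they close a cycle."""
        d1 = {"A": frozenset(), "B": frozenset(["A"]), "C": frozenset(["B"])}
        d2 = {"A": frozenset(["C"]), "B": frozenset(["A"]), "C": frozenset()}
        boot = [(d1, -1.0), (d2, -2.0), (d1, -50.0), (d2, -60.0),
                (d1, -70.0), (d2, -80.0)]
        consensus, table = consensus_network(boot, top_fraction=1 / 3)
        # retained: d1 (-1) and d2 (-2); A->B in both (strength 1);
        # B->C and C->A each in one (strength 0.5, kept at threshold 0.5).
        assert table.strengths[("A", "B")] == 1.0
        arcs = dag_arcs(consensus)
        assert ("A", "B") in arcs
        # B->C (lexicographically first among the 0.5 arcs) inserts; C->A
        # would then close the cycle A->B->C->A and must be skipped
        assert ("B", "C") in arcs
        assert ("C", "A") not in arcs
        assert is_acyclic(consensus)

    def test_too_few_networks_rejected(self):
        dag = {"A": frozenset()}
        with pytest.raises(ValueError, match="at least 3"):
            consensus_network([(dag, 0.0)] * 2)

    def test_consensus_structure_recovery_f1(self):
        """Consensus skeleton recovers a known 10-node network from
        n = 1000 samples with F1 >= 0.8 (orientation not compared)."""
        rng = np.random.default_rng(12)
        nodes = [f"N{i}" for i in range(10)]
        truth = random_bn(nodes, {n: 2 for n in nodes}, rng, edge_prob=0.3,
                          conc=0.25)
        frame = sample_from_bn(truth, 1000, rng)
        data = DiscreteData(frame, {n: 2 for n in nodes})
        boot = bootstrap_structures(data, R=50, seed=2)
        consensus, _ = consensus_network(boot)
        skel_true = {frozenset(a) for a in dag_arcs(truth.dag())}
        skel_est = {frozenset(a) for a in dag_arcs(consensus)}
        tp = len(skel_true & skel_est)
        prec = tp / len(skel_est) if skel_est else 0.0
        rec = tp / len(skel_true) if skel_true else 1.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert f1 >= 0.8


# ---------------------------------------------------------------------------
# parameters and inference


class TestFitParameters:
    def test_posterior_mean_hand_arithmetic(self):
        frame = pd.DataFrame({"X": [0, 0, 0, 1]})
        data = DiscreteData(frame, {"X": 2})
        model = fit_parameters({"X": frozenset()}, data, iss=1.0)
        np.testing.assert_allclose(model.cpts["X"][:, 0], [0.7, 0.3])

    def test_vanishing_prior_recovers_maximum_likelihood(self):
        frame = pd.DataFrame({"X": [0, 0, 1, 1, 1]})
        data = DiscreteData(frame, {"X": 2})
        model = fit_parameters({"X": frozenset()}, data, iss=1e-9)
        np.testing.assert_allclose(model.cpts["X"][:, 0], [0.4, 0.6], atol=1e-9)

    def test_unseen_parent_configuration_is_uniform(self):
        frame = pd.DataFrame({"P": [0, 0, 0], "X": [0, 1, 0]})
        data = DiscreteData(frame, {"P": 3, "X": 2})
        model = fit_parameters({"P": frozenset(), "X": frozenset(["P"])}, data)
        np.testing.assert_allclose(model.cpts["X"][:, 2], [0.5, 0.5])

    def test_cpt_columns_sum_to_one_and_are_positive(self):
        rng = np.random.default_rng(13)
        nodes = ["A", "B", "C"]
        truth = random_bn(nodes, {n: 3 for n in nodes}, rng, edge_prob=0.7)
        frame = sample_from_bn(truth, 80, rng)
        data = DiscreteData(frame, {n: 3 for n in nodes})
        model = fit_parameters(truth.dag(), data)
        for cpt in model.cpts.values():
            np.testing.assert_allclose(cpt.sum(axis=0), 1.0, atol=1e-12)
            assert (cpt > 0).all()


class TestEffectInference:
    def _two_parent_model(self):
        cpt = np.array([[0.9, 0.2, 0.5, 0.6, 0.1, 0.3, 0.7, 0.4, 0.8],
                        [0.1, 0.8, 0.5, 0.4, 0.9, 0.7, 0.3, 0.6, 0.2]])
        return BNModel(
            nodes=["Effect", "M1", "M2"],
            parents={"Effect": ("M1", "M2"), "M1": (), "M2": ()},
            arities={"Effect": 2, "M1": 3, "M2": 3},
            cpts={
                "Effect": cpt,
                "M1": np.full((3, 1), 1 / 3),
                "M2": np.full((3, 1), 1 / 3),
            },
        )

    def test_parentless_effect_reads_marginal_cpt(self):
        model = BNModel(
            nodes=["Effect"], parents={"Effect": ()}, arities={"Effect": 2},
            cpts={"Effect": np.array([[0.7], [0.3]])},
        )
        cls, post = model.predict_effect_exact({})
        assert cls == 0
        np.testing.assert_allclose(post, [0.7, 0.3])

    def test_two_parent_cpt_row_is_read_correctly(self):
        model = self._two_parent_model()
        # config index = M1*3 + M2 (M1 lexicographically first)
        cls, post = model.predict_effect_exact({"M1": 1, "M2": 2})
        np.testing.assert_allclose(post, [0.3, 0.7])
        assert cls == 1
        assert post.sum() == pytest.approx(1.0)

    def test_exact_tie_predicts_class_zero(self):
        model = self._two_parent_model()
        cls, _ = model.predict_effect_exact({"M1": 0, "M2": 2})
        assert cls == 0

    def test_missing_parent_is_an_error(self):
        model = self._two_parent_model()
        with pytest.raises(ValueError, match="missing value"):
            model.predict_effect_exact({"M1": 0})

    def test_likelihood_weighting_is_seed_reproducible(self):
        model = self._two_parent_model()
        ev = {"M1": 0, "M2": 1}
        r1 = model.predict_effect_lw(ev, n_particles=1, seed=5)
        r2 = model.predict_effect_lw(ev, n_particles=1, seed=5)
        assert r1[0] == r2[0]
        np.testing.assert_allclose(r1[1], r2[1])

    def test_deterministic_cpt_gives_certain_posterior(self):
        model = self._two_parent_model()
        model.cpts["Effect"][:, 0] = [1.0, 0.0]
        cls, post = model.predict_effect_lw({"M1": 0, "M2": 0},
                                            n_particles=50, seed=0)
        assert cls == 0
        np.testing.assert_allclose(post, [1.0, 0.0])

    def test_lw_agrees_with_exact_lookup(self):
        """Likelihood weighting and the CPT lookup give the same class on
        random models and evidence; posteriors agree within Monte-Carlo
        error."""
        rng = np.random.default_rng(14)
        for _ in range(40):
            k = int(rng.integers(2, 5))
            nodes = [f"M{i}" for i in range(k)] + ["Effect"]
            arities = {n: 3 for n in nodes}
            arities["Effect"] = 2
            model = random_bn(nodes, arities, rng,
                              forbid_children_of={"Effect"})
            ev = {n: int(rng.integers(arities[n]))
                  for n in nodes if n != "Effect"}
            cls_e, post_e = model.predict_effect_exact(ev)
            cls_l, post_l = model.predict_effect_lw(
                ev, n_particles=800, seed=int(rng.integers(2**31))
            )
            assert cls_e == cls_l
            se = math.sqrt(max(post_e[1] * (1 - post_e[1]), 1e-6) / 800)
            assert abs(post_l[1] - post_e[1]) <= max(3 * se, 0.05)
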