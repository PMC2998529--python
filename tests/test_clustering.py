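"""Topological information content, root selection/merging, sub-graphs, meta-graph."""

import math
import warnings

import pytest

from tcss.annotations import AnnotationSet, build_ica_table
from tcss.clustering import (
    DegenerateClusteringWarning,
    assign_memberships,
    build_metagraph,
    build_subgraphs,
    cluster,
    ict,
    ict_table,
    merge_similar_roots,
    select_roots,
)
from tcss.ontology import OntologyDAG, Term

from conftest import WORKED_CUTOFF, random_dag


def chain_dag(pad_root, extras):
    """Root with ``pad_root`` filler leaves plus a chain of nested nodes.

    Chain node i carries ``extras[i]`` leaf children, so descendant-closure
    sizes (and hence ICT values) are controlled exactly.
    """
    terms, edges = {}, []
    counter = [0]

    def add(name, parent=None):
        counter[0] += 1
        tid = f"GO:{counter[0]:07d}"
        terms[tid] = Term(id=tid, name=name, namespace="cellular_component")
        if parent:
            edges.append((tid, parent, "is_a"))
        return tid

    root = add("root")
    for j in range(pad_root):
        add(f"pad{j}", root)
    chain = [root]
    for i, extra in enumerate(extras):
        node = add(f"chain{i}", chain[-1])
        chain.append(node)
        for j in range(extra):
            add(f"leaf{i}.{j}", node)
    return OntologyDAG("cellular_component", terms, edges), chain


class TestICT:
    def test_root_zero_leaf_log_total(self, worked_dag):
        assert ict(worked_dag, worked_dag.root) == pytest.approx(0.0)
        n = len(worked_dag)
        for leaf in worked_dag.leaves():
            assert ict(worked_dag, leaf) == pytest.approx(math.log(n))

    def test_closed_form_with_descendant_closure(self, worked_dag):
        # GO:0000003 has 4 descendants in the 14-term fixture: (4+1)/14
        assert ict(worked_dag, "GO:0000003") == pytest.approx(-math.log(5 / 14))

    def test_table_matches_single_queries_and_is_monotone(self, worked_dag):
        table = ict_table(worked_dag)
        for t in worked_dag.terms:
            assert table[t] == pytest.approx(ict(worked_dag, t))
        for child, parent in worked_dag.graph.edges():
            assert table[child] >= table[parent]

    def test_frozen_worked_values(self, worked_dag, worked_tables):
        table = ict_table(worked_dag)
        for t, v in worked_tables["ict"].items():
            assert table[t] == pytest.approx(v, abs=1e-6)


class TestSelectRoots:
    def test_enumeration_against_ict(self, worked_dag):
        table = ict_table(worked_dag)
        roots = select_roots(worked_dag, WORKED_CUTOFF)
        assert roots == {t for t, v in table.items() if v <= WORKED_CUTOFF}
        assert worked_dag.root in roots

    def test_tiny_cutoff_keeps_only_namespace_root(self, worked_dag):
        assert select_roots(worked_dag, 0.01) == {worked_dag.root}

    def test_select_all_raises_degenerate_warning(self, worked_dag):
        with pytest.warns(DegenerateClusteringWarning):
            roots = select_roots(worked_dag, math.log(len(worked_dag)))
        assert roots == set(worked_dag.terms)

    def test_nonpositive_cutoff_rejected(self, worked_dag):
        with pytest.raises(ValueError):
            select_roots(worked_dag, 0.0)


class TestMergeSimilarRoots:
    def test_descendant_within_twenty_percent_merges(self):
        # chain node ICTs: engineered below cutoff; r2 inside r1's +-20% window
        dag, chain = chain_dag(85, [2, 10])
        table = ict_table(dag)
        r1, r2 = chain[1], chain[2]
        assert 0.8 * table[r1] <= table[r2] <= 1.2 * table[r1]
        merged = merge_similar_roots(dag, {dag.root, r1, r2}, table)
        assert merged == {dag.root, r1}

    def test_outside_window_both_kept(self):
        dag, chain = chain_dag(85, [12, 0])
        table = ict_table(dag)
        r1, r2 = chain[1], chain[2]
        assert table[r2] > 1.2 * table[r1]
        merged = merge_similar_roots(dag, {dag.root, r1, r2}, table)
        assert merged == {dag.root, r1, r2}

    def test_cascade_compares_survivors_in_ascending_order(self):
        # nested roots at ICT ratios ~ (1, 1.15, 1.3): middle merges into top,
        # bottom then compared against top and kept
        dag, chain = chain_dag(83, [3, 1, 7])
        table = ict_table(dag)
        r1, r2, r3 = chain[1], chain[2], chain[3]
        assert table[r2] <= 1.2 * table[r1] < table[r3]
        merged = merge_similar_roots(dag, {dag.root, r1, r2, r3}, table)
        assert merged == {dag.root, r1, r3}

    def test_namespace_root_never_absorbs(self, worked_dag):
        table = ict_table(worked_dag)
        roots = select_roots(worked_dag, WORKED_CUTOFF)
        merged = merge_similar_roots(worked_dag, roots, table)
        assert merged == roots  # worked fixture ICTs are spread beyond 20%


class TestMembership:
    def test_most_specific_root_wins(self, worked_clustering):
        member = worked_clustering.index.membership
        # deep terms fall to their closest selected root, not the namespace root
        for t in ("GO:0000005", "GO:0000007", "GO:0000008", "GO:0000006"):
            assert member[t] == frozenset({"GO:0000003"})
        for t in ("GO:0000009", "GO:0000011", "GO:0000012"):
            assert member[t] == frozenset({"GO:0000004"})
        assert member["GO:0000003"] == frozenset({"GO:0000003"})

    def test_disjunctive_paths_duplicate_term_and_descendants(self):
        # u has independent paths into two incomparable roots r1, r2
        terms, edges = {}, []

        def add(tid, *parents):
            terms[tid] = Term(id=tid, name=tid, namespace="cellular_component")
            edges.extend((tid, p, "is_a") for p in parents)

        add("GO:0000001")
        add("GO:0000002", "GO:0000001")  # root r1
        add("GO:0000003", "GO:0000001")  # root r2
        add("GO:0000004", "GO:0000002")
        add("GO:0000005", "GO:0000003")
        add("GO:0000006", "GO:0000004", "GO:0000005")  # disjunctive term u
        add("GO:0000007", "GO:0000006")  # descendant of u
        dag = OntologyDAG("cellular_component", terms, edges)
        member = assign_memberships(dag, {"GO:0000001", "GO:0000002", "GO:0000003"})
        assert member["GO:0000006"] == frozenset({"GO:0000002", "GO:0000003"})
        assert member["GO:0000007"] == frozenset({"GO:0000002", "GO:0000003"})
        assert member["GO:0000004"] == frozenset({"GO:0000002"})

    def test_two_parents_in_same_subgraph_no_duplication(self, worked_dag):
        member = assign_memberships(worked_dag, {worked_dag.root, "GO:0000003"})
        assert member["GO:0000008"] == frozenset({"GO:0000003"})

    def test_every_term_covered(self, worked_clustering):
        member = worked_clustering.index.membership
        assert set(member) == set(worked_clustering.dag.terms)
        assert all(member[t] for t in member)


class TestSubgraphsAndMeta:
    def test_frozen_ics_tables(self, worked_clustering, worked_tables):
        ics = worked_clustering.index.ics
        expected = {
            tuple(k.split("|")): v for k, v in worked_tables["ics"].items()
        }
        assert set(ics) == set(expected)
        for key, v in expected.items():
            assert ics[key] == pytest.approx(v, abs=1e-6)

    def test_ics_bounds_and_max_one_per_subgraph(self, worked_clustering):
        index = worked_clustering.index
        for (root, _), v in index.ics.items():
            assert 0.0 <= v <= 1.0 + 1e-12
        for root in index.max_ica:
            peak = max(v for (r, _), v in index.ics.items() if r == root)
            assert peak == pytest.approx(1.0) or index.max_ica[root] == 0.0

    def test_zero_annotation_subgraph_warns(self):
        dag, chain = chain_dag(0, [10, 0])
        ann = AnnotationSet("cellular_component", {"g1": {chain[1]}})
        table = build_ica_table(dag, ann)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            build_subgraphs(dag, {dag.root, chain[1], chain[2]}, table)
        assert any("no annotated terms" in str(w.message) for w in caught)

    def test_metagraph_nodes_and_frozen_icm(self, worked_clustering, worked_tables):
        meta = worked_clustering.meta
        assert meta.nodes == frozenset(worked_tables["roots"])
        for t, v in worked_tables["icm"].items():
            assert meta.icm[t] == pytest.approx(v, abs=1e-6)
        assert meta.icm[worked_clustering.ica.root] == 0.0

    def test_single_root_metagraph_is_one_zero_node(self, worked_dag, worked_ann):
        table = build_ica_table(worked_dag, worked_ann)
        meta = build_metagraph(worked_dag, {worked_dag.root}, table)
        assert meta.nodes == frozenset({worked_dag.root})
        assert meta.icm[worked_dag.root] == 0.0

    def test_sibling_roots_make_three_node_metagraph(self):
        dag, chain = chain_dag(0, [3])
        # two leaves under chain[1] plus the chain node itself; pick two siblings
        sibs = sorted(dag.children(chain[1]))[:2]
        ann = AnnotationSet(
            "cellular_component", {"g1": {sibs[0]}, "g2": {sibs[1]}}
        )
        table = build_ica_table(dag, ann)
        meta = build_metagraph(dag, set(sibs), table)
        assert meta.nodes == frozenset({dag.root, chain[1], *sibs})
        # reduced edges follow original reachability
        assert set(meta.graph.edges()) == {
            (sibs[0], chain[1]),
            (sibs[1], chain[1]),
            (chain[1], dag.root),
        }

    def test_meta_edges_match_reachability_oracle(self, worked_clustering):
        meta = worked_clustering.meta
        dag = worked_clustering.dag
        for u in meta.nodes:
            for v in meta.nodes:
                if u == v:
                    continue
                import networkx as nx

                assert nx.has_path(meta.graph, u, v) == (v in dag.ancestors(u))

    def test_cutoff_stable_within_point_one(self, worked_dag, worked_ann):
        # the fixture's ICT spectrum leaves a gap around 1.25
        reference = cluster(worked_dag, worked_ann, 1.25).index.roots
        for cutoff in (1.15, 1.2, 1.3, 1.35):
            assert cluster(worked_dag, worked_ann, cutoff).index.roots == reference


class TestRandomFixtures:
    @pytest.mark.parametrize("seed", range(3))
    def test_invariants_on_random_corpora(self, seed):
        import numpy as np

        dag = random_dag(seed, 30)
        rng = np.random.default_rng(seed + 7)
        ids = sorted(dag.terms)
        ann = AnnotationSet(
            "cellular_component",
            {f"g{i}": {ids[int(rng.integers(1, len(ids)))]} for i in range(25)},
        )
        clustering = cluster(dag, ann, 1.5)
        index, meta = clustering.index, clustering.meta
        for v in index.ics.values():
            assert 0.0 <= v <= 1.0 + 1e-12
        for v in meta.icm.values():
            assert 0.0 <= v <= 1.0 + 1e-12
        # every annotated term is in a sub-graph or a meta node
        annotated = set().union(*ann.gene_terms.values())
        for t in annotated:
            assert index.membership.get(t) or t in meta.nodes
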