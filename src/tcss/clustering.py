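"""Topology-based clustering of a GO namespace into sub-graphs and a meta-graph.

The topological information content of a term,

    ICT(t) = -ln( |descendants(t) ∪ {t}| / |O| ),

is low for general terms (near the root) and reaches ln|O| at leaves.  Terms
at or below a chosen ICT cutoff become sub-graph roots; nested roots with
ICT within ±20% of an ancestor root are merged into it.  After transitive
reduction, every term is assigned to the sub-graph(s) of its most specific
root ancestor(s) — a term reachable from several incomparable roots is
duplicated into each (multi-parent terms carry their descendants with them).
Sub-graph roots and their ancestors form the meta-graph.

Annotation information content is renormalized to [0,1] at both levels:
ICS(t) within a sub-graph divides ICA(t) by the sub-graph's max ICA, and
ICM(t) over the meta-graph divides by the max ICA among meta nodes.  A pair
of terms sharing a sub-graph is later scored with ICS, an unshared pair with
ICM, which is what compensates for unequal branch depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .annotations import AnnotationSet, ICATable, build_ica_table
from .ontology import OntologyDAG

#: relative half-width of the root-merging window ("within ±20%")
MERGE_WINDOW = 0.2


class DegenerateClusteringWarning(UserWarning):
    """Emitted when a cutoff selects every term as a sub-graph root."""


def ict(dag: OntologyDAG, term_id: str) -> float:
    """Topological information content of one term."""
    dag._check(term_id)
    n = len(dag.descendants(term_id)) + 1
    # log(total) - log(closure): exact 0 at the root, exact ln|O| at leaves
    return math.log(len(dag)) - math.log(n)


def ict_table(dag: OntologyDAG) -> dict[str, float]:
    """ICT for every term, computed via one reverse-topological sweep."""
    total = len(dag)
    closure_size: dict[str, int] = {}
    sets: dict[str, frozenset[str]] = {}
    for t in nx.topological_sort(dag.graph):  # children before parents
        acc = {t}
        for child in dag.graph.predecessors(t):
            acc |= sets[child]
        sets[t] = frozenset(acc)
        closure_size[t] = len(acc)
    log_total = math.log(total)
    return {t: log_total - math.log(closure_size[t]) for t in dag.terms}


def select_roots(
    dag: OntologyDAG,
    cutoff: float,
    ict_values: Mapping[str, float] | None = None,
) -> set[str]:
    """Terms with ICT at or below the topology cutoff become sub-graph roots.

    The namespace root (ICT = 0) is always selected.  If the cutoff captures
    every term the clustering is degenerate (each term its own sub-graph) and
    a warning is emitted.
    """
    if cutoff <= 0:
        raise ValueError(f"topology cutoff must be positive, got {cutoff}")
    if ict_values is None:
        ict_values = ict_table(dag)
    roots = {t for t, v in ict_values.items() if v <= cutoff}
    if len(roots) == len(dag):
        warnings.warn(
            f"cutoff {cutoff} selects all {len(dag)} terms as sub-graph roots",
            DegenerateClusteringWarning,
        )
    return roots


def merge_similar_roots(
    dag: OntologyDAG,
    roots: Iterable[str],
    ict_values: Mapping[str, float],
    window: float = MERGE_WINDOW,
) -> set[str]:
    """Merge nested sub-graph roots with similar ICT.

    Processing kept roots in ascending ICT order (ties by term id), any
    remaining root that descends from the current root and whose ICT lies
    within ±``window`` of it is removed — its would-be sub-graph folds into
    the ancestor's.  Only ancestor/descendant pairs merge; unrelated roots
    would otherwise produce disconnected sub-graphs.
    """
    kept = set(roots)
    for r in sorted(kept, key=lambda t: (ict_values[t], t)):
        if r not in kept:
            continue
        lo, hi = (1 - window) * ict_values[r], (1 + window) * ict_values[r]
        for other in dag.descendants(r) & kept:
            if lo <= ict_values[other] <= hi:
                kept.discard(other)
    return kept


@dataclass(frozen=True)
class SubgraphIndex:
    """Result of topological clustering at one cutoff.

    ``membership`` maps every term to the root(s) of the sub-graph(s) it
    belongs to (possibly several, via term duplication); ``terms`` gives the
    inverse view; ``ics`` holds the within-sub-graph normalized IC for each
    (root, annotated term) pair.
    """

    cutoff: float
    roots: frozenset[str]
    membership: Mapping[str, frozenset[str]]
    terms: Mapping[str, frozenset[str]]  # root -> all member terms
    max_ica: Mapping[str, float]  # root -> max ICA among members
    ics: Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class MetaGraph:
    """Upper-level graph over sub-graph roots and their ancestors."""

    nodes: frozenset[str]
    graph: nx.DiGraph  # reduced, child -> parent
    max_ica: float
    icm: Mapping[str, float]  # only nodes with annotations


def assign_memberships(
    dag: OntologyDAG, roots: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Map each term to its most specific root ancestor(s).

    Candidates are the selected roots among a term's ancestors-or-self; of
    these, the poset-minimal ones (no other candidate descends from them)
    are kept.  Comparable candidates collapse to the deepest; incomparable
    candidates all survive, duplicating the term into several sub-graphs.
    """
    roots = set(roots)
    anc_cache: dict[str, set[str]] = {r: dag.ancestors(r) for r in roots}
    desc_cache: dict[str, set[str]] = {r: dag.descendants(r) for r in roots}
    membership: dict[str, frozenset[str]] = {}
    for t in dag.terms:
        candidates = {r for r in roots if r == t or t in desc_cache[r]}
        minimal = {
            r
            for r in candidates
            if not any(o != r and r in anc_cache[o] for o in candidates)
        }
        membership[t] = frozenset(minimal)
    return membership


def build_subgraphs(
    dag: OntologyDAG, roots: Iterable[str], ica_table: ICATable
) -> SubgraphIndex:
    """Assign terms to sub-graphs and compute ICS tables.

    ``dag`` should already be transitively reduced.  Sub-graphs with no
    annotated term cannot contribute to scoring and are flagged.
    """
    roots = sorted(set(roots))
    membership = assign_memberships(dag, roots)
    terms: dict[str, set[str]] = {r: set() for r in roots}
    for t, rs in membership.items():
        for r in rs:
            terms[r].add(t)
    max_ica: dict[str, float] = {}
    ics: dict[tuple[str, str], float] = {}
    for r in roots:
        annotated = [t for t in terms[r] if t in ica_table]
        if not annotated:
            warnings.warn(f"sub-graph rooted at {r} has no annotated terms")
            continue
        peak = max(ica_table[t] for t in annotated)
        max_ica[r] = peak
        for t in annotated:
            ics[(r, t)] = ica_table[t] / peak if peak > 0 else 0.0
    return SubgraphIndex(
        cutoff=math.nan,
        roots=frozenset(roots),
        membership=membership,
        terms={r: frozenset(ts) for r, ts in terms.items()},
        max_ica=max_ica,
        ics=ics,
    )


def build_metagraph(
    dag: OntologyDAG, roots: Iterable[str], ica_table: ICATable
) -> MetaGraph:
    """Meta-graph over sub-graph roots and their ancestors with ICM values."""
    roots = set(roots)
    nodes = set(roots)
    for r in roots:
        nodes |= dag.ancestors(r)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in dag.ancestors(u) & nodes:
            g.add_edge(u, v)
    g = nx.transitive_reduction(g)
    annotated = [t for t in nodes if t in ica_table]
    peak = max((ica_table[t] for t in annotated), default=0.0)
    icm = {
        t: (ica_table[t] / peak if peak > 0 else 0.0) for t in annotated
    }
    return MetaGraph(nodes=frozenset(nodes), graph=g, max_ica=peak, icm=icm)


@dataclass(frozen=True)
class Clustering:
    """Everything the two-level scorer needs, built at one topology cutoff."""

    dag: OntologyDAG  # transitively reduced
    ica: ICATable
    ict: Mapping[str, float]
    cutoff: float
    index: SubgraphIndex
    meta: MetaGraph


def cluster(
    dag: OntologyDAG,
    ann: AnnotationSet,
    cutoff: float,
    *,
    merge_window: float = MERGE_WINDOW,
    ica_table: ICATable | None = None,
) -> Clustering:
    """Run the full clustering chain at one topology cutoff.

    Order of operations: transitive reduction, root selection, ±window root
    merging, membership assignment (with duplication), ICS/ICM computation.
    Closure-based quantities (ICT, ICA, ancestor queries) are invariant under
    the reduction, which only affects the explicit edge sets.
    """
    reduced = dag.transitive_reduction()
    ict_values = ict_table(reduced)
    roots = merge_similar_roots(
        reduced, select_roots(reduced, cutoff, ict_values), ict_values, merge_window
    )
    if ica_table is None:
        ica_table = build_ica_table(reduced, ann)
    index = build_subgraphs(reduced, roots, ica_table)
    index = SubgraphIndex(
        cutoff=cutoff,
        roots=index.roots,
        membership=index.membership,
        terms=index.terms,
        max_ica=index.max_ica,
        ics=index.ics,
    )
    meta = build_metagraph(reduced, roots, ica_table)
    return Clustering(
        dag=reduced, ica=ica_table, ict=ict_values, cutoff=cutoff,
        index=index, meta=meta,
    )
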