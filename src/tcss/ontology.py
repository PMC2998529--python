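"""Gene Ontology DAG loading and graph operations.

The ontology is held as a :class:`networkx.DiGraph` with edges oriented
child -> parent, matching the direction of ``is_a`` statements in OBO files.
Following stored edges therefore walks *up* the hierarchy, so ``ancestors``
is reachability along stored edges and ``descendants`` is the mirror query.

Each of the three GO namespaces (cellular_component, biological_process,
molecular_function) is loaded separately; cross-namespace edges are dropped
and every relationship type present in the file (``is_a``, ``part_of``,
``regulates``, ...) is kept and treated equally unless explicitly restricted.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet

NAMESPACES = frozenset(
    {"cellular_component", "biological_process", "molecular_function"}
)

#: short aliases accepted wherever a namespace is requested
NAMESPACE_ALIASES: Mapping[str, str] = {
    "CC": "cellular_component",
    "BP": "biological_process",
    "MF": "molecular_function",
    "C": "cellular_component",
    "P": "biological_process",
    "F": "molecular_function",
}

#: GAF aspect letter for each namespace
ASPECT_OF_NAMESPACE: Mapping[str, str] = {
    "cellular_component": "C",
    "biological_process": "P",
    "molecular_function": "F",
}


class OboParseError(ValueError):
    """Raised for a structurally malformed OBO stanza (reports the line)."""


class OntologyError(ValueError):
    """Raised when the loaded graph violates DAG/root requirements."""


class UnknownTermError(KeyError):
    """Raised when a term id is not present in the ontology."""


def resolve_namespace(namespace: str) -> str:
    ns = NAMESPACE_ALIASES.get(namespace.upper(), namespace)
    if ns not in NAMESPACES:
        raise ValueError(
            f"unknown namespace {namespace!r}; expected one of "
            f"{sorted(NAMESPACES)} or aliases CC/BP/MF"
        )
    return ns


@dataclass(frozen=True)
class Term:
    """One GO term: accession, label, namespace and typed parent links."""

    id: str
    name: str
    namespace: str
    obsolete: bool = False
    parent_links: tuple[tuple[str, str], ...] = ()


class OntologyDAG:
    """Terms and typed child->parent edges of one GO namespace.

    Invariants enforced at construction: the graph is acyclic, exactly one
    term has no parents (the namespace root), and consequently every term
    reaches the root by following parent links.
    """

    def __init__(
        self,
        namespace: str,
        terms: Mapping[str, Term],
        edges: Iterable[tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.namespace = resolve_namespace(namespace)
        self.terms: dict[str, Term] = dict(terms)
        self.edges: frozenset[tuple[str, str, str]] = frozenset(edges)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, rel in self.edges:
            for t in (child, parent):
                if t not in self.terms:
                    raise OntologyError(f"edge endpoint {t!r} is not a loaded term")
            if g.has_edge(child, parent):
                g[child][parent]["relations"].add(rel)
            else:
                g.add_edge(child, parent, relations={rel})
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        roots = sorted(t for t in g if g.out_degree(t) == 0)
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one parentless term for namespace "
                f"{self.namespace}, found {roots}"
            )
        self.root: str = roots[0]
        self.graph: nx.DiGraph = g

    # -- basic queries ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an alt_id alias to its canonical id (identity for canon ids)."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(term_id)

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable by repeatedly following parent links (t excluded)."""
        self._check(term_id)
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """Mirror query of :meth:`ancestors`."""
        self._check(term_id)
        return nx.ancestors(self.graph, term_id)

    def parents(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self.graph.predecessors(term_id))

    def leaves(self) -> set[str]:
        return {t for t in self.graph if self.graph.in_degree(t) == 0}

    # -- transformations -------------------------------------------------

    def transitive_reduction(self) -> "OntologyDAG":
        """Unique minimal DAG with the same transitive closure.

        Edges removed by the reduction are redundant (another child->parent
        path exists); surviving edges keep their relationship types.
        """
        reduced = nx.transitive_reduction(self.graph)
        kept = []
        for child, parent in reduced.edges():
            for rel in self.graph[child][parent]["relations"]:
                kept.append((child, parent, rel))
        return OntologyDAG(self.namespace, self.terms, kept, self.alt_ids)

    def to_obo_text(self) -> str:
        """Serialize back to minimal OBO 1.2 (round-trips through parse_obo)."""
        out = ["format-version: 1.2", ""]
        for tid in sorted(self.terms):
            term = self.terms[tid]
            out.append("[Term]")
            out.append(f"id: {term.id}")
            out.append(f"name: {term.name}")
            out.append(f"namespace: {term.namespace}")
            for alias, canon in sorted(self.alt_ids.items()):
                if canon == tid:
                    out.append(f"alt_id: {alias}")
            for child, parent, rel in sorted(self.edges):
                if child != tid:
                    continue
                if rel == "is_a":
                    out.append(f"is_a: {parent}")
                else:
                    out.append(f"relationship: {rel} {parent}")
            out.append("")
        return "\n".join(out) + "\n"


def _prevalidate_obo(text: str) -> None:
    """Cheap structural check so malformed stanza lines are reported by number."""
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            in_stanza = True
            continue
        if line.startswith("["):
            raise OboParseError(f"line {lineno}: unterminated stanza header {raw!r}")
        if in_stanza and ":" not in line:
            raise OboParseError(
                f"line {lineno}: malformed tag-value line {raw!r} (missing ':')"
            )


def parse_obo(
    source,
    namespace: str,
    *,
    relationship_types: Iterable[str] | None = None,
) -> OntologyDAG:
    """Parse OBO 1.2 text into the DAG of one namespace.

    Parameters
    ----------
    source
        Path, file-like object, or the OBO text itself (recognised by an
        embedded newline).
    namespace
        One of the three GO namespaces, or a CC/BP/MF alias.
    relationship_types
        Restrict loaded edges to these relationship types.  Default keeps
        every type present in the file, each weighted equally.

    Obsolete terms are excluded, terms of other namespaces (and any edge
    touching them) are dropped, and ``alt_id`` values are recorded as aliases
    resolving to their canonical id.
    """
    ns = resolve_namespace(namespace)
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    _prevalidate_obo(text)
    try:
        multigraph = obonet.read_obo(io.StringIO(text))
    except Exception as exc:  # pragma: no cover - obonet's own diagnostics
        raise OboParseError(f"OBO parse failed: {exc}") from exc

    dangling = sorted(
        node for node, data in multigraph.nodes(data=True) if "name" not in data
    )
    if dangling:
        raise OntologyError(
            f"terms reference undefined parents: {', '.join(dangling)}"
        )

    keep_rel = set(relationship_types) if relationship_types is not None else None
    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    in_ns = {
        node
        for node, data in multigraph.nodes(data=True)
        if data.get("namespace") == ns
    }
    edges: list[tuple[str, str, str]] = []
    for child, parent, rel in multigraph.edges(keys=True):
        if child in in_ns and parent in in_ns:
            if keep_rel is None or rel in keep_rel:
                edges.append((child, parent, rel))
    for node in in_ns:
        data = multigraph.nodes[node]
        links = tuple(sorted((p, r) for c, p, r in edges if c == node))
        terms[node] = Term(
            id=node, name=data.get("name", node), namespace=ns, parent_links=links
        )
        for alias in data.get("alt_id", []):
            alt_ids[alias] = node
    if not terms:
        raise OntologyError(f"no terms of namespace {ns} in input")
    return OntologyDAG(ns, terms, edges, alt_ids)
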