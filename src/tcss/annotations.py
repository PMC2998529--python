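"""GAF parsing, evidence filtering, most-specific reduction and annotation IC.

The annotation information content of a term t is

    ICA(t) = -ln( annot(t) / annot(root) )

where annot(t) is the number of *distinct* gene products annotated to t or to
any of its descendants (union semantics, no double counting) and annot(root)
is the corpus size, so that annot(t)/annot(root) is a probability and
ICA(root) = 0 exactly.  Natural log is used throughout.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

from .ontology import ASPECT_OF_NAMESPACE, OntologyDAG, UnknownTermError

#: evidence codes excluded in the manually-curated ("IEA-") configuration
IEA_CODES = frozenset({"IEA"})


class UnannotatedTermError(ValueError):
    """Raised when IC is requested for a term with zero annotated genes."""


@dataclass
class GafLoadReport:
    """Row-level accounting of a GAF load."""

    rows_total: int = 0
    rows_kept: int = 0
    skipped_columns: int = 0
    skipped_unknown_term: int = 0
    skipped_evidence: int = 0
    skipped_not_qualifier: int = 0
    skipped_other_aspect: int = 0
    skipped_obsolete: int = 0


@dataclass
class AnnotationSet:
    """gene -> set of GO terms of one namespace, after filtering.

    ``gene_terms`` values are non-empty sets whose ids all exist in the
    companion :class:`~tcss.ontology.OntologyDAG`.
    """

    namespace: str
    gene_terms: dict[str, set[str]]
    symbols: dict[str, str] = field(default_factory=dict)
    excluded_evidence: frozenset[str] = frozenset()
    report: GafLoadReport = field(default_factory=GafLoadReport)

    @property
    def corpus_size(self) -> int:
        return len(self.gene_terms)

    def genes(self) -> list[str]:
        return sorted(self.gene_terms)

    def usable_terms(self, gene: str, root: str) -> set[str]:
        """Terms usable for pair scoring: annotations other than the root."""
        return {t for t in self.gene_terms.get(gene, set()) if t != root}


def parse_gaf(
    source,
    dag: OntologyDAG,
    excluded_evidence: Iterable[str] = (),
) -> AnnotationSet:
    """Parse GAF 2.x rows for ``dag``'s namespace.

    Keeps rows whose aspect (column 9) matches the namespace, drops rows with
    an excluded evidence code (column 7) or a NOT qualifier (column 4),
    resolves alt_ids, and keys genes by DB object id (column 2) with the
    symbol (column 3) kept as metadata.  Malformed or unknown-term rows are
    skipped with a warning and counted in the load report.
    """
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    excluded = frozenset(excluded_evidence)
    aspect = ASPECT_OF_NAMESPACE[dag.namespace]
    report = GafLoadReport()
    gene_terms: dict[str, set[str]] = {}
    symbols: dict[str, str] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        report.rows_total += 1
        cols = line.split("\t")
        if len(cols) < 15:
            warnings.warn(
                f"GAF line {lineno}: expected >= 15 columns, got {len(cols)}; skipped"
            )
            report.skipped_columns += 1
            continue
        gene_id, symbol, qualifier, go_id, evidence, row_aspect = (
            cols[1],
            cols[2],
            cols[3],
            cols[4],
            cols[6],
            cols[8],
        )
        if row_aspect != aspect:
            report.skipped_other_aspect += 1
            continue
        if "NOT" in qualifier.split("|"):
            report.skipped_not_qualifier += 1
            continue
        if evidence in excluded:
            report.skipped_evidence += 1
            continue
        try:
            canonical = dag.resolve(go_id)
        except UnknownTermError:
            warnings.warn(f"GAF line {lineno}: unknown GO id {go_id}; skipped")
            report.skipped_unknown_term += 1
            continue
        gene_terms.setdefault(gene_id, set()).add(canonical)
        symbols.setdefault(gene_id, symbol)
        report.rows_kept += 1

    return AnnotationSet(
        namespace=dag.namespace,
        gene_terms=gene_terms,
        symbols=symbols,
        excluded_evidence=excluded,
        report=report,
    )


def reduce_to_most_specific(ann: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Keep only each gene's most specific terms.

    Any term that is an ancestor of another term annotated to the same gene
    is removed, leaving a per-gene antichain.  A gene's deepest terms always
    survive, so no gene ends up with an empty set.
    """
    reduced: dict[str, set[str]] = {}
    for gene, terms in ann.gene_terms.items():
        ancestors_of_some = set()
        for t in terms:
            ancestors_of_some |= dag.ancestors(t)
        reduced[gene] = {t for t in terms if t not in ancestors_of_some}
    return replace(ann, gene_terms=reduced)


def _gene_sets_below(dag: OntologyDAG, ann: AnnotationSet) -> dict[str, frozenset[str]]:
    """For every term, the distinct genes annotated at or below it.

    Accumulated once in topological order (children before parents in the
    child->parent orientation), so shared descendants are not double counted.
    """
    direct: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in ann.gene_terms.items():
        for t in terms:
            direct[t].add(gene)
    below: dict[str, frozenset[str]] = {}
    for t in nx.topological_sort(dag.graph):
        acc = set(direct[t])
        for child in dag.graph.predecessors(t):
            acc |= below[child]
        below[t] = frozenset(acc)
    return below


@dataclass(frozen=True)
class ICATable:
    """Annotation counts and ICA values (nats) for every annotated term."""

    counts: Mapping[str, int]
    values: Mapping[str, float]  # term -> ICA, only terms with count > 0
    corpus_size: int
    root: str

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.values

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.values[term_id]
        except KeyError:
            raise UnannotatedTermError(
                f"term {term_id} has no annotated genes; exclude it from scoring"
            ) from None

    @property
    def max_value(self) -> float:
        return max(self.values.values(), default=0.0)

    def probability(self, term_id: str) -> float:
        """p(t) = annot(t) / annot(root)."""
        count = self.counts.get(term_id, 0)
        if count == 0:
            raise UnannotatedTermError(term_id)
        return count / self.corpus_size


def annotation_count(dag: OntologyDAG, ann: AnnotationSet, term_id: str) -> int:
    """Distinct genes annotated to ``term_id`` or any of its descendants."""
    dag._check(term_id)
    genes: set[str] = set()
    closure = dag.descendants(term_id) | {term_id}
    for gene, terms in ann.gene_terms.items():
        if terms & closure:
            genes.add(gene)
    return len(genes)


def build_ica_table(dag: OntologyDAG, ann: AnnotationSet) -> ICATable:
    """Compute annot counts and ICA for the whole ontology in one pass."""
    import math

    below = _gene_sets_below(dag, ann)
    counts = {t: len(genes) for t, genes in below.items()}
    corpus = ann.corpus_size
    values: dict[str, float] = {}
    for t, c in counts.items():
        if c > 0 and corpus > 0:
            values[t] = 0.0 if t == dag.root else -math.log(c / corpus)
    return ICATable(counts=counts, values=values, corpus_size=corpus, root=dag.root)


def ica(dag: OntologyDAG, ann: AnnotationSet, term_id: str) -> float:
    """ICA of a single term; raises :class:`UnannotatedTermError` if annot=0."""
    import math

    dag._check(term_id)
    if term_id == dag.root:
        return 0.0
    count = annotation_count(dag, ann, term_id)
    if count == 0:
        raise UnannotatedTermError(term_id)
    return -math.log(count / ann.corpus_size)
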