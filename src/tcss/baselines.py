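"""Classical IC-based semantic similarity baselines on the same ICA corpus.

All measures share the notion of the lowest common ancestor (LCA): the
common ancestor-or-self with maximal annotation information content.
Resnik scores are divided by the ontology-wide maximum ICA so that every
measure lives on [0, 1]:

    resnik(s,t)    = ICA(LCA) / max ICA
    lin(s,t)       = 2 ICA(LCA) / (ICA(s) + ICA(t))
    jiang(s,t)     = 1 / (1 + ICA(s) + ICA(t) - 2 ICA(LCA))
    schlicker(s,t) = lin(s,t) * (1 - p(LCA))          (simRel)
    simGIC(A,B)    = sum ICA over shared ancestor closure
                     / sum ICA over union of ancestor closures

Lin's ratio is normalization-invariant so raw ICA is used there; Jiang's
distance is mapped to a similarity with 1/(1+d) (bounded, monotone, 1 at
d = 0).  simGIC compares whole annotation sets at once, so the MAX/AVG/BMA
combination rules do not apply to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

from .annotations import AnnotationSet, ICATable, build_ica_table
from .ontology import OntologyDAG

GeneMode = Literal["max", "avg", "bma"]


@dataclass
class ICContext:
    """Ontology + ICA corpus shared by all baseline measures."""

    dag: OntologyDAG
    ica: ICATable
    _aos: dict[str, set[str]] = field(default_factory=dict, repr=False)

    @property
    def max_ica(self) -> float:
        return self.ica.max_value

    def ancestors_or_self(self, term: str) -> set[str]:
        got = self._aos.get(term)
        if got is None:
            got = self.dag.ancestors(term) | {term}
            self._aos[term] = got
        return got

    def lca(self, s: str, t: str) -> str:
        """Annotated common ancestor-or-self with maximal ICA (ties by id)."""
        common = [
            c
            for c in self.ancestors_or_self(s) & self.ancestors_or_self(t)
            if c in self.ica
        ]
        best = max(self.ica[c] for c in common)
        return min(c for c in common if self.ica[c] == best)


def build_context(dag: OntologyDAG, ann: AnnotationSet) -> ICContext:
    return ICContext(dag=dag, ica=build_ica_table(dag, ann))


# -- term-level measures -------------------------------------------------


def resnik_term(ctx: ICContext, s: str, t: str) -> float:
    """ICA of the LCA, normalized by the ontology-wide maximum ICA."""
    peak = ctx.max_ica
    if peak == 0:
        return 0.0
    return ctx.ica[ctx.lca(s, t)] / peak


def lin_term(ctx: ICContext, s: str, t: str) -> float:
    denom = ctx.ica[s] + ctx.ica[t]
    if denom == 0:  # both terms are the root
        return 0.0
    return 2 * ctx.ica[ctx.lca(s, t)] / denom


def jiang_term(ctx: ICContext, s: str, t: str) -> float:
    distance = ctx.ica[s] + ctx.ica[t] - 2 * ctx.ica[ctx.lca(s, t)]
    return 1.0 / (1.0 + distance)


def schlicker_term(ctx: ICContext, s: str, t: str) -> float:
    a = ctx.lca(s, t)
    denom = ctx.ica[s] + ctx.ica[t]
    if denom == 0:
        return 0.0
    return (2 * ctx.ica[a] / denom) * (1.0 - ctx.ica.probability(a))


# -- gene-level combination ----------------------------------------------


def _usable(ctx: ICContext, ann: AnnotationSet, gene: str) -> list[str]:
    return sorted(ann.usable_terms(gene, ctx.dag.root))


def combine_gene_score(
    ctx: ICContext,
    ann: AnnotationSet,
    gene_a: str,
    gene_b: str,
    term_fn: Callable[[ICContext, str, str], float],
    mode: GeneMode = "max",
) -> float | None:
    """Apply MAX / all-pairs AVG / best-match average over S x T.

    Returns None (unscorable) when either gene lacks a non-root annotation.
    """
    S, T = _usable(ctx, ann, gene_a), _usable(ctx, ann, gene_b)
    if not S or not T:
        return None
    grid = [[term_fn(ctx, s, t) for t in T] for s in S]
    if mode == "max":
        return max(max(row) for row in grid)
    if mode == "avg":
        return sum(sum(row) for row in grid) / (len(S) * len(T))
    if mode == "bma":
        best_s = [max(row) for row in grid]
        best_t = [max(grid[i][j] for i in range(len(S))) for j in range(len(T))]
        return (sum(best_s) + sum(best_t)) / (len(S) + len(T))
    raise ValueError(f"unknown combination mode {mode!r}")


def resnik_gene(ctx, ann, gene_a, gene_b, mode: GeneMode = "max"):
    return combine_gene_score(ctx, ann, gene_a, gene_b, resnik_term, mode)


def lin_gene(ctx, ann, gene_a, gene_b, mode: GeneMode = "max"):
    return combine_gene_score(ctx, ann, gene_a, gene_b, lin_term, mode)


def jiang_gene(ctx, ann, gene_a, gene_b, mode: GeneMode = "max"):
    return combine_gene_score(ctx, ann, gene_a, gene_b, jiang_term, mode)


def schlicker_gene(ctx, ann, gene_a, gene_b, mode: GeneMode = "max"):
    return combine_gene_score(ctx, ann, gene_a, gene_b, schlicker_term, mode)


def simgic_gene(ctx: ICContext, ann: AnnotationSet, gene_a: str, gene_b: str) -> float | None:
    """IC-weighted Jaccard over the genes' ancestor-closed annotation sets."""
    S, T = _usable(ctx, ann, gene_a), _usable(ctx, ann, gene_b)
    if not S or not T:
        return None
    closure_a: set[str] = set()
    for s in S:
        closure_a |= ctx.ancestors_or_self(s)
    closure_b: set[str] = set()
    for t in T:
        closure_b |= ctx.ancestors_or_self(t)
    union_mass = sum(ctx.ica[t] for t in closure_a | closure_b if t in ctx.ica)
    if union_mass == 0:
        return 0.0
    shared_mass = sum(ctx.ica[t] for t in closure_a & closure_b if t in ctx.ica)
    return shared_mass / union_mass
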