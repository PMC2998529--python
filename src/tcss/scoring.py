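"""Two-level TCSS similarity between term pairs and gene pairs.

A term pair sharing at least one sub-graph is scored with the sub-graph
information content (ICS) of its lowest common ancestor inside that
sub-graph; otherwise with the meta-graph information content (ICM) of its
lowest common ancestor among meta nodes.  "Lowest" common ancestor here
means the common ancestor with maximal ICA (ties broken by term id).

Gene pairs combine term-pair scores over the two genes' annotation sets with
either the maximum (MAX) or the best-match average (BMA) rule.  Genes whose
only annotation is the namespace root are unscorable and are reported with
an explicit sentinel rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .annotations import AnnotationSet
from .clustering import Clustering

Mode = Literal["max", "bma"]

#: level tag for meta-graph scored pairs
META_LEVEL = "meta"


class TermOutsideClusteringError(KeyError):
    """Raised when a term is assigned to no sub-graph and is not a meta node."""


@dataclass(frozen=True)
class SimilarityResult:
    """Score for one gene pair, or an explicit unscorable sentinel."""

    gene_a: str
    gene_b: str
    score: float | None
    mode: Mode
    level: str | None = None  # sub-graph root id or "meta" (MAX mode only)
    terms: tuple[str, str] | None = None  # contributing term pair (MAX mode)
    reason: str | None = None  # populated when score is None

    @property
    def unscorable(self) -> bool:
        return self.score is None


def _ancestors_or_self(clustering: Clustering, term: str) -> set[str]:
    cache = getattr(clustering, "_aos_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(clustering, "_aos_cache", cache)
    got = cache.get(term)
    if got is None:
        got = clustering.dag.ancestors(term) | {term}
        cache[term] = got
    return got


def lca(
    clustering: Clustering,
    s: str,
    t: str,
    within: Iterable[str] | None = None,
) -> str:
    """Common ancestor-or-self of ``s`` and ``t`` with maximal ICA.

    ``within`` restricts the candidate set (a sub-graph's term set or the
    meta node set); only annotated candidates qualify.  Ties break toward
    the lexicographically smallest term id.
    """
    common = _ancestors_or_self(clustering, s) & _ancestors_or_self(clustering, t)
    if within is not None:
        common &= set(within)
    candidates = [c for c in common if c in clustering.ica]
    if not candidates:
        raise TermOutsideClusteringError(
            f"no annotated common ancestor of {s} and {t} in the given view"
        )
    best = max(clustering.ica[c] for c in candidates)
    return min(c for c in candidates if clustering.ica[c] == best)


def term_pair_score(clustering: Clustering, s: str, t: str) -> tuple[float, str, str]:
    """Score one annotated term pair.

    Returns ``(score, level, lca_term)`` where level is the sub-graph root id
    when the pair shares a sub-graph (the best-scoring one if duplication
    puts it in several) and :data:`META_LEVEL` otherwise.
    """
    index = clustering.index
    for u in (s, t):
        if u not in index.membership and u not in clustering.meta.nodes:
            raise TermOutsideClusteringError(u)
    shared = index.membership.get(s, frozenset()) & index.membership.get(
        t, frozenset()
    )
    shared = {r for r in shared if r in index.max_ica}  # drop unannotated sub-graphs
    if shared:
        best: tuple[float, str, str] | None = None
        for r in sorted(shared):
            a = lca(clustering, s, t, within=index.terms[r])
            score = index.ics[(r, a)]
            if best is None or score > best[0]:
                best = (score, r, a)
        return best
    a = lca(clustering, s, t, within=clustering.meta.icm)
    return clustering.meta.icm[a], META_LEVEL, a


def gene_pair_similarity(
    clustering: Clustering,
    ann: AnnotationSet,
    gene_a: str,
    gene_b: str,
    mode: Mode = "max",
) -> SimilarityResult:
    """TCSS similarity between two gene products.

    MAX takes the best term-pair score over S x T; BMA averages each term's
    best match against the other gene's set, symmetrically:

        ( sum_i max_j score(s_i, t_j) + sum_j max_i score(s_i, t_j) )
        / (|S| + |T|)

    BMA never exceeds MAX since every best match is bounded by the global
    pair maximum.
    """
    if mode not in ("max", "bma"):
        raise ValueError(f"mode must be 'max' or 'bma', got {mode!r}")
    root = clustering.ica.root
    S = sorted(ann.usable_terms(gene_a, root))
    T = sorted(ann.usable_terms(gene_b, root))
    for gene, terms in ((gene_a, S), (gene_b, T)):
        if not terms:
            reason = (
                "gene not annotated" if gene not in ann.gene_terms
                else "only root-level annotation"
            )
            return SimilarityResult(gene_a, gene_b, None, mode, reason=reason)

    table = {
        (s, t): term_pair_score(clustering, s, t) for s in S for t in T
    }
    if mode == "max":
        (s, t), (score, level, _) = max(
            table.items(), key=lambda kv: (kv[1][0], kv[0])
        )
        return SimilarityResult(gene_a, gene_b, score, mode, level=level, terms=(s, t))
    best_s = [max(table[(s, t)][0] for t in T) for s in S]
    best_t = [max(table[(s, t)][0] for s in S) for t in T]
    score = (sum(best_s) + sum(best_t)) / (len(S) + len(T))
    return SimilarityResult(gene_a, gene_b, score, mode)


def score_pairs(
    clustering: Clustering,
    ann: AnnotationSet,
    pairs: Iterable[tuple[str, str]],
    mode: Mode = "max",
) -> pd.DataFrame:
    """Score many gene pairs; unscorable pairs keep NA scores with a reason."""
    rows = []
    for a, b in pairs:
        r = gene_pair_similarity(clustering, ann, a, b, mode)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "score": r.score,
                "level": r.level,
                "terms": "|".join(r.terms) if r.terms else None,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "level", "terms", "reason"])
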