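"""Synthetic OBO / GAF / pair / expression fixtures.

The generator emulates the structural features that motivate two-level
scoring on the real Gene Ontology: branches of very unequal depth (the
'intracellular'-deep vs 'extracellular'-shallow contrast), multi-parent
terms, and annotation corpora biased toward specific (leaf) terms.  It does
not attempt GO-scale realism (>10^4 terms) or evidence-code semantics
beyond the IEA flag.

PPI benchmarks are planted against a reference clustering: a positive pair
shares a sub-graph with probability ``co_rate_pos``, a negative pair with
``co_rate_neg``; realized rates are reported so tests can verify the
construction.  All randomness flows through per-artifact seeds so ontology
and annotations can vary independently; a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, parse_gaf, reduce_to_most_specific
from .clustering import cluster
from .evaluation import EvaluationError, LabeledPairSet
from .ontology import ASPECT_OF_NAMESPACE, OntologyDAG, parse_obo


@dataclass(frozen=True)
class BranchSpec:
    """One branch below the namespace root.

    ``depth`` is the maximum root-to-leaf distance contributed by the
    branch (depth 1 = a single child of the root); ``width`` is the number
    of terms per level below the branch root.
    """

    depth: int
    width: int = 1


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ontology/annotation fixture."""

    branches: Sequence[BranchSpec] = (BranchSpec(4, 3), BranchSpec(2, 2))
    multi_parent_p: float = 0.1
    n_genes: int = 50
    leaf_bias: float = 0.7  # probability an annotation lands on a leaf
    max_terms_per_gene: int = 3
    iea_fraction: float = 0.0
    coherent: bool = False  # concentrate each gene's annotations in one concept
    super_groups: int = 0  # mid-level compartment nodes between root and branches
    home_weights: Sequence[float] | None = None  # branch popularity (coherent mode)
    namespace: str = "cellular_component"
    seed: int = 0

    @property
    def n_terms(self) -> int:
        return 1 + self.super_groups + sum(
            1 + (b.depth - 1) * b.width for b in self.branches
        )

    def validate(self) -> None:
        for b in self.branches:
            if b.depth < 1 or b.width < 1:
                raise ValueError(f"invalid branch spec {b}")
        if not 0 <= self.multi_parent_p <= 1 or not 0 <= self.leaf_bias <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.iea_fraction <= 1:
            raise ValueError("iea_fraction must lie in [0, 1]")
        if self.n_genes < 1 or self.max_terms_per_gene < 1:
            raise ValueError("need at least one gene and one term per gene")
        if self.super_groups < 0:
            raise ValueError("super_groups must be >= 0")
        if self.home_weights is not None and (
            len(self.home_weights) != len(self.branches)
            or any(w < 0 for w in self.home_weights)
            or sum(self.home_weights) == 0
        ):
            raise ValueError("home_weights must be non-negative, one per branch")


def _go_id(i: int) -> str:
    return f"GO:{i:07d}"


def _branch_roots(dag: OntologyDAG, spec: FixtureSpec) -> list[str]:
    """Branch-root ids in branch order (ids are assigned deterministically)."""
    roots = []
    counter = 1 + spec.super_groups
    for branch in spec.branches:
        counter += 1
        roots.append(_go_id(counter))
        counter += (branch.depth - 1) * branch.width
    missing = [r for r in roots if r not in dag]
    if missing:
        raise ValueError(f"spec does not match ontology: missing {missing}")
    return roots


def generate_ontology(spec: FixtureSpec) -> str:
    """Emit OBO 1.2 text for the specified branch structure.

    Each branch root is a child of the namespace root — or, when
    ``super_groups`` > 0, of a mid-level compartment node (branch i attaches
    to super i mod ``super_groups``), emulating broad divisions like
    intracellular vs extracellular.  Each deeper branch level holds
    ``width`` terms whose primary parent is drawn from the previous level.
    Extra multi-parent edges (probability ``multi_parent_p``) always point
    to a strictly earlier level of the same branch, preserving acyclicity
    by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counter = 1
    root = _go_id(counter)
    stanzas = [
        "[Term]",
        f"id: {root}",
        "name: namespace root",
        f"namespace: {spec.namespace}",
        "",
    ]
    supers = []
    for s_idx in range(spec.super_groups):
        counter += 1
        sid = _go_id(counter)
        supers.append(sid)
        stanzas += [
            "[Term]",
            f"id: {sid}",
            f"name: compartment {s_idx}",
            f"namespace: {spec.namespace}",
            f"is_a: {root}",
            "",
        ]
    for b_idx, branch in enumerate(spec.branches):
        counter += 1
        branch_root = _go_id(counter)
        parent_of_branch = supers[b_idx % len(supers)] if supers else root
        stanzas += [
            "[Term]",
            f"id: {branch_root}",
            f"name: branch {b_idx} root",
            f"namespace: {spec.namespace}",
            f"is_a: {parent_of_branch}",
            "",
        ]
        levels = [[branch_root]]
        for level in range(1, branch.depth):
            current = []
            for w in range(branch.width):
                counter += 1
                tid = _go_id(counter)
                parent = levels[-1][rng.integers(0, len(levels[-1]))]
                lines = [
                    "[Term]",
                    f"id: {tid}",
                    f"name: branch {b_idx} level {level} term {w}",
                    f"namespace: {spec.namespace}",
                    f"is_a: {parent}",
                ]
                if rng.random() < spec.multi_parent_p:
                    pool = [t for lv in levels for t in lv if t != parent]
                    if pool:
                        extra = pool[rng.integers(0, len(pool))]
                        lines.append(f"relationship: part_of {extra}")
                lines.append("")
                stanzas += lines
                current.append(tid)
            levels.append(current)
    header = ["format-version: 1.2", f"ontology: synthetic-{spec.seed}", ""]
    return "\n".join(header + stanzas)


def generate_annotations(dag: OntologyDAG, spec: FixtureSpec) -> str:
    """Emit GAF 2.1 text annotating ``n_genes`` genes onto ``dag``.

    Every gene receives 1..max_terms_per_gene distinct non-root terms; a
    configurable fraction of rows carries the IEA evidence code, the rest
    IDA.  Two placement modes:

    * scattered (default): each term is drawn independently from the whole
      ontology, from the leaves with probability ``leaf_bias`` and from
      internal terms otherwise.
    * coherent (``spec.coherent``): each gene first picks a *home* concept
      (a branch root, in branch order) with probability proportional to
      ``spec.home_weights`` (uniform when unset) and then annotates
      uniformly within the home's sub-tree.  Skewed weights reproduce the
      Zipf-like annotation imbalance of real corpora: heavily used general
      concepts acquire low IC, sparsely used specific ones high IC, which
      is what makes raw-IC measures under-score pairs in popular shallow
      concepts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    leaves = sorted(dag.leaves())
    internal = sorted(set(dag.terms) - set(leaves) - {dag.root})
    if not internal:  # star-shaped ontologies: fall back to leaves
        internal = leaves
    if spec.coherent:
        homes = _branch_roots(dag, spec)
        if spec.home_weights is not None:
            home_p = np.asarray(spec.home_weights, dtype=float)
        else:
            home_p = np.ones(len(homes))
        home_p = home_p / home_p.sum()
    aspect = ASPECT_OF_NAMESPACE[dag.namespace]
    rows = ["!gaf-version: 2.1"]
    for g in range(1, spec.n_genes + 1):
        gene = f"G{g:04d}"
        k = int(rng.integers(1, spec.max_terms_per_gene + 1))
        if spec.coherent:
            home = homes[rng.choice(len(homes), p=home_p)]
            pool_home = sorted(dag.descendants(home) | {home})
            k = min(k, len(pool_home))
        else:
            k = min(k, len(set(leaves) | set(internal)))
        chosen: set[str] = set()
        while len(chosen) < k:
            if spec.coherent:
                pool = pool_home
            else:
                pool = leaves if rng.random() < spec.leaf_bias else internal
            chosen.add(pool[rng.integers(0, len(pool))])
        for term in sorted(chosen):
            evidence = "IEA" if rng.random() < spec.iea_fraction else "IDA"
            rows.append(
                "\t".join(
                    [
                        "SYN",          # DB
                        gene,           # DB object id
                        gene.lower(),   # symbol
                        "",             # qualifier
                        term,           # GO id
                        "SYN_REF:0000001",
                        evidence,
                        "",
                        aspect,
                        f"synthetic gene {gene}",
                        "",
                        "gene",
                        "taxon:559292",
                        "20100301",
                        "SYN",
                    ]
                )
            )
    return "\n".join(rows) + "\n"


def generate_fixture(spec: FixtureSpec) -> tuple[OntologyDAG, AnnotationSet]:
    """Ontology + most-specific-reduced annotations, parsed through the
    package's own readers."""
    dag = parse_obo(generate_ontology(spec), spec.namespace)
    ann = parse_gaf(generate_annotations(dag, spec), dag)
    return dag, reduce_to_most_specific(ann, dag)


def generate_ppi_benchmark(
    dag: OntologyDAG,
    ann: AnnotationSet,
    n_pos: int,
    n_neg: int | None = None,
    co_rate_pos: float = 0.9,
    co_rate_neg: float = 0.2,
    reference_cutoff: float = 2.0,
    seed: int = 0,
) -> tuple[LabeledPairSet, dict]:
    """Plant a co-sub-graph signal into labeled gene pairs.

    Under the clustering at ``reference_cutoff``, two genes co-cluster when
    the sub-graph root sets covering their annotations intersect.  The
    namespace root's residual sub-graph is ignored for this test: a pair
    meeting only there scores through the zero-IC root, which is no signal.
    Each
    positive pair is drawn co-clustered with probability ``co_rate_pos``,
    each negative with ``co_rate_neg`` (negatives default to the same count
    as positives).  Returns the pair set plus diagnostics with realized
    rates.
    """
    if not co_rate_pos > co_rate_neg:
        raise EvaluationError("need co_rate_pos > co_rate_neg to plant a signal")
    if n_neg is None:
        n_neg = n_pos
    clustering = cluster(dag, ann, reference_cutoff)
    membership = clustering.index.membership
    gene_roots: dict[str, frozenset[str]] = {}
    for gene in ann.genes():
        covered: set[str] = set()
        for t in ann.usable_terms(gene, dag.root):
            covered |= membership.get(t, frozenset())
        covered.discard(dag.root)
        if covered:
            gene_roots[gene] = frozenset(covered)
    genes = sorted(gene_roots)
    if len(genes) < 4:
        raise EvaluationError("too few annotated genes to build a benchmark")

    rng = np.random.default_rng(seed)
    used: set[frozenset[str]] = set()

    def draw_pair(co: bool) -> tuple[str, str]:
        for _ in range(10_000):
            i, j = rng.integers(0, len(genes), size=2)
            if i == j:
                continue
            a, b = sorted((genes[i], genes[j]))
            key = frozenset((a, b))
            if key in used:
                continue
            share = bool(gene_roots[a] & gene_roots[b])
            if share == co:
                used.add(key)
                return a, b
        raise EvaluationError(
            f"could not draw a {'co' if co else 'non-co'}-clustered pair; "
            f"annotation structure too {'fragmented' if co else 'uniform'}"
        )

    def draw_set(n: int, co_rate: float) -> tuple[list[tuple[str, str]], int]:
        pairs, n_co = [], 0
        for _ in range(n):
            co = bool(rng.random() < co_rate)
            pairs.append(draw_pair(co))
            n_co += int(co)
        return pairs, n_co

    positives, pos_co = draw_set(n_pos, co_rate_pos)
    negatives, neg_co = draw_set(n_neg, co_rate_neg)
    diagnostics = {
        "reference_cutoff": reference_cutoff,
        "n_subgraph_roots": len(clustering.index.roots),
        "realized_co_rate_pos": pos_co / n_pos if n_pos else 0.0,
        "realized_co_rate_neg": neg_co / n_neg if n_neg else 0.0,
    }
    pair_set = LabeledPairSet(
        positives=tuple(positives),
        negatives=tuple(negatives),
        provenance=f"planted co-sub-graph benchmark at cutoff {reference_cutoff}",
        seed=seed,
    )
    return pair_set, diagnostics


def generate_expression(
    genes: Sequence[str],
    n_experiments: int = 5,
    samples_per_experiment: int = 10,
    coexpressed_pairs: Sequence[tuple[str, str]] = (),
    coexpression: float = 0.8,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Gaussian expression profiles, optionally with planted co-expression.

    Genes in ``coexpressed_pairs`` share a latent profile mixed in with
    weight ``coexpression``; all other profiles are independent N(0, 1).
    """
    rng = np.random.default_rng(seed)
    partner_latent: dict[str, np.ndarray] = {}
    out: dict[str, pd.DataFrame] = {}
    for e in range(n_experiments):
        name = f"exp{e + 1:02d}"
        data = rng.standard_normal((len(genes), samples_per_experiment))
        frame = pd.DataFrame(
            data,
            index=list(genes),
            columns=[f"s{j + 1}" for j in range(samples_per_experiment)],
        )
        for a, b in coexpressed_pairs:
            latent = rng.standard_normal(samples_per_experiment)
            for g in (a, b):
                if g in frame.index:
                    noise = rng.standard_normal(samples_per_experiment)
                    frame.loc[g] = coexpression * latent + (1 - coexpression) * noise
        out[name] = frame
    return out


def expression_to_long_tsv(experiments: dict[str, pd.DataFrame]) -> str:
    """Long-format TSV: experiment, gene, one column per sample value."""
    rows = ["experiment\tgene\t" + "\t".join(
        next(iter(experiments.values())).columns
    )]
    for name, frame in experiments.items():
        for gene, profile in frame.iterrows():
            rows.append(f"{name}\t{gene}\t" + "\t".join(f"{v:.6f}" for v in profile))
    return "\n".join(rows) + "\n"


def spec_metadata(spec: FixtureSpec) -> str:
    """Fixture parameters echoed as JSON (shipped beside generated files)."""
    payload = asdict(spec)
    payload["branches"] = [asdict(b) for b in spec.branches]
    payload["n_terms"] = spec.n_terms
    return json.dumps(payload, indent=2, sort_keys=True)
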