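# Methods

## Model and assumptions

The package scores a gene-product pair by where their Gene Ontology
annotations sit relative to a partition of one GO namespace into
*sub-graphs* of related terms. The driving assumption is that annotation
corpora and ontology structure are both informative but differently
biased: annotation counts say how specific a term is *in use*, while the
descendant count says how specific it is *topologically*. The two-level
scheme uses the topological signal to decide which terms belong to one
concept, then renormalizes the annotation signal inside each concept so
that a shallow but complete concept is not penalized relative to a deep
one.

All quantities operate on one namespace at a time; edges of every
relationship type present in the OBO file (`is_a`, `part_of`,
`regulates`, …) are treated as equivalent parent links, with a loader
option to restrict types. Obsolete terms are dropped at load, `alt_id`
aliases resolve to canonical accessions, and cross-namespace edges are
discarded. Annotations with a `NOT` qualifier are excluded (they assert
non-membership); rows with excluded evidence codes (typically `IEA`) are
dropped on request; each gene is then reduced to its most specific terms
(a per-gene antichain), since a term aggregates its descendants.

## Information content

* **Annotation IC.** ICA(t) = −ln(annot(t)/annot(root)), where annot(t)
  counts *distinct* genes annotated to t or any descendant (union
  semantics, no double counting) and annot(root) is the corpus size. The
  denominator makes annot(t)/annot(root) a probability with p(root) = 1
  and ICA(root) = 0; a summed-over-terms denominator would double-count
  genes and break the probabilistic reading that the worked example
  (p = 0.104) requires. Natural log throughout. Terms with annot = 0
  carry no ICA and are excluded from scoring.
* **Topological IC.** ICT(t) = −ln((|D(t)|+1)/|O|) over the descendant
  closure D(t). Reading the "child" count as the full closure (plus self,
  avoiding −ln 0 at leaves) is what makes published cutoffs in the 2–4
  range meaningful: direct-child counts would place every GO term far
  above them. ICT is computed as log|O| − log closure so that the root is
  exactly 0 and leaves exactly ln|O|, making boundary cutoffs behave
  predictably.

Both tables are computed in one reverse-topological sweep with set
accumulation, so shared descendants are never double counted.

## Clustering

Terms with ICT ≤ cutoff become sub-graph root candidates; the namespace
root (ICT 0) always qualifies. Candidate roots nested under another root
with ICT within ±20% of the ancestor's are merged into it, processed in
ascending ICT order with lexicographic tie-break — merging unrelated
(incomparable) roots would create disconnected "sub-graphs", and the
ascending sweep makes cascading deterministic. The namespace root's ±20%
window is degenerate at zero, so it never absorbs anything.

After transitive reduction (the unique minimal DAG with the same
reachability), each term is assigned to the sub-graph(s) of its *most
specific* root ancestor(s): among selected roots that are ancestors-or-
self of the term, the poset-minimal ones. Comparable candidates collapse
to the deepest (which also maximizes ICT, by monotonicity); incomparable
candidates all survive, duplicating the term — and implicitly its
descendants — into several sub-graphs, which is exactly the
disjunctive-ancestor case that term duplication is meant to handle.
Without the most-specific rule every sub-graph would contain the whole
ontology, since the namespace root is always selected.

ICS(t) within a sub-graph divides ICA(t) by the sub-graph's maximal ICA
(so at least one term per sub-graph has ICS = 1); ICM(t) over the
meta-graph — sub-graph roots plus all their ancestors, with reduced
induced edges — divides by the maximal ICA among meta nodes. Sub-graphs
containing no annotated term are flagged with a warning and excluded from
scoring; a sub-graph whose only annotated term is the namespace root gets
ICS ≡ 0.

## Scoring

The lowest common ancestor of two terms is the common ancestor-or-self
with maximal ICA, ties broken toward the smallest accession for
reproducibility. A term pair sharing at least one sub-graph scores the
ICS of its LCA within that sub-graph (the maximum across shared
sub-graphs when duplication provides several, consistent with MAX
semantics); otherwise it scores the ICM of its LCA among meta nodes,
which always exists because the namespace root is a meta node. A term
that *is* a meta node still belongs to its own sub-graph, so meta scoring
applies only when no sub-graph is shared.

Gene pairs combine term scores by MAX or BMA (each term's best match
against the other set, averaged over |S| + |T|); BMA ≤ MAX holds
identically. Genes lacking any non-root annotation are *unscorable* and
are reported with an explicit sentinel and reason, never silently
dropped; evaluation counts them separately and excludes them from
TPR/FPR denominators.

Baselines share the ICA corpus: Resnik is normalized by the
ontology-wide maximal ICA to land on [0, 1]; Lin's ratio is
normalization-invariant so raw ICA is used; Jiang's distance d maps to
similarity 1/(1+d) (bounded, monotone, exactly 1 at d = 0 — the transform
is a configuration point since no canonical choice exists); simRel
multiplies Lin by (1 − p(LCA)); simGIC is the IC-weighted Jaccard index
over ancestor-closed annotation sets and takes no combination rule.
When the cutoff is so low that the namespace root is the only sub-graph
root, TCSS MAX degenerates to normalized Resnik MAX exactly — a useful
internal consistency check that the test suite exercises.

## Evaluation harness

ROC curves sweep all distinct scores as thresholds (predict positive at
score ≥ threshold; tied scores collapse to one threshold) and AUC is the
trapezoidal integral over (FPR, TPR) with (0, 0) prepended; on tie-free
data this equals the Mann–Whitney U statistic divided by n₊n₋, which the
tests verify against SciPy. F1 tables use a fixed semantic-similarity
cutoff grid (0.05…0.95, step 0.05) and method comparison reports the mean
of F1 ratios over cutoffs where the baseline F1 is positive, with the
count of excluded cutoffs. The topology-cutoff grid search scores a
labeled benchmark at each cutoff and returns the AUC argmax, ties broken
toward the smaller cutoff.

Negative pair sets are sampled uniformly (seeded, rejection sampling with
an enumeration fallback) from the gene universe minus self-pairs and
known positives, defaulting to the positive-set size.

Expression agreement per pair computes a Pearson correlation per
experiment, transforms with Fisher's z = arctanh r (|r| = 1 clamped to
1 − 10⁻⁹), averages, and inverts with tanh. The reference formula divides
the summed z values by N − 1; this is kept as the default (with
max(N−1, 1) so a single experiment stays finite) and an ordinary-mean
(`n`) option is exposed, since the N − 1 denominator is nonstandard for
an average and is likely a typo. Zero-variance profiles skip that
experiment for that pair; pairs absent from the matrix are reported with
NA.

## Synthetic fixtures

The generator emits parseable OBO 1.2 and GAF 2.1 text for ontologies
made of a namespace root, optional mid-level compartment nodes
(`super_groups`), and branches with exact depth/width control, so the
depth-7-vs-depth-1 imbalance that motivates the method can be
constructed directly. Multi-parent edges are added only toward earlier
levels of the same branch, keeping acyclicity by construction. Annotation
placement has two modes: *scattered* (independent terms, leaf-biased) and
*coherent* (each gene annotates within one branch concept, with per-branch
popularity weights). Skewed weights reproduce the Zipf-like imbalance of
real corpora — heavily used general concepts acquire low IC — which is
the regime where raw-IC measures misrank pairs. All randomness is
seeded per artifact type; fixed seeds give byte-identical files.

Planted PPI benchmarks draw positive pairs that share a sub-graph under a
stated reference clustering with probability 0.9 and negatives with
probability 0.2 (realized rates are reported). The residual sub-graph
rooted at the namespace root is ignored by the co-clustering test, since
pairs meeting only there score through the zero-IC root and carry no
signal. The shipped study corpus for the benchmark (8 concepts under two
compartments, one popular single-term concept, 150 genes, popularity
weights 0.40/0.10/0.10/0.07/0.12/0.07/0.08/0.06, reference cutoff 2.5)
is sized so the full grid search runs in seconds on one core.

### What the planted benchmark does and does not show

Below the construction cutoff the clustering normalizes at the
compartment level, over-scores same-compartment non-co pairs, and loses
roughly five AUC points — the benchmark resolves the lower arm of the
cutoff curve sharply. Above the construction cutoff it cannot lose by
construction: planted co-positive and co-negative pairs are drawn from
the same distribution, and LCA-IC scores are monotone in the hierarchy,
so finer clusterings only reshuffle ranks within the co-group. The grid
search therefore recovers the construction cutoff as the *smallest*
optimum via its deterministic tie-break. On real corpora the
above-cutoff arm of the AUC curve falls for reasons this generator does
not emulate (label-correlated annotation depth, curation artifacts);
passing tests demonstrate the machinery and the lower arm, not the full
U-shape. Likewise the synthetic scale (tens of terms, hundreds of genes)
leaves real-GO phenomena — tens of thousands of terms, heavy multi-
parentage across branches, evidence-code structure beyond IEA —
untested.

## Numerical choices and degenerate inputs

* Ties anywhere (LCA choice, MAX-mode contributing pair, merge order,
  grid-search argmax) break lexicographically or toward the smaller
  value, so every result is reproducible bit for bit.
* Score equality checks in tests use absolute tolerances of 1e−6 (against
  hand-computed six-decimal tables) or 1e−12 (against exact identities).
* A cutoff selecting every term triggers a degenerate-clustering warning
  but proceeds (each term becomes its own sub-graph; pairs score at meta
  level, reproducing normalized-IC ranking).
* Single-class label vectors, empty benchmarks, zero-candidate negative
  sampling and zero-baseline F1 ratios raise typed errors rather than
  returning silently wrong numbers.

## Limitations

The implementation targets desk-scale corpora; `networkx` transitive
reduction and per-term set accumulation are comfortably fast to a few
thousand terms but have not been profiled at full-GO scale. Wang et al.'s
edge-based measure is out of scope (only an external R implementation was
ever used for it), as are cross-ontology score combination, GO-slim
mapping, and protein-complex (k > 2) similarity.
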