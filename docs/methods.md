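# Methods

This note documents the models and procedures implemented in kgwalk, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Graph model

A `KnowledgeGraph` is a set of named individuals, classes and object
properties, a set of triples (relational edges, `rdf:type` instantiation
edges, and — in closed graphs — `rdfs:subClassOf` edges), and two axiom
boxes: class axioms (TBox) and property axioms (RBox). Parsing routes
asserted `rdfs:subClassOf`, OWL class-expression and property-axiom triples
into the boxes, so the *walkable* edge set of a raw graph contains only
relational and instantiation edges; the class hierarchy becomes walkable
only through materialization. This split is what makes the
with/without-reasoning contrast meaningful: in the raw graph an annotation
reaches exactly its asserted leaf class, while the closed graph adds type
edges to every entailed ancestor.

Identifiers are plain strings; serialization expands them to IRIs under a
reserved base namespace and the round trip `parse(serialize(kg)) = kg` is
exact on raw graphs (tested over random generator output). Serializing a
*closed* graph folds its subclass edges onto the same `rdfs:subClassOf`
triples that encode the TBox axioms; they are re-derivable by a single
`materialize` call.

Reified annotations mint fresh individuals `ann:f1, ann:f2, …` from a
deterministic counter, skipping any identifier already present — uniqueness
is the requirement, determinism makes builds reproducible. Duplicate
triples collapse (RDF set semantics). Entity categories (drug, protein,
disease, …) are assigned from a configurable class→category map, resolving
through named subclass ancestors; undeclared properties are declared on the
fly with a logged warning by default, or rejected in strict mode.

## Reasoner

Axioms are normalized first: equivalences become subsumption pairs in both
directions; nested intersections and existentials are flattened through
fresh intermediate classes (`norm:X1, …`), leaving six class normal forms
(named subclass, conjunction subclass `A1 ⊓ A2 ⊑ B`, `∃r.A ⊑ B`,
`A ⊑ ∃r.B`, disjointness) and five property forms (subproperty,
transitivity, reflexivity, binary chain). Fresh classes participate in
every inference but are filtered from all emitted triples, keeping the
closure inside the named fragment.

TBox saturation computes the least fixpoint of: reflexivity `C ⊑ C`;
transitivity; conjunction firing; and the existential composition
`C ⊑ ∃r.A`, `A ⊑ A′`, `∃s.A′ ⊑ B` with `r ⊑* s` (reflexive-transitive
subproperty closure) entailing `C ⊑ B`. Property chains and transitivity
act on the ABox only; chain composition at the TBox level is not part of
the rule set.

ABox materialization runs semi-naive (delta-driven) rounds of:

* R1 type inheritance through the *saturated* hierarchy,
* R2 subproperty, R3 transitivity, R4 binary chains,
* R5 reflexivity — `r(x,x)` for every named individual, behind a flag
  defaulting on (restricting to r-participants would be semantically
  incomplete),
* R6 conjunction and R7 left-existential class inference,
* all saturated subsumptions added as subclass edges (the reflexive
  `C ⊑ C` pairs are kept internal — they would only create degenerate
  self-loop walk tokens).

`A ⊑ ∃r.B` never mints anonymous individuals; it only feeds saturation.
Disjointness violations are collected into the closure report as
`(individual, A, B)` tuples; they are diagnostics, not errors. The engine
is checked for set-identity against a naive one-rule-at-a-time fixpoint
oracle (kept in the test suite only) on hundreds of random instances
spanning all eleven axiom forms, plus monotonicity, idempotence and
rule-order independence.

## Walks

A walk of length `n` (counting edges; at most `2n+1` tokens) follows
uniformly random *outgoing* edges, recording both nodes and edge labels.
Dead ends truncate the walk — no restarts, no self-loops. Instantiation
and subclass edges of the closed graph are traversed like any relational
edge, under reserved label tokens. The start set defaults to all nodes;
each start node owns an RNG substream spawned from the corpus seed, so
corpora are bit-identical regardless of scheduling. Only outgoing edges
are followed by default, matching the directed semantics of the relations;
an optional flag makes every edge traversable backwards under a
synthesized inverse label (`prop_inv`), default off.

## Embeddings

Skip-gram with negative sampling, trained by plain sequential SGD (a
numba-compiled kernel; deterministic for a fixed seed). Choices the
formulation leaves open, fixed here:

* Noise distribution `Pn(w)`: unigram frequency to the 3/4 power — the
  convention of the word2vec lineage. Noise draws are with replacement,
  redrawn when they hit the center token.
* Subsampling: discard probability `max(0, 1 − sqrt(t/f))`, applied
  per-token per-epoch; `t = 10⁻³` by default. Tokens at or below the
  threshold are never discarded.
* Window `c` counts tokens — nodes and labels alike — matching a
  plain-text reading of the corpus; the effective window per center is
  drawn uniformly from `1..c` (the standard dynamic-window scheme).
* Minimum count 1: every walked token receives a vector. Nodes never
  reached by any walk have none, and downstream consumers treat them as
  missing, never as zero vectors.
* Learning rate decays linearly from `alpha` (default 0.025) to
  `min_alpha` over the planned token stream; 5 epochs by default.
* Initialization: inputs uniform in `±0.5/dim`, outputs zero.

The per-pair objective `log σ(v′_O·v_I) + Σ log σ(−v′_i·v_I)` and its
analytic gradient are exposed as plain functions and verified against
central finite differences at 1e-5 relative tolerance; the kernel
implements the same math.

Embeddings are written in the word2vec text format (header `vocab dim`,
one token per line). Cosine similarity raises on zero vectors; neighbor
queries exclude the query token and break ties lexicographically.

## Prediction protocol

Per property: 5-fold cross-validation partitions the property's edges into
disjoint chunks. Per fold, the held-out chunk is removed, the training
graph is (optionally) materialized — held-out triples that inference
re-derives are **deleted and counted as leakage** — then walked and
embedded; a logistic regression (L2, C = 1.0, lbfgs) is fit on pair
features of the retained positives and an equal number of type-constrained
negatives, and scored on the held-out positives plus freshly sampled
negatives disjoint from the training negatives. Negatives are always
non-edges of the *original* graph between nodes matching the property's
source/target categories; only same-property edges are excluded, not edges
of other properties between the same pair.

Pair features are the concatenation of the two endpoint embeddings by
default (a `2d` feature vector), switchable to the Hadamard product. The
two maps answer different questions: a linear model over *concatenated*
features can only score `w1·e_u + w2·e_v` — node-level propensities — while
a linear model over the *Hadamard* product scores `Σ_d w_d e_{u,d} e_{v,d}`,
a learned inner product, i.e. pair-level similarity. The F-measure is
computed at the 0.5 probability cutoff; ROCAUC counts ties as one half.

The shared-relation pair task removes the defining relation's edges before
embedding, labels entity pairs by whether they share at least one target
of that relation in the original graph, samples an equal number of
non-sharing pairs, and evaluates a classifier on an 80/20 pair split.

Grid search reruns the CV protocol per parameter combination on a single
property, reusing cached walk corpora across combinations that differ only
in embedding-stage parameters, and returns a table ranked by mean AUC with
per-cell failures recorded rather than raised.

## Synthetic fixtures and what they show

`generate` plants a latent-group block structure: entities per category,
a rooted class tree per category whose leaves are split into per-group
pools, reified annotations drawn from the group pool, and relational edges
drawn with within-group probability `p_in` (optionally per group) and
cross-group `p_out`, plus a small uniform noise fraction.

The default configuration uses two groups with *asymmetric* densities
(`hasTarget`: 0.85 in the signal group, 0.02 in the background group,
0.02 across). This is deliberate: with two symmetric dense blocks, "same
group" over concatenated embeddings is a parity function and provably not
linearly separable — held-out edges of a block model are statistically
identical to within-block non-edges, so no linear classifier could reach
high held-out AUC no matter how good the embeddings. One dense block plus
background turns the signal into an AND of two half-spaces, which is
linear. The fixture therefore tests that the pipeline recovers a planted,
linearly decodable community signal — not that it can solve parity.

`generate_reasoning_benefit` plants a signal that exists *only after
closure*: interacting pairs are annotated with distinct sibling leaf
classes whose shared parent (and subtree ancestor) is unreachable in the
raw graph. Its reference evaluation uses Hadamard features, because the
planted signal is pair-level similarity (a shared inferred ancestor), the
very thing a concatenation map cannot express; with concatenation the fold
classifier instead keys on the held-out endpoints' loss of their single
relation edge and lands below chance. At the reference parameters the
closed-graph AUC exceeds the raw-graph AUC by ≈ 0.2.

`destroy_signal` is the null control: the property's edges are re-drawn
uniformly at random within the original endpoint categories. The re-draw
destroys the degree profile along with the block structure — a
degree-preserving shuffle would leave a legitimate node-propensity signal
and therefore would not be a signal-free null.

**Scope of these demonstrations.** The generator emulates the *structure*
of integrated biomedical graphs (two layers, reified annotations, category
constraints, community-driven relations), not their statistics: real
degree distributions are heavy-tailed, annotation depth varies, relations
overlap, and knowledge graphs are incomplete (some sampled "negatives" are
true edges). Passing fixtures shows the pipeline is correct and recovers
plantable signal; it does not predict absolute performance on any real
database.

## Reference problem sizes

Desk-scale study conditions, chosen once so a full CV run takes seconds on
one CPU: ≈180 entities across three categories, ≈2 200 raw triples
(≈3 650 closed), embedding dimension 64, 20 walks of length 10 per node,
context 5. At this corpus size (≈70k tokens per fold) the full-scale
schedule of 5 epochs at rate 0.025 leaves embeddings undertrained, so the
scaled-down configuration trains 15 epochs at initial rate 0.05
(`synthetic.scaled_down_eval_params`). The full-scale defaults
(512 dimensions, 100 walks of length 20, context 10, 5 epochs) remain the
`PipelineConfig` defaults.

## Known limitations

* EL support is the listed rule subset: no nominals, no concrete domains,
  no ⊥-propagation beyond disjointness detection, binary chains only.
* The reasoner materializes eagerly; graphs far beyond ~10⁶ triples would
  need the delta indexes to move off Python sets.
* Skip-gram training is single-threaded by design (bit-reproducibility);
  large corpora trade wall-clock time for determinism.
* Logistic regression on embedding features captures linear structure
  only; parity-like relational patterns require the Hadamard map or a
  non-linear classifier.
* Walks follow outgoing edges only; nodes with zero out-degree contribute
  singleton walks and learn their vectors purely from incoming contexts of
  other walks.
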