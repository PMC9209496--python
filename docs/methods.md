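# Methods

## The language model

Two independent LSTM stacks process each protein: the forward stack
reads residues left-to-right and predicts the *next* residue; the
backward stack reads right-to-left and predicts the *previous* one. The
training loss is the sum of the two directions' mean cross-entropies,
minimized with AdamW (β₁ = 0.9, β₂ = 0.999, weight decay 0.01) under a
linear learning-rate warmup from 0 to the configured rate over
`warmup_steps` updates, constant afterwards. Reference-scale defaults —
3 layers × 1,024 hidden units per direction, sequences clipped to 1,500
residues, learning rate 1e-3 with 8,000 warmup steps, batches of 1,024 —
are kept as the `LanguageModelConfig` defaults; the bundled studies use
a 2 × 64 model trained for 300 steps in batches of 16 with 30 warmup
steps (the warmup:total ratio of the reference setup, ~4%).

Implementation is pure numpy: layer forward passes, backpropagation
through time, and the optimizer are written out explicitly, and the
analytic gradients are checked against central finite differences in the
test suite (relative tolerance 1e-3 at ε = 1e-5). Batches are
right-padded; because both stacks are causal in their own reading
direction (the backward stack consumes per-sequence-reversed,
right-padded input), states at real positions are unaffected by padding,
and the test suite asserts bit-level agreement between batched and
single-sequence embeddings.

Tokenization uses 29 tokens: `<pad>`, `<start>`, `<stop>`, the 20
canonical residues, and dedicated tokens for the ambiguity letters
B, Z, X, U, O, J. Ambiguity letters are legal *inputs* (they receive
embeddings) but never prediction *targets*, since they denote an
unresolved residue rather than a ground truth; the output head therefore
covers exactly the 20 canonical residues. The first residue contributes
no backward target and the last no forward target; those positions are
simply absent from the loss. `<start>`/`<stop>` are reserved in the
vocabulary but not inserted into inputs — pooling is over residue
positions only.

**ECE.** Exponential Cross-Entropy is `exp` of the mean per-target
cross-entropy in natural-log units, pooled over both directions and all
positions of all sequences (this makes it invariant under permutation
of the evaluation set). It is bounded below by 1 and equals the class
count — 20 — for a uniform predictor; the all-zero-weight model realizes
that bound exactly and serves as a calibration point. Cross-entropy base
(nat) is recorded in checkpoint metadata.

**Embeddings.** For each position the final layer's forward and backward
hidden states are concatenated (2 × hidden units; summing would halve
the dimension and is inconsistent with the 2,048-dimensional reference
embedding), then averaged over positions. Mean pooling, rather than the
last hidden state, is the established choice for proteins, which are far
longer than the sentences recurrent models were designed around.

## Baseline representations

The bag-of-k-mers vector counts all overlapping length-k substrings,
columns in alphabetical k-mer order, dimension 20^k (k = 3 by default:
8,000 columns). Windows containing an ambiguity letter contribute no
count, which keeps the dimension at exactly 20^k; a sequence shorter
than k yields a zero vector with a logged warning. Counts are held
sparse internally. TFIDF weighting uses the smoothed-IDF convention
`idf(t) = ln((1+n)/(1+df(t))) + 1` with L2-normalized rows (sklearn's
`TfidfTransformer` backs the implementation); the fitting corpus is an
explicit argument so a reference corpus can weight a query set.
Amino-acid frequency vectors normalize canonical-residue counts to sum
to one, ignoring ambiguity letters.

## Dimensionality reduction

PCA (default 50 components) centers the data and uses exact SVD up to
2,000 input columns, seeded randomized SVD above. Component signs are
canonicalized — the largest-magnitude loading of each component is made
positive — so results are bit-reproducible across runs. UMAP (default
n_neighbors = 50, min_dist = 0.3, all other parameters at library
defaults) consumes PCA output and is seed-reproducible but
orientation-arbitrary. The pipeline always feeds PCA output to UMAP.

## Label recovery

For each ontology, analysis is restricted to proteins that carry at
least one label there. Those proteins are partitioned into `n_folds`
seeded folds (default 5, i.e. 20% held out at a time); for each fold a
nearest-neighbor index is built on the remaining folds and every
held-out protein queries its `max_neighbors` (default 51) nearest
labeled neighbors by Euclidean distance, normally on the 50-dimensional
PCA vectors. Neighbor search is exact: distances to all index points
with ties broken by ascending protein id (a deliberate determinism
guarantee; approximate indexes only pay off far above these benchmark
sizes). A query protein is never its own neighbor — structurally, since
it sits in the held-out fold, and defensively in the index code.

Label aggregation over the k nearest neighbors is configurable:

* **majority** (default): a label is predicted iff it occurs in more
  than k/2 of the k neighbors; if no label clears the bar, the single
  nearest neighbor's label set is used, so predictions are never empty;
* **union**: all labels seen among the k neighbors;
* **plurality**: the most frequent label(s).

Each prediction is scored against the true label set with IoU,
example-based Precision, Recall and F1 (empty predictions score 0
precision by convention; F1 = 0 when P + R = 0). For single-label
ontologies all four metrics coincide with 0/1 accuracy. The procedure is
repeated `n_repeats` times (default 5) with seeds derived as
`seed + repeat`; aggregates are mean ± sd per (ontology, k).

**Recovery Error Rate.** `RER(p) = 1 − mean IoU(p)` with the mean pooled
over all recorded (ontology, k, repeat) values for protein p. Pooling
(rather than first averaging within each ontology) weights ontologies by
the number of evaluations they contribute; with a shared k-grid across
ontologies the two conventions differ little, and pooling keeps the
definition a plain mean over recorded values.

## Embedding distance versus sequence identity

Embedding distance is Euclidean, normally on 50 PCA components.
Sequence distance is `100 − percent identity` from a full global
pairwise alignment: BLOSUM62 scoring, affine gaps (open −10, extend
−0.5), identity = identical columns / alignment length with gap columns
in the denominator. This is a deliberate departure from the k-tuple
approximation used by multiple-alignment tools for unaligned input:
the exact pairwise alignment is self-contained and reproducible, at the
cost of not matching those tools' output numerically. Residues missing
from BLOSUM62 (U, O, J) are mapped to their closest standard letters
(C, K, L) for alignment only.

The group report computes, for both metrics, mean pairwise distance
within each group (unordered distinct pairs), between each group pair,
and from each group to a background sample (default 500 ids, drawn with
a seed from the matrix ids outside all groups; the reference analysis
reported insensitivity to background sizes of 100–1,000). Singleton
groups are excluded from within-group means with a logged note.

## The synthetic generator

Each family is defined by `motifs_per_family` conserved motifs
(default 2 × 10 residues, distinct across families). A member sequence
is an i.i.d. random background (default 96 residues) with the family's
motif copies spliced in at random positions, each copy independently
point-mutated at `substitution_rate` (default 0.1). Three ontologies are
emitted: *function* (one label per family, deterministic from motif
content), *domain* (one label per motif present), and *taxonomy*
(uniform over `n_taxa`, independent of the sequence — verified by a
chi-square independence check in the tests). `inject_shared_motif` adds
one motif to every member of selected families, modelling cross-family
similarity such as enzymes that share substrates; shared motifs are the
only source of multi-label annotations, which keeps the ground truth
auditable.

The background composition is configurable on the 20-simplex and
defaults to uniform. The language-model study instead uses natural
(UniProtKB) amino-acid composition, exposed as
`synthetic.natural_composition()`: residue composition is the first
statistic a protein language model learns, and a uniform background
leaves nothing generalizable — a model trained briefly on uniform
random backgrounds can only memorize its training sequences, and its
held-out ECE does not improve. With natural composition the 300-step
2 × 64 model reaches held-out ECE ≈ 18.0 against the ≈ 20.0 untrained
baseline, approaching the unigram entropy floor of ≈ 17.96 for that
composition.

What the generator does **not** model: indels and length heterogeneity,
positional composition, phylogenetic correlation between members, and
realistic family-size or label-frequency distributions. Passing
benchmarks on this corpus therefore demonstrates that the machinery is
correct and that motif-coupled labels are recoverable in principle —
not that any representation will reach a particular score on real
catalog data.

## Study conditions and problem sizes

The bundled studies (exercised by `scripts/acceptance.py` and the test
suite) run at sizes chosen to keep a full pass comfortably on one CPU:

* **LM study**: 5 families × 40 members, natural composition, 80/20
  train/held-out split; 2 × 64 model, 300 steps, batch 16.
* **Recovery study**: the 5 × 40 default corpus, k-mer TFIDF → PCA-50,
  fivefold CV, k ∈ {1, 3, 11, 51}, 5 repeats.
* **Use-case study**: 5 families × 6 members with 3 × 12-residue motifs
  over 80 background residues (~31% conserved content — in the range of
  enzyme families sharing whole catalytic domains), 3 groups plus a
  12-protein background drawn from the remaining families.
* **kNN exactness**: 500 points in 50 dimensions, 10 queries, every
  neighborhood size from 1 to 51, against a brute-force sort.

## Numerical choices and edge cases

* Distance ties in neighbor search break by ascending protein id;
  fold permutations, background draws and repeat seeds all derive from
  explicit integer seeds, so every analysis is bit-reproducible.
* PCA component signs are canonicalized as described; UMAP is only
  seed-reproducible.
* IoU/Precision/Recall are undefined (and raise) for empty ground-truth
  sets; proteins unlabeled in an ontology are excluded from that
  ontology's analysis instead.
* A sequence of length 1 contributes no language-model targets; an
  evaluation set consisting only of such sequences is an error.
* Matrix persistence rejects non-finite values and verifies the JSON
  sidecar (ids, method, dim) against the stored array on load.

## Known limitations

* The numpy language model is CPU-bound and intended for method
  development and benchmarking, not catalog-scale training; the
  reference-scale configuration is expressible but impractical here.
* Exact kNN is quadratic in corpus size; beyond ~10⁵ proteins an
  approximate index would be the right tool.
* Percent identity will not numerically match k-tuple-based tools, and
  the global-alignment identity of two co-optimal alignments can differ
  in the last decimal depending on traceback order.
* UMAP coordinates are for visualization only; no downstream analysis
  consumes them.
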