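# protrep

Alignment-free protein representations for metagenomics, plus the
benchmark that tells you whether a representation is any good.

Gut-microbiome catalogs are full of proteins that no alignment-based
database recognizes: up to ~40% of metagenomic gene products have no hit
in curated family resources. One way around the alignment bottleneck is
to represent every protein as a fixed-length numeric vector — an
*embedding* — and transfer annotations between neighbors in vector
space. This package implements that whole workflow at laptop scale:

* a **bidirectional LSTM protein language model**: two recurrent stacks
  read the sequence left-to-right and right-to-left, trained to predict
  the next and the previous residue. A protein's embedding is the mean
  over positions of the concatenated final-layer hidden states
  (`2 × hidden_units` dimensions — 2,048 at the reference 1,024 units).
  Model quality is tracked by **ECE** (Exponential Cross-Entropy,
  i.e. perplexity): `ECE = exp(mean per-residue cross-entropy)`, ≥ 1,
  exactly 20 for a uniform predictor over the canonical alphabet.
  Implemented in pure numpy (forward, backpropagation through time, and
  AdamW), with gradients verified against finite differences.
* **classical baselines**: the alphabetically ordered bag of k-mers
  (dimension 20^k: 400 / 8,000 / 160,000 for k = 2/3/4) with smoothed
  TFIDF weighting, and amino-acid frequency vectors;
* **PCA** reduction (default 50 components, deterministic component
  signs) and **UMAP** 2-D projection (n_neighbors = 50, min_dist = 0.3)
  for visualization;
* the **label-recovery benchmark**: fivefold cross-validated multi-label
  kNN annotation transfer (Euclidean neighbors, up to N = 51) over any
  ontology — protein families, orthologs, EC numbers, GO terms,
  taxonomy — scored with example-based IoU, Precision, Recall and F1,

      IoU = |pred ∩ truth| / |pred ∪ truth|

  and summarized per protein by the **Recovery Error Rate**
  `RER = 1 − mean IoU` (pooled over ontologies, neighborhood sizes and
  repeats);
* an **embedding-vs-sequence distance analysis** comparing Euclidean
  distances in representation space against global-alignment percent
  identity (BLOSUM62, affine gaps), within functional groups, between
  groups, and to a random background;
* a **synthetic corpus generator** — families defined by conserved
  motifs spliced into random backgrounds, with motif-derived "function"
  labels and sequence-independent "taxonomy" labels — so the entire
  pipeline runs end-to-end with no external data.

## Worked example

```python
import protrep as P

corpus = P.generate_corpus(P.FamilySpec(seed=11))          # 5 families x 40 members
m = P.kmer_tfidf_matrix(corpus.proteins, k=3)              # 200 x 8000 bag of 3-mers
reduced, evr = P.pca_reduce(m, P.ProjectionConfig(pca_components=50))
print(f"PCA to {reduced.dim} dims explains {evr.sum():.1%} of variance")

cfg = P.RecoveryConfig(k_values=(1, 3, 11, 51), n_repeats=5, seed=0)
report = P.evaluate_recovery(reduced, corpus.annotations,
                             ["function", "taxonomy"], cfg)
for ont in ("function", "taxonomy"):
    print(f"{ont:9s} mean IoU {report.mean_iou(ont):.3f}")
rer = P.recovery_error_rate(report)
print(f"RER range {rer.min():.3f}-{rer.max():.3f} over {len(rer)} proteins")
```

prints

```
PCA to 50 dims explains 30.2% of variance
function  mean IoU 0.922
taxonomy  mean IoU 0.188
RER range 0.000-1.000 over 200 proteins
```

Function labels follow the conserved motifs, so nearest neighbors in
k-mer space recover them well (IoU 0.92); taxonomy labels were assigned
at random, so their recovery sits at the ~1/5 chance level for five
taxa — the benchmark separates representations that capture biology from
ones that cannot. Per-protein RER then flags the members that even good
neighbors cannot explain.

The same workflow is available from the shell:

```bash
protrep simulate --out-fasta corpus.fasta --out-annotations labels.tsv --seed 11
protrep baseline --fasta corpus.fasta --method kmer-tfidf --k 3 --out kmer.mat
protrep reduce   --in kmer.mat --components 50 --out reduced.mat
protrep recover  --matrix reduced.mat --annotations labels.tsv \
                 --ontologies function,taxonomy --k 1,3,11,51 --seed 0 --out report.tsv
```

plus `train` / `ece` / `embed` for the language model, `project` for
UMAP coordinates and `distances` for the group-distance report. Every
command writes a JSON manifest beside its outputs; deterministic
commands rerun byte-identically from the same manifest.

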