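# Methods

## The model

`genesem` treats microbial gene families as the words of a language and
assembled contigs as its sentences. The working assumption is the genomic
analogue of the distributional hypothesis: in prokaryotes, co-functioning
genes are frequently clustered (operons, defense islands, secretion loci),
so the identity of a gene's neighbors carries information about its
function. The package learns that signal in two stages and then exploits it
in three downstream analyses.

### Stage 1 — skip-gram embeddings (`genesem.embedding`)

Each token g_i (a KO subcluster `KXXXXX.YY` or a hypothetical cluster
`hypo.clst.ZZZZ`) is mapped to a vector f(g_i) ∈ R^k by skip-gram with
negative sampling (SGNS). For every center/context pair within a symmetric
window of w positions on the same contig, training ascends

    log σ(u_ctx · v_center) + Σ_{n ∈ noise} log σ(−u_n · v_center),

with noise tokens drawn from the unigram distribution raised to the 3/4
power. f(g_i) is row i of the input matrix (identically W^T applied to the
one-hot vector of g_i); the context matrix is persisted only for
reproducibility.

Implementation notes:

* The inner loop is a numba-compiled kernel. Randomness inside the kernel
  comes from an explicit MINSTD linear congruential generator (all
  arithmetic below 2^47, so the compiled and pure-Python paths are
  bit-identical); `compiled=False` runs the very same function uncompiled,
  which the test suite uses as a bit-for-bit cross-check of the compiled
  path.
* The context window is fixed at w tokens each side (matching the formal
  −w ≤ j ≤ w definition), not randomly shrunk as in some word2vec
  implementations.
* No frequent-word subsampling: ubiquitous families are instead removed by
  the corpus frequency filter (below).
* Defaults: w = 5, k = 300, 5 negatives, 5 epochs, learning rate decaying
  linearly 0.025 → 0.0001. Window and dimension are the corpus-scale
  settings; epoch count, negative count and the learning-rate schedule are
  this package's choices (standard SGNS practice) and are exposed in the
  configuration. For synthetic desk-scale corpora (a few thousand contigs,
  a few hundred families) the tests and the acceptance script use k = 64,
  which is ample for vocabularies that small and keeps runs fast; nothing
  in the analyses depends on that choice beyond run time.
* Analytic per-pair loss/gradient functions (`sgns_pair_loss`,
  `sgns_pair_gradients`) are exposed so the SGD kernel can be verified
  against central finite differences.

### Corpus construction (`genesem.corpus`)

Gene tables (contig, ordinal position, token) become ordered sentences.
Three filters produce the training corpus:

* contigs shorter than 10 kbp are dropped (too little context; strict cut,
  a 10,000 bp contig survives);
* families with fewer than 24 occurrences are dropped ("at least 24" is
  inclusive);
* families with corpus frequency above 10⁻³ are dropped, with frequency
  computed on the min-count-filtered corpus.

Removed tokens are deleted in place — remaining tokens close ranks, so
context windows skip over removals rather than seeing a placeholder — and
sentences reduced below two tokens are dropped (they yield no context
pairs). Because removing a ubiquitous family shrinks the frequency
denominator and dropping short sentences shrinks counts, a single pass of
these rules is not idempotent at borderline thresholds; `filter_tokens`
therefore iterates the round (min-count → max-frequency → sentence drop) to
a fixed point. The first round is exactly the order stated above; further
rounds fire only in degenerate regimes, and idempotence holds by
construction.

### Stage 2 — category classification (`genesem.classifier`)

Embeddings of annotated tokens feed a four-layer feed-forward network:
hidden sizes 256/128/64, ReLU activations, dropout 0.2 on hidden layers
during training, softmax output, trained with Adam on categorical
cross-entropy for 20 epochs (batch size 256 by default; the desk-scale runs
use batch 16 so that a 50–100-word training set still yields enough
optimizer steps). The predicted category is the softmax argmax, ties broken
by category order. The network is implemented directly in numpy (forward,
backward, Adam) so that dropout placement, initialization and seeding are
fully controlled and runs are deterministic.

Category schemes: categories with **more than** `min_appearances` (default
80) KO-words in the corpus form the retained set C*; KOs listed under
several categories are resolved by a configurable priority list; excluded
categories with more than `other_min_appearances` (default 50) KO-words
each contribute `other_sample_size` (default 20) randomly sampled KOs to an
"Other" class.

Reliability weighting: a prediction's weighted score is
raw softmax × AUPR of the predicted category (AUPR measured by
cross-validation). A prediction is *reliable* when the weighted score is at
least t = 0.9 **or** the raw score alone is at least t′ = 0.99. Two open
choices are resolved here: the weighting formula is taken as the product
(the minimal combination that stays in [0,1]), and the two thresholds are
combined with OR so that very confident predictions in low-AUPR categories
are not silently discarded. Both choices are configurable.

### Evaluation (`genesem.evaluation`)

Three cross-validation schemes:

* **naive k-fold over contigs** (k = 5): embeddings retrained per fold on
  the training contigs only; held-out tokens are scored through their
  retrained embedding, and tokens absent from a fold's training vocabulary
  are reported as unscorable rather than counted as errors;
* **leave-one-taxonomic-group-out**: one fold per taxon label, testing
  generalization across evolutionary distance;
* **leave-one-KO-out**: one fold per orthologous family, all subcluster
  words held out together; a single full-corpus embedding is reused and
  only the classifier is retrained per fold, which emulates encountering a
  family absent from the labeled training set.

Metrics are computed with scikit-learn: one-vs-rest precision–recall
curves, AUPR as average precision (the step-wise, non-interpolating
estimator), per-category F1, support-weighted F1 and a confusion matrix.
Folds are aggregated by pooling scores (micro-average); per-fold reports
are also returned so macro summaries can be formed either way.

The remote-homology baseline consumes a three-column table
(query, subject, E-value): same-KO "self hits" are discarded, hits with
E ≥ 10⁻³ are discarded (strict), each query takes the category of its
minimum-E-value surviving subject (E-value ties broken by subject token
order), and queries with nothing left are labeled "no hit".

### Rarefaction (`genesem.rarefaction`)

For a category c with predicted families P_c and per-family gene counts
W_c^p, the curve reports the mean number of distinct families in n genes
drawn uniformly **without replacement** from the category's gene multiset,
with 2.5/97.5 percentile bootstrap confidence intervals over 10,000
replicates (the without-replacement choice makes n = |G_c| recover |P_c|
exactly and admits the hypergeometric closed form
E[P_c^n] = Σ_p [1 − C(N−W_p, n)/C(N, n)], which the tests use as an oracle;
with-replacement sampling is available behind a flag). The size grid is
logarithmic, 20 points per decade over [10³, 10⁶], clipped to the pool.
`discovery_slope` summarizes saturation as the relative rise of the mean
curve over its final decade: ~0 for a plateaued category, approaching 0.9
for the identity curve where every gene is a new family.

### System detection (`genesem.systems`)

Reliable predicted words of one category with corpus count strictly above
`min_count` (default 1000, which presumes a corpus of hundreds of millions
of genes; synthetic tests scale it to their corpus) form the columns of a
binary contig × word incidence matrix. Pairwise Pearson correlation of the
binary columns (the phi coefficient) is thresholded into a graph; connected
components of size ≥ 3 are reported as candidate systems ranked by mean
within-cluster correlation, each with supporting contigs (those carrying at
least two members). Component semantics mean the reported minimum pairwise
correlation can fall below the threshold for chain-shaped clusters; the
threshold is guaranteed only along a spanning path. Constant
(all-zero/all-one) columns have undefined phi and are dropped with a
warning. Detection is fully deterministic.

## The synthetic generator (`genesem.synthetic`)

The generator emulates the statistical structure the method relies on,
entirely at the token level:

* background families drawn i.i.d. per gene from a Zipf law
  (exponent 1.2 by default — a long-tailed family-size distribution);
* planted "systems": blocks of 3–10 tokens inserted contiguously (operon
  style) into a configurable fraction of contigs, with optional per-member
  dropout and an option to scatter members instead;
* contig lengths of 1 kbp per gene, 15–40 genes per contig by default;
* taxonomy-group labels drawn per contig from configured proportions;
* a configurable fraction of system members relabeled into the
  `hypo.clst.*` namespace, so "predict the function of unannotated genes"
  is testable against known truth;
* a companion hit-table generator that gives a chosen fraction of annotated
  queries one correct-category, different-KO best hit, emulating the
  sensitivity ceiling of sequence search.

What it deliberately does not model: real taxonomic composition (groups are
exchangeable labels, systems are group-invariant), nucleotide or protein
sequences, strand and intergenic distance, annotation noise (every token
label is correct), shared genes between systems, and family-abundance
correlations. Passing tests therefore demonstrate that each algorithm
recovers the structure it targets when that structure is present as
modeled — not that real corpora satisfy the model.

## Numerical and design choices

* Vocabulary order is count-descending, token-id ascending; all ranking
  ties (nearest neighbors, analogies, argmax) are broken by this or by
  category order, so every output is deterministic.
* Cosine similarity against a zero vector is defined as 0.
* Sigmoid arguments are clipped at ±30 in the training kernel; losses use a
  1e-12 floor inside logarithms.
* Classifier weights are He-initialized; dropout uses inverted scaling.
* One global seed derives every per-stage seed as the first four bytes of
  sha256("<seed>:<stage>") modulo 2³¹, so a single integer reproduces an
  entire pipeline run; the pipeline caches each stage under a content hash
  of its parameters and input files and skips unchanged stages on rerun.
* Degenerate inputs fail early with typed errors: vocabularies below two
  tokens cannot be trained; single-category schemes cannot be fit; empty
  rarefaction pools are rejected; an empty incidence matrix is a warning,
  not an error.

## Problem sizes used in tests

Synthetic runs use 120–5000 contigs, vocabularies of a few hundred
families, embedding dimension 12–64, and 50–2000 bootstrap replicates in
unit tests (10,000 where the rarefaction closed form is checked). These
sizes were chosen so the full statistical structure is present while each
check completes in seconds.

## Known limitations

* SGNS training is single-threaded; corpus-scale (10⁸-gene) training would
  need a parallel kernel and the determinism guarantee would then hold only
  per-thread-count.
* Leave-one-KO-out retrains one classifier per KO; at thousands of KOs this
  is hours of compute and is intended for subsampled family sets at desk
  scale.
* The candidate-system extractor is the minimal automated counterpart of
  what is in practice a manual review step; thresholded connected
  components can chain distinct but overlapping systems, which is why the
  per-candidate correlation summaries are reported.
* Real-data effects absent from the generator (annotation errors,
  horizontally transferred partial operons, taxon-specific family usage)
  are untested by construction.
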