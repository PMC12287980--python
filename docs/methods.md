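# Methods

## Model

`adrscore` treats drug–side-effect prediction as bipartite link prediction
from node embeddings. The inputs are a deduplicated relation table (pairs of
drug and side-effect terms), and one embedding vector per term on each axis.
Vocabularies are induced from the observed pairs and sorted lexicographically,
so every derived matrix is reproducible across runs and platforms; indices are
0-based internally and user-facing output always reports terms.

For each candidate cell (α, β) the two factors are

* `sim_x(α, β)` — the maximum similarity of drug α to the drugs known for
  side effect β, excluding α itself;
* `sim_y(α, β)` — the maximum similarity of side effect β to the side effects
  known for drug α, excluding β itself;

and the relation score is their product. The underlying assumption is purely
analogical: similar drugs share side-effect profiles, and similar side effects
share causative drugs. The product demands support from *both* directions,
which is what makes it robust to one noisy axis (see the ablation tests).

Key conventions, chosen where the method definition is silent:

* **Empty related set after exclusion.** A side effect known for exactly one
  drug, scored against that drug (or the symmetric case), has no evidence left
  after leave-one-out. The factor is set to 0 and the cell is flagged in an
  explicit mask (`empty_x_mask` / `empty_y_mask`). Zero encodes "no evidence"
  without inventing a prior; the mask lets evaluation either keep such cells
  as score-0 negatives (the default, so every cell of the matrix is scored) or
  drop them (`drop_masked=True`).
* **Negative similarities are not clamped.** Under cosine, factors lie in
  [−1, 1] and the product of two negative factors can be positive. This is
  rare with real biomedical vectors and clamping would silently distort
  metric comparisons.
* **Ties in rankings** are broken by (drug term, side-effect term)
  lexicographic order, so top-k lists are deterministic.

## Similarity metrics

Cosine is the primary metric. For comparison experiments the package also
computes Euclidean and Manhattan distances (exposed as *negated* distances:
negation is the parameter-free order-preserving conversion, and only the
ordering matters for ROC analysis — the numeric threshold is then
metric-specific and reported as-is), the raw dot product, and a generalized
(Ruzicka) Jaccard `Σ min(a_i, b_i) / Σ max(a_i, b_i)`. Set-style Jaccard is
undefined on dense real vectors, so the continuous generalization is used; it
requires nonnegative components and raises otherwise, with an explicit
`jaccard_min_shift` flag that subtracts the global component minimum rather
than silently inventing a binarization. All similarity matrices are full
squares including self-pairs; exclusion happens at scoring time.

## Embeddings

The exchange format is the word2vec text dialect, extended to multi-word
terms by treating the last `dim` whitespace tokens of a line as the vector.
Files are written with 17 significant digits so doubles round-trip exactly —
this is what makes the staged CLI byte-identical to the one-shot pipeline.
Missing vocabulary terms raise by default (silent zero vectors would corrupt
similarity ranks); `skip` and `zero` policies are available and logged.

An optional contextual-encoder backend embeds each term independently as its
own sequence, mean-pooling final-hidden-layer token vectors excluding special
tokens (mean pooling is the standard context-free term-embedding choice and is
symmetric in token order; a `first_token` alternative is provided, and only
the final hidden layer is implemented). The backend refuses to run when the
encoder stack is not installed locally, pointing users at the file loader, so
no part of the pipeline ever requires network access.

## Evaluation

All cells are pooled into one score vector; a cell is a positive iff the pair
is in the known relation table. This is deliberately in-sample — the same
adjacency builds the related sets and supplies the labels — and is sound only
because leave-one-out exclusion removes each pair's self-evidence; a held-out
mode (mask a fraction of known pairs, score with the rest, evaluate
masked-vs-unknown) is provided as the stricter alternative.

The ROC curve is built over the unique score values with the strict
`score > t` convention, plus a final predict-everything point, so it runs from
(0, 0) to (1, 1). The trapezoidal area over this tie-grouped curve is
mathematically identical to the tie-corrected Mann–Whitney rank AUC; both are
computed and cross-checked to 1e-9 at every call, and the operating threshold
maximizes TPR − FPR (smallest qualifying threshold on ties).

## External validation

Predictions at the active threshold are cross-tabulated against an external
relation extract restricted to the score matrix's vocabularies. Because
unknown pairs dominate, each repeat uses all externally known pairs plus an
equal-size uniform sample (without replacement) of unknown pairs; the
two-sided Fisher exact test and the cross-product odds ratio
(Haldane–Anscombe +0.5 on all cells iff any cell is zero) are computed per
repeat and aggregated. The mean over repeats is the headline statistic; the
median is also reported because per-repeat odds ratios are right-skewed.
Whether one should average p-values or pool the tables is genuinely
ambiguous; per-repeat values are stored so either summary can be formed.
Repeats draw from independent child streams of one seeded generator
(`SeedSequence.spawn`), making results bit-reproducible.

## Synthetic benchmark

The planted-factor generator stands in for a curated relation database plus
pretrained embeddings. Each drug and side effect gets a latent factor uniform
on {1..K}; relations are Bernoulli(p_in) within factor and Bernoulli(p_out)
across; embeddings are the factor's orthonormal centroid (rows of the
identity, so zero-noise geometry is exact) plus isotropic Gaussian noise with
per-component standard deviation `noise_sd`. Isolated entities are resampled
(and logged) so induced vocabularies cover everyone. The defaults — 60 drugs,
120 side effects, K = 6, dim = 32, p_in = 0.6, p_out = 0.02, noise_sd = 0.3,
seed 7 — are the package's reference benchmark and are kept small enough that
the full pipeline runs in well under a second.

What the generator emulates: block-structured relation tables, embedding
geometry correlated with the relation structure, and an external source
enriched for true signals (`generate_external_extract` samples cells with
probability ∝ enrichment^rank-quantile of the score; enrichment 1 is the
null). What it does not emulate: term-frequency effects, MedDRA granularity
and synonym structure, correlated reporting biases, or the heavy-tailed
degree distributions of real pharmacovigilance data — so passing benchmarks
demonstrates correct mechanics and sensible statistical behaviour, not
clinical performance.

A structural note on the benchmark's ceiling: the in-sample evaluation counts
cross-factor background relations (rate `p_out`) as positives, and these carry
no recoverable signal by construction. At the defaults roughly 14% of
positives are background, which caps the expected in-sample AUC near 0.89
even with noise-free embeddings; the measured defaults AUC is ≈ 0.86, rising
toward that ceiling as `noise_sd → 0` and falling monotonically as noise
grows (chance level when `p_in = p_out`). Setting `p_out = 0` removes the cap
entirely: every unmasked within-factor pair then outranks every cross-factor
pair exactly.

## Numerical and reproducibility choices

* Cosine values are clipped to [−1, 1] and diagonals pinned (1 for cosine,
  0 for negated distances) to suppress float round-off; matrices are
  symmetrized as `(S + Sᵀ)/2`.
* Vectorized scoring uses a −inf diagonal on the similarity matrix to
  implement self-exclusion, and is tested against a brute-force
  quadruple-loop oracle to 1e-12.
* All score/vector exports use `%.17g` and are parsed with round-trip float
  precision, so staged and one-shot runs agree byte-for-byte.
* Every stochastic routine takes an explicit seed; pipelines log all
  configuration values, and artifacts are written atomically (temp file +
  rename).

## Limitations

* In-sample AUC, as in the evaluation above, is optimistic relative to the
  held-out mode; both are provided.
* Term normalization (lowercase + trim, plus an optional user-supplied
  synonym mapping file) is a desk-scale proxy for identifier-level
  standardization against compound and terminology databases.
* The Jaccard metric on real-valued embeddings depends on the chosen
  nonnegativity handling; comparisons across metrics should note the
  `jaccard_min_shift` setting.
* Expert curation steps that follow ranking in practice (e.g. excluding drug
  classes used despite known side effects) are out of scope beyond a
  user-supplied exclusion of candidates from the ranked list.
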