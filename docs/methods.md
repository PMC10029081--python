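# Methods

## Data model

A patient record is a pair (labels, visits): a set of static label codes
(demographic bins, chronic phenotypes) and an ordered list of visits, each
holding a set of medical codes, optional lab values (lab id → real), and
the gap in days since the previous visit. For modeling, a record becomes a
binary matrix of `max_T + 3` rows over the vocabulary `C`: start row,
label row, `T` visit rows, end row, zero padding. A row-validity mask
tracks the `T + 3` real rows; padded rows never enter the loss or any
statistic. The gap code on a visit row describes the gap *preceding* that
visit, so the first visit carries none.

The vocabulary fixes the column order: medical codes in a seeded random
permutation (ordering has no modeling effect, so reproducibility wins and
the seed is stored with the vocabulary), then label codes, bucket codes,
and the start/end specials.

### Bucketing

Continuous variables are discretized into half-open buckets
`[b_k, b_{k+1})`, the last bucket closed on the right so the configured
range tiles exactly; indices are 0-based. Encoding maps a value to its
bucket code; decoding draws uniformly within the bucket bounds. Strategies:
`uniform` (equal width), `quantile` (equal frequency, reducing the bucket
count with a warning when the sample has too few distinct values), and
`explicit` (clinically chosen bounds). Out-of-range values fail at encode
time by default; a clamp-to-extreme-bucket option exists for messy inputs
and is used by the simulator pipeline, whose value distributions are
truncated to the bucket range anyway.

## The generator

The record probability factorizes first over rows, then over codes within
a row. Two modules realize the factorization:

**Visit level.** Rows are embedded by a code-embedding matrix (|C|×n_emb)
plus learned positional embeddings (one per row slot, sized to the full
`max_T + 3` input rows), then passed through `M` pre-norm transformer
decoder blocks: causally masked multi-head self-attention and a GELU
feed-forward of width `4·n_emb`, both with residual connections, followed
by a final layer norm. Row `t` of the output depends only on input rows
≤ `t`; this is the property the perturbation tests verify.

**Code level.** History row `t` is concatenated with input row `t+1`
(the offset) giving vectors of width `n_emb + |C|`, which pass through `N`
masked linear layers (ReLU between layers, sigmoid at the end; the first
`n_emb` outputs of the final layer are discarded). The weight masks are
upper-triangular. The diagonal is kept on layers `1..N−1` and **zeroed
within the code block on layer N**: with a non-strict diagonal at the
output layer, the output for code `i` would see its own input bit — a
leak. History (embedding-portion) inputs sit above the code block in the
triangle and therefore always reach every code output. The masks are
checked before every forward pass and after training.

**Coarse ablation.** `coarse=True` replaces the code-level module with a
single linear map + sigmoid from the history alone: each code probability
conditions on previous visits but not on previous codes of the same visit.

**Loss and likelihood.** Training minimizes mean binary cross-entropy over
all code positions of valid non-start target rows (label and end rows
included; the start row is never predicted; padding excluded).
The record log-likelihood sums Bernoulli log-probabilities of every code
bit — present and absent — over the same rows; per-code perplexity is
`exp(−Σ log P / N)` with `N` the count of present (1) bits over those rows.
Counting label/end bits in `N` keeps the normalizer consistent with the
likelihood it normalizes; `visit_rows_only=True` restricts `N` to clinical
rows for sensitivity analyses.

**Numerical policy.** All arithmetic is float64. Probabilities are clipped
to `[ε, 1−ε]`, ε = 1e-12, before any logarithm. Adam uses β = (0.9,
0.999), eps 1e-8; parameters initialize as N(0, 0.02²) with zero biases
and masked entries zeroed. Dropout defaults to 0.1 inside the decoder
blocks and 0 in the masked-linear stack. Training aborts with diagnostics
on a non-finite loss. Gradients are hand-derived; the test suite checks
them against central finite differences for every parameter group.

## Generation

Rows are sampled in order; within a row, codes are sampled one Bernoulli
at a time in vocabulary order, each conditioned on the completed prefix
and the bits already drawn in the row (for `N = 2` this uses an
incremental update of the first masked layer's pre-activations, so a full
row costs one pass per code over a single matrix column). Temperature
scales logits before the sigmoid (default 1.0).

Plumbing choices the probabilistic model itself does not determine:

* **Stopping** — generation ends at the first sampled row containing the
  end code; that row becomes a clean end row (other bits zeroed). At the
  visit capacity an end row is forced.
* **Row restrictions** — the label row samples only label positions;
  visit rows sample medical, bucket and end positions. This guarantees
  every generated matrix satisfies the structural invariants and decodes.
* **Conditioning** — a supplied label set is written into row 1 verbatim
  (and pinned bits participate in the intra-row conditioning of later
  draws); partial pinning is supported through the lower-level sampler.
* **Bucket repair** — independent Bernoulli draws can switch on several
  buckets of one variable in a row; the repair step keeps the
  highest-probability bucket and drops the rest.
* **Reproducibility** — each record owns a generator spawned from the
  cohort seed and consumes exactly one uniform vector per sampled row,
  so output is independent of internal batching.

## Fidelity metrics

Probability profiles count medical and bucket codes only (labels and
specials are reported separately via label prevalences). At record level
each map is "fraction of records containing …" (a code; an unordered pair
in one visit; an ordered pair in consecutive visits); at visit level the
denominators are visits and visit transitions. Profiles are compared by
squared Pearson correlation over the **union** of keys (absent key = 0);
restricting to the intersection would inflate scores. R² therefore
measures correlation, not `y = x` agreement. Degenerate inputs (fewer
than two keys or zero variance) return 0 with a warning. Aggregate
statistics use population (ddof=0) standard deviations.

## Privacy audit

All distance-based attacks use record fingerprints: |C|-length presence
vectors over labels + all visits (specials excluded). The paper-standard
Hamming distance between such vectors is computed exactly via
`|a| + |b| − 2 a·b`.

* **Membership (dataset)** — score attack records by minimum distance to
  the synthetic cohort; label the lowest-distance half as members; ties
  break by stable record order (members listed first). **Membership
  (model)** — same rule with raw log-likelihood scores; no length
  normalization (longer records score lower; documented confound).
* **Attribute inference** — conditional attributes = label codes + the
  `k` most prevalent medical codes (prevalence from the target/training
  cohort); nearest reference record by Hamming distance on the
  conditional sub-vector (ties → lowest index) donates its sensitive bits;
  micro-averaged F1. Agreement counts both shared 1s and shared 0s; an
  alternative reading (shared 1s only) exists but is not implemented.
* **NNAA** — subsets of size `n` from training/synthetic/evaluation
  cohorts; four indicator means with strict `>` and self-exclusion for
  within-set nearest neighbors; risk = `aa_es − aa_ts`. Equal distances
  count as "not greater". The accepted-risk threshold in the literature
  is 0.03.

## Ground-truth simulator

The simulator stands in for real corpora, which are proprietary or
credentialed. Its "small" preset: 120 medical codes, 4 labels (prevalences
0.35/0.25/0.15/0.08), 6 condition modules of 10 codes each (five triggered
by single labels or the {L0, L1} pair, one always active at half
emission), per-code heavy-tailed background rates `10^U(−2.8, −1.4)`,
negative-binomial visit counts (r=2, p=0.35) truncated to [1, 12],
log-normal gaps (μ=3.2 ≈ 25 days, σ=0.7) whose location falls with visit
index (slope 0.25 on log1p(t) — later visits in long records have shorter
gaps), and two labs (heart-rate-like: mean 80, sd 12, +8 under L1;
glucose-like: mean 100, sd 20, +15 under L0), truncated to their bucket
ranges. Module codes persist: once a code has appeared it recurs with
probability 0.65 per subsequent visit — the chronic-repetition structure
a sequence model must capture. These values were fixed once as a
realistic desk-scale analogue of outpatient claims structure (a few
visits per record, a handful of codes per visit, label-linked disease
clusters).

An independent oracle sampler (explicit per-visit probability vectors, no
shared code path with the main sampler) provides Monte-Carlo reference
profiles, plus closed-form per-visit unigram probabilities for module-free
configurations; tests require the two implementations to agree.

**What passing tests do not show:** the simulator has no ICD hierarchy,
no code rarity beyond the configured tail, no measurement error, no
informative missingness, and its dimensionality (~150 columns) is two
orders of magnitude below real claims vocabularies. Results here validate
the machinery — factorization, sampling, metrics, attacks — not clinical
realism or scalability of the training recipe.

## Reference experiment sizes

The acceptance pipeline uses 2,000 training records, the reduced generator
(M=2 blocks, N=2 masked layers, n_emb=64, 4 heads), the standard recipe
(Adam 1e-4, batch 48, 50 epochs), 2,000 generated records, a 1,000-record
held-out cohort, NNAA subsets of n=500 averaged over 5 draws, and a
1,000+1,000 membership attack set. These sizes keep a full run to a few
minutes on one CPU while leaving Monte-Carlo error well inside the
evaluation bands.

## Known limitations

* Training is plain-numpy on CPU; it is meant for desk-scale studies, not
  the 12-block, ~10,000-code regime.
* The fine sampler's per-code loop makes generation cost linear in |C|
  per row; acceptable at desk scale.
* Bucket repair slightly biases multi-bucket rows toward high-probability
  buckets; the event is rare for a trained model.
* The membership model attack uses raw log-probabilities, which are
  record-length-confounded by construction.
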