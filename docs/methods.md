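# Methods

This note records the model, the defaults and the numerical choices behind
`concernminer`, and what the synthetic-data experiments do and do not show.

## The pipeline model

The analysis treats a response as a bag of words. A weighted term–document
matrix `A` (terms × documents) is built from a background corpus *plus the
meaningful responses themselves*, so response-specific usage enters the
space. Weighting is log-entropy, the standard LSA scheme:

```
a_td = log(1 + tf_td) · (1 − H_t / log D),   H_t = −Σ_d p_td log p_td,
p_td = tf_td / gf_t
```

A term spread evenly over all documents gets global weight 0; a term
concentrated in few documents gets weight near 1. Raw counts are retained as
an option because several exactness oracles (fold-in consistency, column
sums) are sharpest there. No stop list and no stemming are applied at this
stage: removing whole contentless responses, not common words, is the
filtering model, and surface forms are kept so that context disambiguates
polysemy ("hurt my back" vs "we moved back").

Truncated SVD gives `A ≈ U_k Σ_k V_kᵀ`, the best rank-k approximation in
Frobenius norm. Defaults: k = 300 at full scale; desk-scale runs and tests
use k in 20–50, which is ample for a dozen planted topics. Up to
`min(T, D) = 3000` the factorization uses a dense LAPACK SVD (exact,
deterministic); above that, Lanczos `svds` with a fixed start vector. Sign
ambiguity is resolved per singular pair by making the largest-magnitude
entry of each term-vector column positive, so serialized spaces round-trip
bit-identically. Trailing singular values below
`max(T, D) · eps · σ_1` are dropped and k reduced, keeping the spectrum
strictly positive.

Conventions: term–term cosines use scaled term vectors (rows of `U_k Σ_k`);
a response with weighted count vector `a` folds in as `Σ_k⁻¹ U_kᵀ a` (which
reproduces a training document's row of `V_k` exactly); response–medoid
similarity compares the fold-in vector with the medoid's scaled term vector.
The cosine of a zero vector is defined as 0, so a fully out-of-vocabulary
response is never assigned anywhere.

## Null filtering

A response is meaningless iff its normalized form (lowercase, punctuation
and digits stripped, whitespace collapsed) is empty or an exact member of
the pattern bank. Exact matching — not substring or regex — reproduces the
entire-response-removal semantics and biases errors toward calling a
response meaningful, the safer direction for downstream analysis. The
shipped bank has ~60 entries; production analyses of this kind accumulate
several hundred patterns, so user-supplied pattern files (one per line, `#`
comments) and a human-override file (response id → forced label) are
supported. Participants whose response is filtered out are treated as
non-responders in the propensity model.

## Term clustering

Clustering terms are those occurring strictly more than `min_freq = 70`
times (token count, not document frequency) across meaningful responses,
minus a ~150-word function-word stop list that exists only for this
selection step. Dissimilarity is `1 − cosine` over scaled term vectors,
giving entries in [0, 2].

PAM is implemented from the distance matrix alone, as in the classic
BUILD + SWAP formulation: BUILD seeds the first medoid at the point of
minimum total distance and greedily adds the point with the largest cost
reduction; SWAP evaluates every (medoid, non-medoid) exchange and applies
the best strictly improving one until none exists. All ties break to the
lowest index, so the algorithm is fully deterministic. A strict-improvement
threshold of 1e-12 guards against float cycling. PAM is a heuristic: on all
tiny instances we can enumerate it is within 5% of the exhaustive optimum
(and exact on well-separated data), which is the guarantee the tests
assert. Default cluster count is 20 at full scale; the synthetic default is
12, one per planted topic. Clusters judged to lack semantic meaning can be
listed in an exclusion file: they are dropped from concern tables but their
responses remain in the demographic analyses.

## Assignment and tabulation

Membership is binary and multi-label: a response joins every cluster whose
medoid cosine strictly exceeds the threshold (default 0.2). Concern-table
percentages use the table's total assignment count as denominator (the
convention under which the published per-cluster counts sum exactly to the
printed table n), with per-stratum percentages over stratum assignment
totals; the per-response denominator is also derivable from the emitted
counts. All printed percentages are one decimal, rounded half-up — Python's
bankers' rounding would disagree on exact ties, hence a decimal-based
helper.

## Propensity model and agreement

The responder model is a single maximum-likelihood logistic regression with
all covariates entered simultaneously (statsmodels, Newton, relative
log-likelihood tolerance 1e-8, ≤100 iterations), fitted per panel/survey
stratum when strata are present. AORs are `exp(β)` with Wald 95% intervals
`exp(β ± 1.96·SE)` — the standard epidemiologic convention. Complete cases
only, except self-rated general health, which keeps an explicit Missing
level. Rank deficiency and separation raise errors naming the offending
columns rather than returning unstable estimates. Reference levels are
male, born before 1960, high school or less, married, white non-Hispanic,
no deployment, enlisted, Reserve/Guard, Air Force, "Others" occupation, and
very good/excellent health.

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from the raters'
marginal products; the degenerate case of two identical constant raters is
defined as κ = 1. Per-category agreement is computed one-vs-rest.
Landis–Koch bands are attached as annotations only.

## The synthetic cohort

The generator defines the study conditions and is itself tested code.

* **Topics.** Twelve areas of concern (illness/injury, exposure, exercise,
  back pain, deployment, arm symptoms, mental health, weight, vaccination,
  anxiety, surgery, plus a diffuse general-health topic). Each topic has six
  exclusive high-weight seed terms carrying 60% of its mass and twelve
  lower-weight terms, some shared across topics (pain, chronic, anxiety …)
  so clusters are not trivially block-diagonal. Background filler is ~100
  function words with Zipf weights.
* **Documents.** Bag-of-words; 70% of tokens from the document's topic(s),
  30% filler. A document carries one topic with probability 0.8, otherwise
  two. Lengths are negative-binomial: mean 60 (dispersion 10, floor 10) for
  background documents, mean 15 (dispersion 5, floor 3) for responses —
  short free-text answers. Word order is random because LSA is
  order-blind.
* **Null responses.** With probability `null_rate` (default 0.546) a
  response is a casing/punctuation variant that normalizes into the shipped
  pattern bank.
* **Participants.** Covariate margins follow a large military cohort
  (e.g. 26.8% female, 57% active duty, 7.7% fair/poor health); response
  propensity is logistic with log-odds patterned on the observed adjusted
  odds of open-text response, with fair/poor health fixed at log 3 and an
  intercept of −0.86 chosen to give a ~38% marginal response rate.
* **Seeding.** One integer seed; each operation draws from its own
  `SeedSequence` substream, so regenerating one artifact never perturbs
  another and equal seeds give byte-identical outputs.

**What passing recovery tests show — and what they do not.** At the default
experiment scale (5,000 documents, ~26,500 participants, ~10,000 responses,
k = 50, 12 clusters, threshold 0.2) the pipeline assigns ≥ 90% of
single-topic responses to the cluster carrying their topic's seed terms and
reaches ARI ≈ 0.87 against planted labels, and the propensity refit covers
the planted coefficients at the nominal Wald rate. This validates the
machinery end to end, but the synthetic text is far cleaner than real
responses: tokens are drawn from known pools, there are no misspellings,
no rare topics, no correlated covariates, and topic separation is
configured. Real-data performance (e.g. the share of responses a 0.2
threshold assigns) cannot be inferred from these numbers.

**Statistical test design.** Envelope tests on generator output use exact
moments derived under the generative model — for seed-term counts that means
a compound (law-of-total-variance) standard deviation over document length
and topic membership, not the naive binomial SD, which understates the
variance of topic-clustered counts. Families of simultaneous checks (~34
covariate levels, ~72 seed terms) use a family-wise |z| ≤ 4 bound;
single-quantity checks use 3 SE.

## Known limitations

* k is a configuration constant; no dimension-selection criterion is
  implemented.
* PAM is quadratic in memory in the number of clustering terms; fine for
  ~1,000 terms, not for 100,000.
* The meaningfulness filter is purely lexical; a paraphrased null response
  ("nothing springs to mind") not in the bank is kept.
* One response per responding participant; repeated measures within
  participants across panels are generated independently.
* Published per-panel percentages in the motivating analysis contain three
  cells inconsistent with their own printed counts; the tabulation here
  reproduces count-consistent values (see the test suite's frozen table).
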