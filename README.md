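# concernminer

Open-ended survey questions ("Do you have any concerns about your health not
covered in this survey?") produce free text that large epidemiologic cohorts
cannot afford to hand-code. `concernminer` implements a latent semantic
analysis (LSA) pipeline for mining such responses at scale, together with the
statistical layer epidemiologists wrap around it:

1. **Semantic space** — a background corpus is turned into a weighted
   term–document matrix (log-entropy weighting, no stop list, no stemming)
   and factored by truncated SVD, `A ≈ U_k Σ_k V_kᵀ` (full-scale default
   k = 300). Terms live in rows of `U_k Σ_k`; a new response folds in as
   `Σ_k⁻¹ U_kᵀ a`.
2. **Null filtering** — responses that convey no information ("No", "N/A",
   "I have nothing to say") are removed whole by exact match against a
   normalized pattern bank; errors deliberately bias toward keeping
   responses. Participants with only meaningless responses count as
   non-responders downstream.
3. **Term clustering** — words occurring more than 70 times in meaningful
   responses (minus a function-word stop list) are clustered on
   1 − cosine dissimilarity with PAM (partitioning around medoids,
   BUILD + SWAP, deterministic; default 20 clusters). Each cluster is
   represented by its medoid and labeled by a human as an *area of concern*.
4. **Assignment** — a meaningful response joins every cluster whose medoid
   cosine exceeds 0.2 (strictly); clusters are ranked by membership and
   tabulated per survey panel with one-decimal half-up percentages.
5. **Responder propensity** — multivariable logistic regression of "provided
   a meaningful open-ended response" on demographic and service covariates,
   reported as adjusted odds ratios (AOR) with 95% Wald intervals, plus
   Cohen's κ for LSA-versus-human agreement checks.

Because the motivating cohort's corpus and personnel data are proprietary,
the package ships a **synthetic-cohort generator** with known ground truth:
topic-structured documents and responses (12 planted areas of concern), a
configurable meaningless-response share (default 54.6%), and covariates tied
to response propensity by planted log-odds (fair/poor self-rated health at
log 3). Every analysis stage is validated by recovering what was planted.

## Worked example

```python
from concernminer import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_docs=800, n_participants=3000,
                k=30, k_c=12, min_freq=20, out_dir="run1")
report = run_pipeline(cfg)
print(report["counts"])
print(report["percentages"])
```

prints

```
{'n_surveys': 3000, 'n_responses': 1099, 'n_meaningless': 601,
 'n_meaningful': 498, 'n_assigned': 481}
{'pct_any_response': 36.6, 'pct_meaningless_of_responses': 54.7,
 'pct_meaningful_of_responses': 45.3, 'pct_meaningful_of_surveys': 16.6,
 'pct_assigned_of_meaningful': 96.6}
```

— of 3,000 simulated participants, 1,099 (36.6%) wrote something in the
open-ended field; 601 of those responses (54.7%) were contentless and
removed whole; 481 of the 498 meaningful responses (96.6%) landed in at
least one of the 12 term clusters. The run directory holds every
intermediate artifact: the corpus, vocabulary, term–document matrix (Matrix
Market), the semantic space, the clustering with per-cluster term summaries
for labeling, the response–cluster assignment table, the area-of-concern
table, and the AOR table. In `run1/aor.tsv` the planted health gradient is
visible immediately — participants reporting fair/poor general health have
AOR 2.20 (95% CI 1.59–3.04) for providing a meaningful response versus the
very-good/excellent reference at this small n (the planted propensity acts
on responding at all; the meaningful-response odds ratio is attenuated by
the covariate-independent null filter).

The same pipeline is scriptable from the shell:

```
concernminer run --config run.yaml
concernminer simulate --n-docs 5000 --n-participants 26500 --seed 1 --out-dir run2
concernminer cluster --run-dir run2 --min-freq 70 --k 20
```

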