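# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and what the synthetic data do and do not
establish.

## Phrase representation and similarity

A phrase is an adjective–noun pair. Its vector representation is the
**component-wise sum** of the two word vectors, with no normalization
before summing; summation is a standard, empirically competitive
aggregation for short phrases and keeps the representation linear in
its constituents. Phrase similarity is the cosine of the angle between
compound vectors. Cosine is scale-invariant, so the magnitude jitter in
word2vec-style embeddings does not affect any downstream decision.

Token matching is exact and case-sensitive: for morphologically rich
languages case-folding is lossy, and silent normalization would make
similarity values irreproducible against the source embedding.
Vectors with L2 norm below 1e−12 are rejected at load time so the
cosine precondition (non-zero inputs) holds globally thereafter.

## Lexical filtering

Inclusion bounds (defaults): corpus frequency within the 35–90
percentile band, computed **within part of speech** by the nearest-rank
method with inclusive endpoints; 7–13 characters; 2–6 syllables
(syllable counts are taken from the lexicon table — syllabification is
language-specific and out of scope); at most 5 phonological neighbors.

A *phonological neighbor* is defined as a token of equal length at
Hamming distance exactly 1 (one substituted character). Reading
"sharing all but one character" as substitution-only is the narrow
interpretation; insertion/deletion neighbors are not counted.
Neighborhoods are counted against the full filtered token set before
any removal, so the filter is order-independent.

## Triplet and foil construction

The original norming of such stimulus sets includes human judgment
(picking the "most meaningful" phrases, vetoing pragmatically odd
combinations, re-assigning adjectives between triplets). The package
replaces that layer with deterministic rules so a build is exactly
reproducible from its seed:

* the meaningfulness proxy is the word-level cosine between adjective
  and noun: the target adjective is chosen from the top-10 ranked
  candidates;
* the **close lure** is the candidate whose compound-phrase cosine with
  the target phrase is maximal within [0.70, 1); the **distant lure**
  is the candidate closest to the midpoint of [0.40, 0.65] (the
  midpoint rule keeps distant lures away from both band edges);
* conflicts are resolved greedily: an adjective, once used in any
  phrase, is never reused, so a full build uses 3·n_triplets + n_foils
  distinct adjectives (425 under the default 100 + 125 build);
* foil adjectives must stay below 0.70 word-level cosine against
  *every* target adjective; each foil noun is paired greedily with the
  most similar admissible adjective, keeping foils plausible phrases
  while semantically unrelated to the targets.

The distant band's upper edge is 0.65 rather than 0.70, leaving a
buffer (0.65, 0.70) in which a phrase is neither kind of lure; both
edges are configurable. All ties break by descending similarity, then
lexicographic token order.

## Counterbalanced rotation and trial ordering

Per participant, the recognition list comprises 50 exact repeats, 25
close lures, 25 distant lures and 25 foils; since 50 + 25 + 25 equals
the 100-triplet pool, each participant *partitions* the triplet pool
across the three triplet-derived conditions. The rotation cuts the pool
into blocks of gcd(50, 25, 25) = 25 and rotates a fixed block-role
pattern (target, target, close, distant) by one block per participant;
foils rotate as 5 blocks of 25. Over each cycle of 4 (and 5)
participants every block serves every role its quota of times, so with
40 participants each triplet is a target exactly 20 times and a
close/distant lure source exactly 10 times, and each foil appears
exactly 8 times. Exact equalization therefore requires the participant
count to be a multiple of both cycle lengths (lcm = 20 under the
defaults); violations raise a design error naming the failing
condition. A single participant can never equalize exposures under the
partition structure, and is rejected for that reason.

Encoding lists present the target phrase of every assigned triplet
(100) plus 100 fillers. Where fillers come from is not dictated by the
design; the package draws them from pool items the participant will
*not* see at recognition — unassigned-triplet targets first, then
foil-pool phrases outside the participant's foil block (exactly 100
such phrases under the defaults). This keeps the phrase universe closed
and preserves the two provenance invariants: every lure's noun was
encoded as a target, and no recognition-foil noun was pre-exposed.

Orderings obey a run-length constraint (default: at most 3 consecutive
trials of one condition, applied to both phases). The sampler is a
guarded greedy draw: at each position a label is drawn with probability
proportional to its remaining count, among labels that (a) do not
extend a maximal run and (b) leave every label c satisfying
`remaining_c ≤ max_run · (others_c + 1)` — the feasibility condition
for arranging the remainder without an over-long run. Any choice
maintaining the guard keeps the schedule completable, so the draw never
dead-ends; infeasible label compositions are detected up front. A
single-label list is exempt (there is no condition mixing to
constrain). Stimulus timing (fixation, stimulus, ISI, confidence
window) is metadata only and is not simulated.

Seeding: one global seed expands to per-participant substreams keyed by
participant id, so a participant's schedule does not depend on the
order in which schedules are generated.

## Generative response model

Each recognition decision arises from latent evidence
`e = η + ε, ε ~ N(0, 1)`, with linear predictor

```
η = β₀ + (β_sim + β_sim×age · old) · s + β_age · old + u_participant
```

where `s` is cosine similarity (targets 1.0; the similarity term is
absent for foils, which have no encoded baseline phrase to measure
distance from), `old` indicates the older age group, and
`u ~ N(0, σ_participant²)` is drawn once per participant. The response
is 'old' iff `e > 0`, except on lapse trials (probability `lapse`),
where a fair coin decides; hence
`P('old') = lapse/2 + (1−lapse)·Φ(η)`. Confidence (guessing / unsure /
sure) bins `|e|` against two thresholds; confidence is generated for
format completeness and not analyzed. Encoding-phase cover-task
responses are not simulated.

Default parameters:

| parameter | default | rationale |
|---|---|---|
| β_sim | ln 158.0 ≈ 5.06 | log of the exponentiated similarity estimate reported for this design in the verbal-aging literature |
| β_age | ln 3.67 ≈ 1.30 | same source: older adults respond 'old' more |
| β_sim×age | ln 0.25 ≈ −1.39 | same source: shallower similarity slope in older adults |
| β₀ (foil intercept) | −4.4 | chosen once so that, at the similarity levels the default build realizes (close ≈ 0.92, distant ≈ 0.53), condition means are ordered targets ≫ close > distant > foils, with the old group above the young on lures and slightly below on targets |
| σ_participant | 0.35 | moderate between-participant spread, ≈ 0.1 in response-probability units at mid-scale |
| lapse | 0.02 | small attention-failure rate keeping all response probabilities off 0/1 |
| confidence thresholds | (0.8, 2.0) | roughly thirds of the evidence distribution at mid-scale |

A single-index probit cannot match all four observed response levels of
a real cohort — exact repetition boosts target recognition beyond what
similarity alone predicts — so the preset privileges the qualitative
ordering over absolute levels (simulated foil rates are lower than
typically observed).

## Scoring

'Old' proportions are computed per participant and condition; trials
with no response are excluded from numerator and denominator. d′ for a
contrast is `Φ⁻¹(p_hit) − Φ⁻¹(p_fa)` after an explicit edge
correction: `clip` (default) bounds proportions to
[1/(2N), 1 − 1/(2N)] and only bites at 0 or 1; `loglinear` applies
(count + 0.5)/(N + 1) always. Which correction ran is recorded per
score, since the choice is consequential exactly in the
high-performance regime. A collapsed target-vs-lure d′ (close and
distant pooled) is provided for comparison with tasks that do not grade
lure similarity.

The LDI for three-response (old/similar/new) data is computed **as the
companion picture task prints it**: p('similar'|foil) −
p('similar'|lure). Note this is the negation of the more common
lure-minus-foil convention; the sign is kept so scores are directly
comparable with that task's output, and d′ and LDI are never
conflated.

## Inference

The response model is fitted as a **fixed-effects probit**: design
matrix (1, s, old, s·old) over target and lure trials, maximum
likelihood via iteratively reweighted least squares (Fisher scoring).
Each step is step-halved until the log-likelihood does not decrease, so
the LL trace is non-decreasing by construction. Convergence: relative
LL change < 1e−8 or 100 iterations. Standard errors come from the
inverse *observed* information at the optimum; CIs are Wald. Estimates
are also reported exponentiated (exp β > 1 raises the odds of 'old'),
matching the reporting scale of mixed-model analyses of this design.
Degenerate responses (all 'old'/'new') and diverging linear predictors
raise a separation error rather than returning garbage. Random effects
for participant, item and trial order are deliberately out of scope;
`probit_design_matrix` exposes the exact design so an external
mixed-model backend can be plugged in on identical data.

Mahalanobis screening computes squared distances against the sample
mean and covariance and excludes rows beyond the χ² quantile (default
0.95) with df = number of covariates unless overridden. When screening
a study sample the screen should run per age group, so group mean
differences are not mistaken for outliers; a helper does exactly that.
Near-singular covariances (condition number > 1e12) are rejected with a
pointer at collinear covariates.

Fisher's r-to-z comparison uses
`z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))` with a two-sided
normal p-value; sample sizes are explicit arguments (whole-group vs
post-exclusion n is the caller's decision).

## Synthetic-data generator

`generate_fixture_embedding` emulates two structural facts of real
word embeddings and lexica:

* **Clustered neighborhoods.** Cluster centroids are unit vectors drawn
  inside a random low-dimensional subspace (default 6 of 200
  dimensions), which spreads cross-cluster cosines over a wide range —
  like loosely related topics — instead of concentrating them near 0 as
  independent high-dimensional directions would; token vectors scatter
  around their centroid with spread 0.7 (within-cluster cosine ≈ 0.67).
  This combination populates both lure bands for every noun: close
  lures come from the noun's own neighborhood, distant lures from
  moderately related clusters. Defaults (700 nouns, 2200 adjectives)
  leave pool sizes after filtering comparable to a realistically
  pre-filtered norming lexicon, with ample slack for the 225-noun /
  425-adjective build.
* **Psycholinguistic marginals.** Frequencies are Zipf-distributed
  (exponent 1.1) with ranks shuffled within part of speech; tokens are
  pronounceable CV/CVC-syllable strings whose length and syllable
  counts are consistent by construction and deliberately spill outside
  the filter bounds, so the lexical filter has real work to do.

What the generator does **not** emulate: polysemy and part-of-speech
ambiguity, pragmatic fit (a phrase can be semantically close yet
unidiomatic), item-level response variance (random intercepts per
phrase), order/fatigue effects, and realistic foil base rates. Passing
tests therefore establish the correctness of the pipeline's arithmetic,
counterbalancing, calibration and estimator behavior under the stated
model — not that the stimulus builder would reproduce a human-curated
stimulus set from a real embedding.

## Calibration experiments

The calibration suite uses 80 participants × the default lists (8,000
target/lure trials per replicate), 100 seeded replicates:

* **Parameter recovery** simulates with `σ_participant = 0` and
  `lapse = 0` so the generator and the fitted fixed-effects probit
  coincide; both the similarity slope and the interaction must land
  within 3 estimated SEs of truth in ≥ 95/100 replicates. (With a
  nonzero lapse the fitted model is misspecified and the slope is
  attenuated — a model-mismatch effect, not an estimator defect.)
* **Null calibration** sets `β_sim = β_sim×age = 0`, keeps the default
  lapse (without it the default intercept leaves essentially no 'old'
  responses and the fit is degenerate), and requires the 95% Wald CI
  for the similarity coefficient to cover 0 in 93–97 of 100 replicates.
  The lapse shifts only the intercept under the null, so coverage of
  the similarity term remains nominal (measured ≈ 94.5% over 400
  replicates).

## Numerical and I/O notes

* Probit likelihoods use `log Φ` via scipy's `logcdf` (no catastrophic
  cancellation in the tails); Fisher weights are clipped away from
  0/1 probabilities at 1e−12.
* CSV/TSV reads of floating-point columns use round-trip float parsing;
  the default fast parser can be off by one ulp, which would break the
  byte-identical rerun guarantee.
* word2vec text files are written with `repr(float)` (shortest exact
  form), so write → read → write is byte-stable.
* Problem sizes in tests and the acceptance script (40- and
  80-participant designs, 100-replicate calibrations, ~10⁵-trial
  monotonicity checks) are the package's chosen defaults for the
  experiments they implement; the full test suite runs in well under a
  minute.

## Known limitations

* The fixed-effects probit understates uncertainty for cohorts with
  real participant heterogeneity (use the design-matrix hook with a
  mixed-model backend for such data).
* The stimulus builder's greedy, never-reuse-an-adjective rule can
  declare infeasibility on pool compositions a backtracking search
  could satisfy; the synthetic defaults leave generous slack.
* LDI is computed only from externally supplied three-response data;
  the built-in simulator generates two-response (old/new) data and
  cannot produce 'similar' responses.
* The phonological-neighbor rule is substitution-only by definition;
  lexica normed under an insertion/deletion-inclusive rule will filter
  slightly differently.
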