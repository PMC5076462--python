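# Methods

`semprime` reconstructs, end to end, the computational apparatus of a
cosine-controlled lexical-decision priming study: distributional
semantic spaces, similarity-stratified stimulus generation, a
trial-level reaction-time simulator, and the crossed mixed-effects
analysis. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data can and
cannot show.

## Semantic spaces

Two count-based distributional models are implemented.

**LSA-type.** A word-by-document matrix; cell (w, d) counts tokens of
w in document d. Document co-occurrence emphasises syntagmatic
(associative, topic-level) relations.

**HAL-type.** A word-by-word matrix over *content* tokens only: after
dropping function words within a sentence, every ordered pair of
content tokens at distance ≤ w co-occurs, symmetrically and with flat
(unweighted) increments; pairs never cross sentence boundaries, and
same-word pairs are skipped so the diagonal stays zero. The default
window is w = 3 content words, the size repeatedly found best for
priming-related evaluation; flat increments are used because the
window-size literature the design follows does not employ a decay
scheme. The window is symmetric (±3) — the usual reading of "within a
window of three content words".

Both matrices are weighted by positive pointwise mutual information,
`max(0, ln(n_wc N / (n_w. n_.c)))`, with marginals taken from the
(vocabulary-restricted) count matrix itself and natural logarithms;
zero counts stay exactly zero. The weighted matrix is reduced to k
dimensions (default 300, the standard setting) by truncated SVD, and
word vectors are the rows of `U_k diag(s_k)`. The `U Σ` convention is a
deliberate choice where toolkits differ: it preserves the weighted
matrix's row geometry exactly at full rank, which makes the reduction
testable against a direct cosine oracle. Matrices whose smaller
dimension is ≤ 600 are decomposed exactly (LAPACK); larger ones use a
seeded randomized SVD (7 power iterations, deterministic sign
convention), so spaces are reproducible bit-for-bit given (corpus,
configuration, seed).

Similarity is the cosine of the angle between word vectors. For all
similarity-band and class logic, negative cosines are clamped to zero —
the general form of the rule the original analysis applied to its
legacy space. Tokens are case-sensitive and unlemmatized; content-word
status comes from the corpus annotation (a `~` prefix marks function
words in the file format).

## Stimulus generation

The generation procedure manipulates cosine similarity as an
independent variable instead of analysing it post hoc:

1. **Pool.** 300 words satisfying the target constraints (concrete
   noun, 4–9 letters, Leipzig frequency class 10–15) are sampled
   uniformly without replacement; 200 become targets, 100 become primes
   for nonword trials. Frequency class is `round(log2(f_max / f))` with
   `f_max` the corpus's top-ranked word count — the Leipzig convention.
2. **Classes.** [0, 1] is partitioned into ten contiguous intervals
   ([0, 0.09), [0.09, 0.18), …, [0.81, 1]); intervals are half-open
   with the last closed, which resolves the shared endpoints of the
   published class list. Targets are assigned to classes as equally as
   possible (exactly 20 each when 10 | 200), uniformly at random.
3. **Primes.** For each target, a prime is drawn uniformly from the
   words whose clamped cosine to the target lies in the assigned class
   and which satisfy the prime constraints (concrete noun, 4–10
   letters, class 9–16) and are not yet part of the item material
   (global uniqueness over all primes and targets). If the candidate
   set is empty the target is re-assigned uniformly at random to
   another class (budget: 20 attempts; re-assignment may revisit a
   class). A wrapper can regenerate the whole list with fresh seeds
   until the matching checks pass and, optionally, until the planned
   allocation is realized without re-assignments.
4. **Nonwords.** Stand-in pseudowords are built by consonant/vowel-
   pattern resampling of reference targets (lengths copied from
   sampled targets, every slot refilled with a letter of the same
   class, lexicon collisions rejected). This matches the length
   distribution by construction; it does not model any particular
   language's phonotactics, which a dedicated pseudoword generator
   would.
5. **Matching.** Diagnostics: Welch t-tests (nonword vs. word target
   length; word- vs. nonword-trial prime length and frequency class)
   and Pearson correlations of cosine with target/prime length and
   frequency class, each flagged at α = 0.05; zero-variance checks are
   flagged as skipped.
6. **Blocks.** Items are partitioned at random into 4 blocks of 50 word
   + 25 nonword trials; block order follows a cyclic Latin square
   recycled over participants, and within-block order is re-randomized
   per participant. Trial-schedule metadata (SOA 1000 ms, response
   timeout 3000 ms, feedback 1000 ms) is carried on the block plan for
   the simulator; no stimulus presentation is implemented.

## Synthetic lexicon and corpus

No raw RT data or corpus-scale spaces are publicly deposited for this
design, so the package generates its own study material. The generator
is first-class, tested code, and its defaults define the study
conditions used by the tests and the acceptance script.

**Lexicon.** V = 1000 content words plus 12 function words. Content
frequencies follow a shallow power law (exponent 0.12) and the function
words form a much steeper head (exponent 2.5) whose top count is 2^9.4
times the top content count. This anchors the whole content band at
Leipzig classes 10–11, with the class boundary at the median content
frequency so both classes are well populated (the analysis model needs
frequency-class variance), while keeping absolute counts high
(≈565–1290 at the default 1.8M-token budget). The anchoring mirrors the real
situation the study exploited: words of frequency class 10–15 in an
880M-token corpus are still high-count words with stable vectors. A
single Zipf law over the whole vocabulary cannot reproduce that at
desk scale — it either starves the class-10–15 band of tokens or of
members — which is why the head is parameterized separately. With
exponent 0 all content frequencies are equal (degenerate limit), but
frequency classes stay near 10 because the head anchor is fixed.
Word lengths (3–12 letters, mass on 4–9, thin tail above 9) and
concreteness flags (p = 0.78) are assigned independently of frequency;
the thin long-word tail keeps prime-length matching feasible at a
1000-word scale, where the 300-word pool visibly depletes the 4–9
letter stock (a depletion artifact corpus-scale studies do not have).

**Corpus.** Content words belong to one of C = 40 latent categories
arranged on a ring; near-synonym pairs (5% of content words, planted
among the more frequent half) share a category and hence a context
profile. Each document has a latent ring position; every content token
draws its category from a wrapped Gaussian kernel (σ = 2.5 ring units,
mass-weighted so realized counts track the lexicon) around that
position, then a word within the category frequency-proportionally.
Function-word slots are interleaved at the lexicon's frequency share.
Kernel overlap makes between-category similarity decay smoothly with
ring distance, so derived spaces produce cosines covering all ten
similarity classes — the feasibility property stimulus generation
needs. A harder mixture (one or two whole categories per document) was
tried first and rejected: it pins the own-category context share near
1/2, which produces a cosine cliff between within- and cross-category
pairs and leaves the middle similarity bands empty.

Defaults: 900 documents × 25 sentences × 80 tokens = 1.8M tokens.
This is the smallest budget at which both space types give stable
enough vectors (median within-category cosine ≈ 0.85–0.92 after the
300-dimensional reduction) for the top similarity class to be
populated for essentially all targets. What the generator does *not*
emulate: real word-frequency tails, morphology and orthography,
polysemy, document-length variation, and any semantic structure beyond
one ring of categories; passing tests therefore show that the pipeline
is correct and calibrated under its stated model, not that the
substantive findings generalize.

## Reaction-time model

Word-trial log RTs follow the same crossed mixed model the analysis
assumes:

    logRT_ij = β0 + β_cos·cos_i + β_lT·lenT_i + β_fT·fcT_i
             + β_lP·lenP_i + β_fP·fcP_i
             + S_j·(1, cos_i, lenT_i, fcT_i) + I_i + ε_ij,

with S_j ~ MVN(0, Σ_S), I_i ~ N(0, σ_I²), ε ~ N(0, σ_ε²), RT =
exp(logRT). Nonword trials share the intercept, the subject/item
intercepts and the residual but carry no covariate effects. Each trial
is an error with probability p_err; with probability p_out the RT is
replaced by a uniform draw from (1500, 3000) ms (a slow-outlier
process, subsequently caught by the RT screen).

Defaults (log-ms scale): β0 = 6.20 (median RT ≈ 600 ms at mean
covariates), β_cos = −0.05 (within the reported range of priming
effects for this design), β_lenT = β_freqT = 0.01, β_lenP = β_freqP =
0.002; SDs 0.12 (subject intercept), 0.04 (cosine slope), 0.004
(target-length and target-frequency slopes), σ_I = 0.04, σ_ε = 0.18;
p_err = 0.017 and p_out = 0.004, matching the reported exclusion rates
(~1.7–1.8% errors, ~0.3–0.4% RT outliers); 44/43 subjects. Σ_S is
diagonal by default but estimated unstructured. The true variance
components of the original data are unrecoverable (no deposited RTs);
these values are declared, not fitted. Covariates enter uncentered and
unscaled.

## Analysis

Preprocessing keeps word trials; drops subjects, then items, with
word-trial error rates above 25%; drops error trials; then drops RTs
outside [100, 1500] ms (the bounds are read as exclusive — "under
100 ms or over 1500 ms" — so boundary values are kept; the percentage
is reported on the post-error base); and takes natural logs. The
subject-before-item order is a convention; the published order is not
explicit.

The baseline model has fixed effects of prime/target length and
frequency class, by-subject random intercepts and slopes for cosine,
target length and target frequency (the cosine *random* slope is in
the baseline, per the maximal-random-effects recommendation), and
by-item random intercepts. The cosine model adds the cosine fixed
effect. For pooled data from two experiments sharing targets, item
intercepts are replaced by crossed prime and target intercepts and no
by-target slopes are added. Parameter counts: 18 vs 19 for the pooled
pair (6 fixed + 10 by-subject covariance + 2 crossed intercept
variances + 1 residual), consistent with the published AIC/log-
likelihood pair.

**Estimation.** Everything is ML, not REML, so likelihood-ratio tests
on fixed effects are valid. The fitter (`semprime.mixedlm`) implements
the profiled deviance of the linear mixed model with a block-diagonal
relative covariance factor: for covariance parameters θ, the fixed
effects, random-effect modes and residual variance are profiled out
through one Cholesky factorization of `Λ'Z'ZΛ + I`, and

    −2ℓ(θ) = 2 log|L| + n(1 + log(2π·pwrss/n)).

The analytic gradient (trace identity for the log-determinant,
envelope theorem for the penalized RSS) drives an L-BFGS-B search from
λ = I, followed by a short Nelder-Mead polish from a tiny simplex;
convergence is declared when the polish cannot improve the deviance by
more than 1e-3. Fits that fail this check are refitted with diagonal
covariance blocks and flagged (`fallback="diagonal"`); fits with a
relative-factor diagonal below 1e-4 are flagged singular but returned
(boundary estimates are legitimate ML solutions). Standard errors come
from the profiled information `σ̂²(X'V⁻¹X)⁻¹`; AIC = 2k − 2 log L with
k counting fixed effects, free covariance parameters and the residual
variance. The fitter reproduces lme4 ML fits (log-likelihood,
estimates, SEs, parameter counts) on crossed-design test data; an R
cross-check runs in the test suite.

Wald intervals use the exact normal quantile (1.959964 at 95%).
Likelihood-ratio χ² is clamped at zero; p-values are reported to three
decimals in summaries. Predicted RT curves are exponentiated
fixed-effect predictions over the cosine range at mean covariates.

## Calibration

`semprime.calibration` closes the loop: simulate experiments from the
generative model, run the exact analysis, and measure (i) type-I error
of the cosine LRT under β_cos = 0 at a reduced size (20 subjects × 100
class-stratified items; 500 replications), and (ii) bias and 95%
Wald-interval coverage of β̂_cos at study scale (43 subjects × 200
items, β_cos = −0.05; 200 replications). Replications rotate over
independently regenerated stimulus samples (fresh pool draw and prime
sampling per replicate), because a real replication redraws its
stimuli and a single frozen item list contributes a fixed
stimulus-sampling perturbation that would otherwise be conflated with
estimator bias. Within-replication fits are warm-started from the
previous replication's covariance parameters (the optimum is
independent of the start; this only saves iterations).

Observed behaviour at defaults: rejection rate ≈ 0.04, mean β̂_cos
within Monte-Carlo error of −0.05, coverage ≈ 0.95 (ML intervals are
mildly anti-conservative in small samples, as expected).

## Reduced problem sizes

The test suite and the acceptance script run the full default study
(1.8M-token corpus, 300-dimensional spaces, 200-item designs) for
structural checks, and the calibration at 500/200 replications; the
pipeline round-trip test uses a scaled-down configuration (500 words,
600k tokens, 40 targets, 6 subjects) chosen so every stage still
exercises its real code path. These sizes are the package's own
defaults for a reproducible desk-scale study.

## Known limitations

* The corpus generator produces one ring of categories with a single
  kernel width; real corpora have hierarchical, anisotropic topic
  structure, and real cosine distributions are not uniform across
  bands.
* The frequency-class scale is anchored by a synthetic closed-class
  head; only classes ~10–11 are populated by content words, so the
  class-range constraints (10–15, 9–16) are exercised mainly at their
  lower edges.
* Nonwords are pattern-resampled strings, not phonotactically
  validated pseudowords.
* Matching occasionally fails a check by construction (the ceiling on
  noisy cosines couples weakly with frequency); the regenerate wrapper
  handles this the way the original "we ensured" step implies.
* The mixed-model fitter covers the structures this design needs
  (crossed grouping factors, one covariance block per factor); it is
  not a general formula-based mixed-model engine.
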