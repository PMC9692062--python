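# Methods

This note records the model assumptions, estimation conventions, and
numerical choices behind `morphtrade`, and what the synthetic test
surface does and does not establish about real corpora.

## Word model and ordering space

A word token is a root plus at most one affix per templatic slot, with
slots fixed to a side (prefix or suffix).  An ordering grammar is one
total order per side over the slots, in root-distance coordinates
(rank 1 = adjacent to the root); linear position is derived at
linearization time.  Counterfactual orderings permute abstract morpheme
labels only: no allomorphy, no morphophonology, and a slot never changes
side, since the typological universals at issue concern distance from
the root rather than side of attachment.  Consequently the search space
for a language is the product of per-side permutation groups, which for
attested templates (≤ ~8 slots per side) is small enough that exhaustive
enumeration is often feasible and is used as the search oracle in tests.

## Information profile estimation

All estimation is within-word: each linearized word is an independent
sequence, and no cross-word (sentence-level) context is used.  The
profile `I_t` is obtained as differences of an entropy ladder
`H_0 ≥ H_1 ≥ … ≥ H_{t_max}`, where `H_t` is the expected total code
length of a word when every position is predicted from its `t`
preceding symbols.  Conventions, each of which is shared by the plug-in
estimator and the exact enumeration oracle so that the two agree to
machine precision on corpora realizing a distribution with exact
multiplicities:

* **Position stratification.**  Conditional distributions are estimated
  per position-within-word; contexts at different positions are never
  pooled.  Words are short and positions are strongly non-exchangeable
  (the root sits at a fixed boundary), so stratification is the natural
  regime; it is also what makes the exact profile invariant under string
  reversal for fixed-length distributions, and exactly zero beyond the
  reach of a Markov source — two structural checks the test suite
  enforces at 1e-12.
* **Boundary handling.**  Sequences are left-padded (position-distinct
  boundary symbols, though under stratification any fixed convention is
  equivalent) and closed with one end symbol that *is* a predicted
  position.  Predicting word termination matters: which affixes are
  present — and hence where the word ends — is informative about the
  root, and that information is part of the within-word statistical
  structure being measured.
* **Scale.**  `H_t` is reported in bits per word.  All orderings of a
  corpus share its word count and length distribution, so comparisons
  and AUC rankings are unaffected by the choice of a per-word versus
  per-symbol scale.
* **Clipping.**  `I_t = max(0, H_{t-1} − H_t)`.  The plug-in ladder is
  nonincreasing by construction, so clipping can only fire under
  held-out smoothing; clip events are counted on the profile
  (`n_clipped`), and the conservation identity
  `Σ I_t = H_0 − H_{t_max}` holds exactly whenever none fired.

Two estimators are provided.  `plugin` (default for synthetic and
oracle-checked runs) uses maximum-likelihood conditional frequencies.
`heldout` (recommended for real corpora) scores each of k folds (default
10) under count tables built from the remaining folds, with absolute
discounting (default d = 0.5) and recursive lower-order backoff down to
a uniform base; this trades the plug-in's optimism for an upper bound on
the true cross-entropy.  The default horizon is
`t_max = longest linearized word + 1`, beyond which no within-word
information exists.

## Tradeoff curve and AUC

For a profile `I_1..I_T`, the curve point at horizon `T` is
`(Σ_{t≤T} t·I_t, Σ_{t>T} I_t)`: a memory bound in bits (each bit
weighted by the distance it must be held) against the excess surprisal
bound (information irretrievably beyond the horizon).  The y-axis is
*excess* surprisal — the surprisal bound minus its asymptote
`S_∞ = H_{t_max}` — so the curve ends at zero, its area is finite and
independent of the `S_∞` estimate, and the AUC depends only on the
profile.  AUC integrates the piecewise-linear curve by the trapezoid
rule from memory 0 to the final memory value; between consecutive points
with `I_T > 0` the slope is exactly `−1/T`, so curves are convex by
construction.  Lower AUC = more information-local ordering.

## Optimization and baselines

Hill climbing restarts from uniform random grammars (default 10
restarts; the enumerable-fixture tests use 5), evaluates the full
neighborhood of single-slot relocations within each side, and moves to
the strictly best neighbor (steepest descent), breaking ties toward the
lexicographically smallest rank vector so the entire search is
bit-reproducible given its seed.  Objective values are memoized per
grammar: on a K-slot side the reachable space has K! points, so repeated
visits are free and small spaces degenerate gracefully into exhaustive
search.  Real-valued weight representations (as in word-order
optimization work) were deliberately avoided — relocation moves already
connect the permutation space, and the discrete representation keeps
traces exact.

Baseline families: uniform random orderings; orderings constrained by
typological universals, expressed as precedence chains over affix
classes and interpreted strictly on root-distance ranks within and
across sides, sampled by rejection (budget 10,000) with an exact
enumeration fallback, which keeps the constrained sampler uniform over
admissible linear extensions; the reversed attested order; and the
hill-climbed optimum.  When the full space has at most 10,000 grammars
the pipeline enumerates instead of sampling, removing sampling error.

## Pairwise accuracy and baseline quantiles

Accuracy of a candidate ordering against the attested one counts, over
every word token, every unordered pair of attested same-side affixes,
scoring agreement in relative order; token weighting follows the
definition of the statistic, and cross-side pairs are excluded because
side membership fixes their order regardless of grammar.  A corpus with
no evaluable pair raises rather than returning a vacuous score.
Reversing a candidate complements its accuracy.  Quantile placement
against a baseline sample counts strictly worse baselines only, so ties
(e.g. a random baseline that happens to equal the candidate) never
inflate the quantile.

## Root–affix conditional mutual information

For a target slot or affix class, the statistic averages the pointwise
log-ratio `log2 P(w_k | w_1..w_{k-1}) / P(w_k | w_2..w_{k-1})` over all
tokens whose position `k` realizes the target, where `w_1` is the root
and the string runs root-outward on the target's side (prefix strings
are mirror-read; opposite-side affixes are not part of the context).
The default estimator is plug-in, with counts pooled at each context
length and restricted to strings long enough to have a symbol at the
predicted position; it is exact on enumerable fixtures.  Plug-in
estimates are, however, badly biased upward when root-anchored contexts
are sparse: a context observed once makes the numerator conditional 1
regardless of the true dependence, and the bias grows with distance from
the root precisely where true dependence shrinks — bad enough to
scramble slot comparisons at realistic corpus sizes.  The `crossfit`
estimator removes that failure mode: conditionals are estimated on
k-fold train splits (default 5) with absolute discounting (d = 0.5) and
backoff that drops the leftmost context symbol — so the root-anchored
conditional backs off through exactly the root-free conditional it is
compared against — and pointwise values are averaged over the held-out
fold.  Cross-fitted values are conservative (shrunk toward zero, and
slightly negative where the root adds nothing beyond smoothing), but
rank comparisons across slots are reliable, which is what the gradient
analysis needs.

## Synthetic generator

The generator emulates the cooccurrence structure argued to drive
morpheme ordering: affix presence and affix value both depend on the
root, with controllable strength.  Dependence is routed through a latent
class carried by root identity (`class = rank mod C`) so that every
planted quantity has a closed-form oracle by enumeration over
classes × outcomes, while root frequencies remain Zipfian
(`P(rank) ∝ rank^{-s}`) as in real lexica.  Per slot `k` (1-based):
presence probability `(1−δ_k)q_k + δ_k·ρ_{k,c}` with the deterministic
pattern `ρ_{k,c} = [(k+c) even]`, and value = the class-anchored value
`(c·k) mod V_k` with probability `λ_k`, else uniform.  Structural
assignments are deterministic functions of indices rather than sampled
tables, so reproducibility requires no stored parameters and the
oracle MI is monotone in both dependence knobs.  Config validation
rejects anything that would require clamping a derived probability.

The reference language used throughout the acceptance surface: 50 Zipf
(s = 1.0) roots, 2 classes, four suffix slots with V = 4,
q = (0.9, 0.7, 0.6, 0.5), δ = (0.5, 0.3, 0.15, 0.0),
λ = (0.8, 0.5, 0.25, 0.05), planted order λ-descending, 30,000 tokens.
Exact enumeration of the model distribution over all 24 orderings
confirms the planted order is the true AUC optimum under these
conventions, so planted-order recovery is a consistency check on the
whole pipeline, not a lucky draw.

What the generator does *not* emulate: phonological realization and
fusion, inter-affix dependence beyond what the shared class induces,
paradigm defectivity, sentence-level conditioning, and mixed
prefix+suffix templates beyond structural support.  Passing the
synthetic tests therefore validates the estimators, the search, and the
statistics under a known ground truth; it does not by itself establish
conclusions about any natural language, for which the held-out estimator
and a user-supplied segmented corpus are the intended route.

## Problem sizes and determinism

Test and acceptance runs use the reference scale (30,000 tokens, 20
generator seeds, 200 baseline orderings, 5 hill-climbing restarts) and
smaller enumerable fixtures (250–400 tokens, 3–4 slots) where an
exhaustive oracle is the point; these sizes give stable statistics for
every check while keeping the full suite inexpensive.  All randomness
flows through explicit integer seeds (numpy `default_rng`); sampling,
search, and pipeline output are bit-reproducible, and the experiment
runner writes byte-identical tables for identical configurations.
Entropy accumulation uses exact summation (`math.fsum`) where identities
are asserted at 1e-12, and n-gram contexts are compressed to dense
integer ids (`np.unique`) so alphabet size never limits the context
radix.

## Known limitations

* The plug-in profile estimator is optimistic on small corpora; compared
  orderings share the bias direction but not necessarily its magnitude.
  For real-corpus claims, use the held-out estimator.
* CoNLL-U input reconstructs affix order declaratively from the schema,
  since FEATS are unordered; the segmented TSV, which records attested
  order, is the authoritative format.
* Sides are fixed under reordering; languages whose universals interact
  with side of attachment are out of scope.
* The conditional-MI gradient analysis compares slots within one corpus
  and grammar; absolute cross-corpus CMI values are estimator-dependent
  (plug-in optimistic, crossfit conservative) and should not be compared
  across estimators.
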