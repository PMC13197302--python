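# Methods

## Model

A fluency corpus is a set of ordered, repeat-free word lists over a shared
vocabulary of `W` types.  The generative model is a Markov chain on `W + 1`
states: the words plus one *jump* pseudo-state (index 0 internally; word ids
are shifted by +1 inside the full matrix and never exposed).  The full
transition matrix is

    P_J = [ 0    ρ  ]
          [ θ    P′ ]     with  p′_ij = (1 − θ_i) p_ij ,

where `p_ij` comes from row-normalizing a nonnegative adjacency matrix,
`θ_i` is the probability of a global reset from word `i`, and ρ is the
landing distribution after a reset.  Jumps can equivalently be attached at
the adjacency level (border `A` with jump weights θ̃ and landing weights ρ̃,
then row-normalize; `θ_i = θ̃_i / (θ̃_i + Σ_j a_ij)`).  The jump state can be
*reabsorbed* exactly — `P_ABS = P′ + θρᵀ` — which preserves all effective
word-to-word transition probabilities while removing the pseudo-state; the
package verifies this identity to 1e-10 against absorbing-chain solves and
uses `P_ABS` for topological quantities (semantic cohesion, stationary
analyses) where an explicit jump state would bias step counts.

### Censored-walk likelihood

Produced sequences record each word at first activation only.  The
probability that the next emitted word is `t` given the visited prefix `S`
is the probability that a walk started at the last visited word is absorbed
at `t` when `S ∪ {jump}` is transient and every unvisited word absorbs.
With `Q` the transient block and `r` the target column, this is
`eₛᵀ (I − Q)⁻¹ r`; the implementation solves the adjoint system once per
prefix and reads off the whole next-word distribution.  List likelihood is
the product of the first-word term (ρ for jump-start models, an empirical
frequency distribution for INVITE) and the per-transition absorption
probabilities.  Impossible transitions yield −inf rather than an exception
so model comparison over a corpus remains total; the corpus-level gLL is
then 0 with the offending lists flagged.

Numerics: dense LU solves (transient blocks are at most list-length-sized,
far below any problem size where sparse iterative methods would pay off);
absorption probabilities are clipped to [0, 1]; row sums are validated to
1e-12 at construction.

## Estimators

Unweighted: first-edge, naive random walk (all adjacent pairs), Pathfinder
(mean positional separation distances, sparsest network `q = W−1, r = ∞`
via Floyd–Warshall minimax distances; an edge survives iff its direct
distance does not beat any path's bottleneck), conceptual network, planar
correlation network (Pearson correlations of list-occurrence vectors, edges
added in descending order while planarity holds, ties broken by token-id
pair; planarity via networkx), and a U-INVITE variant (seeded
random-permutation sweeps over single-edge toggles, a toggle kept iff the
corpus CRW log-likelihood strictly increases; the original edge-ordering
heuristics are not reproduced and the provenance records this).
Unweighted models receive a scalar θ tuned by fivefold CV and a
frequency-proportional ρ.

The CN significance test is self-contained: the co-occurrence count of a
pair within positional window `d` over lists containing both words is
compared with a random-placement null in which the two positions are a
uniform pair of the list's slots (closed-form per-list probability
`(dλ − d(d+1)/2) / C(λ,2)`, capped at `d = λ−1`).  The count's exceedance
probability is an exact Poisson-binomial tail computed by dynamic
programming — no normal approximation at any size — and edges require both
`c ≥ min_cooc` and Bonferroni-corrected significance over all tested
(co-listed) pairs at α = 0.05.  The test lives behind one function so an
alternative null can be swapped in.

Weighted: BIGRAM-FIXED uses directed adjacent-pair counts as weights with a
CV-tuned scalar θ.  BIGRAM-IND prunes counts below a threshold (CV-tuned;
grid 1..8) and pools each node's removed outgoing weight into its jump
weight, giving node-specific θ_i; ρ̃ is the list-frequency vector.
BIGRAM-CN masks the γ-powered counts by the CN edge set and pools *all*
off-mask weight into the jump weights.  `0^γ` is defined as 0 for every γ
(including γ = 0) so that masked edges whose evidence came from non-adjacent
co-occurrence contribute no invented local mass.  γ defaults to 1 and is
tuned by fivefold CV over {0, 0.25, …, 2.0, densified near 1}.

INVITE parameterizes the row-stochastic matrix by a softmax of a free
matrix β (diagonal excluded) and minimizes the L2-penalized negative CRW
log-likelihood of the transitions.  Gradients are exact: the derivative of
each absorption probability with respect to the transient block is the
outer product of the adjoint and forward solves, chained through the
softmax.  INVITE-CN restricts β to the CN mask and additionally optimizes
per-node jump logits and landing softmax weights, with the first-word term
included (the walk starts at the jump state); masked-out rows force
θ_i = 1.  Free-parameter counts (`W(W−1)` and `nnz(mask) + 2W − 1`) feed
the BIC.  The default optimizer is full-batch L-BFGS with the analytic
gradient — corpora in this domain are small enough that a deterministic
quasi-Newton run is both faster and more reproducible than stochastic
descent — with an averaged-SGD option (seeded, per-list sampling, penalty
spread across lists) retained for parity with gradient-descent practice.
β initializes at 0 (uniform rows) by default for bit-reproducibility; a
seeded random init is available.

## Metrics

* **gLL** — geometric-mean per-emission probability
  `exp(Σ log-lik / Σ λ)`; the emission count includes each list's first
  word.  Both the pooled corpus value and the per-list geometric means are
  reported, because the per-list values are what the beta fits and
  equivalence tests operate on.
* **fLL** — per list, `(∏_i [1 − (1 − f_wi/N)^{λ/λ̄}])^{1/λ}` with
  frequencies, `N` and λ̄ frozen from a designated reference (training)
  corpus.  Words absent from the reference zero the value and are flagged;
  the unseen-word mapper should run first.
* **nRB** — count of adjacent pairs in the CN-derived relevant set `R`,
  detrended as `C* = C − m(λ − λ̄)` with slope `m` fit once by least squares
  on the reference corpus, so test and synthetic lists are scored on the
  reference scale.

Statistical apparatus: maximum-likelihood beta fits on (0,1) (values
clipped to 1e-9 from the endpoints) with the mode and a shortest credible
interval found by width minimization over the quantile offset (default mass
50%); Gaussian fits for nRB; one-sample KS tests with parametric-bootstrap
p-values (fit–refit on simulated samples, 200 replicates by default) since
shape parameters are estimated from the data; a discretized-normal KS
variant on integer support; percentile bootstrap CIs (1,000 replicates,
geometric mean for gLL/fLL, arithmetic for nRB); `BIC = k ln n − 2 ln L`
with `n` = total emissions; density overlap as `100 ∫ min(pdf_a, pdf_b)` by
dense trapezoid quadrature; and R² between bigram count vectors pooled over
both directions of the relevant pairs.

BF01 is computed by the BIC approximation, a deliberate, documented default
since the literature rarely states its Bayes-factor recipe:
goodness-of-fit compares the fitted parametric family against a
histogram-density alternative (Sturges bins); the two-sample variant
compares one pooled fit against separate fits of the same family.  Values
above 1 favor the null (good fit / same distribution).  The method is
pluggable and recorded in every report.

## Synthetic generation and the ground-truth generator

Sampling is a literal censored walk on the full matrix: start at the jump
state (or at a frequency-drawn word for jump-free models), sample rows,
record words at first visit, never record the jump state, stop at the
target length (step cap 10⁶ with a truncation flag for trapped walks;
lengths clip to [1, W]).  List lengths draw from a discretized normal
(integer `k` gets the mass of `[k−½, k+½)`, truncated at 1 and `L_max`),
fitted to data by maximum likelihood with a σ floor of 0.5 for degenerate
samples.

The ground-truth generator used in recovery experiments emulates, at
reduced scale, the structure of real fluency corpora: 20 words in 4
clusters; dense within-cluster weights and *sparse* between-cluster bridges
(10% of between pairs), since global moves are carried by the jump state;
log-normal (σ = 0.75), frequency-coupled edge weights, because association
strengths in real corpora are strongly skewed — near-homogeneous weights
would make per-pair bigram counts indistinguishable from sampling noise, a
regime real data are demonstrably not in; per-node jump probabilities
uniform on (0.05, 0.25), matching the observation that roughly seven of
eight transitions in human lists stay within the local component; and a
landing distribution iterated to the stationary distribution of the
reabsorbed chain, so the ground truth satisfies the ρ-proportional-to-
frequency property the estimator family itself assumes (a decoupled ρ would
measure misspecification rather than recovery).  Recovery runs use 500
training and 100 held-out lists with lengths ~ N(9, 2.2²) — a scaled-down
analogue of ~400-type corpora with mean length ~16.5; with only 20 types a
list necessarily covers far more of the vocabulary than a real list does,
which makes censoring artifacts *stronger* than in real data, so recovery
results are conservative in that respect.

What the generator does not emulate: perseverations and corrections
(corpora are assumed pre-cleaned), off-topic intrusions, response times and
the decision to stop (length is the sole stopping mechanism), and
participant-level heterogeneity in θ or ρ.  Passing recovery tests
therefore show that the estimation pipeline inverts the assumed generative
process at realistic scale and noise — not that human lists follow the
model.

## Tuning

Fivefold cross-validation over whole lists (folds keyed to list ids, so
composition is independent of storage order).  The score is pooled
validation gLL after per-fold unseen-word mapping; ties break toward the
smaller parameter value (sparser models).  Default grids: θ ∈ {0.1, …,
0.9}, prune threshold ∈ {1..8}, γ as above.

## Jump validation

Switches are labeled from an external category annotation (a transition is
a switch iff the two words share no category; transitions touching
unannotated words are excluded and counted).  Predictors: static θ of the
source word, the prefix-adjusted jump probability (absorption at the jump
state with the visited prefix transient — both are emitted, since either
reading of "the model's jump probability" is defensible), inverted degree,
and inverted 3-step semantic cohesion on the reabsorbed matrix (step-1
self-returns count, as reabsorption can create a positive diagonal).  AUCs
use the midrank Mann–Whitney statistic; paired AUC comparison uses DeLong's
test with placement values computed from midranks.

## Known limitations

* One jump state; partial resets via multiple pseudo-nodes are out of scope
  of this version (the block layout leaves room).
* The U-INVITE search is a randomized-sweep stand-in with the same
  acceptance rule as the original, not its published heuristics; on large
  vocabularies it is O(W²) likelihood evaluations per sweep and is only
  practical for small problems.
* The CN null assumes word positions exchangeable within a list given
  presence; serial-order effects (typicality gradients) violate this
  mildly.
* Exceedance tests and Bonferroni correction make CN edges conservative on
  small corpora; downstream nRB values inherit that conservatism.
* Bigram-count weights are biased estimates of local transition weights
  when lists cover a large fraction of the vocabulary (censored-path and
  jump-mediated adjacencies inflate off-structure counts); this is a
  property of the estimator family, visible in recovery experiments as a
  modest gLL gap to the generating model.
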