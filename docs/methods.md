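# Methods

## Model

The data are a completed SI epidemic on a closed population of `m`
individuals: shifted infection times `Ĩ` (index case at 0, strictly
increasing — the continuous-time model gives ties probability zero, so tied
times are rejected as invalid input rather than jittered) and a
transmission tree `P` in which each non-index node has exactly one infector
with a smaller label.  The latent contact graph `G` is simple, undirected
and hollow; the transmission tree is necessarily a spanning subgraph of
`G`.

**Network.**  `G` is generated by sequential growth in a latent entry order
`σ` (a uniform-prior permutation, distinct from the infection order): a
founding dyad, then each entrant `i ≥ 3` gains `X_i` backward edges, where
`X_i` follows the censored Poisson(μ) on `{1, …, i−1}` (mass at 0 moved to
1, upper tail lumped at `i−1`).  Targets are drawn one at a time without
replacement with weights mixing the degree share (weight `1−γ`) and the
entry-recency share (weight `γ`).  The mean of `X_i` for large `i` is
`μ* = μ + e^{−μ}`, which is why `α = β·μ*` acts as a network-scaled rate.

**Epidemic.**  Given `G`, each infected–susceptible edge carries an
independent Exponential(β) clock; the epidemic is observed to completion.
Equivalently each infected node contacts neighbours at rate β per edge; we
simulate the equivalent Markov chain (waiting time Exponential(β × cut
size), infectee proportional to its infected-neighbour count, infector
uniform among those) and relabel nodes into infection order afterwards.

**Likelihood.**  `π(P|G)` is a product over nodes of the reciprocal of
their earlier-infected neighbour count (with indicator constraints);
`π(Ĩ|G,β) = β^{m−1} exp(−β Σ_{i<j} G_ij (Ĩ_j − Ĩ_i))`; and `π(G|μ,γ,σ)` is
built constructively as the product over entry steps of the censored
Poisson pmf and the exact probability that sequential weighted sampling
without replacement produced the realised neighbour set.  This constructive
density integrates to one by construction; the test-suite verifies
normalisation to 1e−10 by enumerating all supported graphs at m = 3, 4
across a (μ, γ) grid, and agreement of the density with simulator
frequencies at 10^5 replicates.

## Computing the selection-set probability

The probability that successive sampling yields a given unordered set has
no product closed form; it is computed exactly by a dynamic program over
sub-multisets of the chosen weights,

    P(A) = Σ_{s∈A} P(A−s) · w_s / (1 − W(A−s)),

with weights tied by value grouped (for γ = 0 the weights are degree
ratios, so group counts are large and the state space is small).  For large
sets of distinct weights the same quantity is evaluated through the
exponential-race representation — successive sampling is the order
statistics of independent Exponential(w) clocks — as the 1-D integral
`∫ U e^{−Uy} Π_s (1 − e^{−w_s y}) dy` with `U` the unchosen mass, computed
by trapezoid quadrature on the log axis (step 0.12), where the integrand
decays exponentially at both ends; agreement with the DP is ~1e−9 relative
and is unit-tested.  The DP path is used whenever its grouped state count
is ≤ 512, which covers every case the normalisation oracles touch, so the
exactness guarantees are unaffected by the quadrature.

Numerical notes: the Poisson upper tail is taken from the Poisson survival
function (regularised incomplete gamma), never naive summation; the
kernels are numba-compiled and operate on cached log-pmf/log-tail tables so
that only a μ-update rebuilds them.

## Sampler

Metropolis-within-Gibbs over `(β, μ, γ, σ, G)`:

* `β` — conjugate Gibbs, Gamma(a_β + m − 1, b_β + E) with `E` the total
  edge exposure.  Priors default to Gamma(1, 0.001) on β and μ — vague,
  scale 1000.
* `μ`, `γ` — Gaussian random-walk Metropolis on the natural scale, with
  out-of-support proposals rejected.  During burn-in only, the proposal sd
  is multiplied by `exp((acc − 0.25)/√b)` per 50-iteration batch `b`,
  targeting ≈ 0.25 acceptance; the post-burn-in kernel is fixed, keeping
  the chain Markov.  This adaptation also self-tunes to the prior scale
  when the likelihood is flat in μ (large-μ regions), which is what makes
  the vague prior mixable.
* `σ` — uniformly random transpositions (default `m` proposals per
  iteration, configurable); moves breaking the support (an entrant with no
  backward edge) are auto-rejected via a −∞ density.  Any irreducible
  symmetric proposal is valid; transpositions are chosen for locality.
* `G` — each unknown potential pair is flipped by delayed-acceptance
  Metropolis: stage one uses the cheap factors (tree neighbour counts and
  times exposure), and only survivors pay the full graph-density
  recomputation, whose ratio alone drives stage two (Christen–Fox; the
  stage-one surrogate is a fixed function of the state, so the invariant
  distribution is exact).  The per-proposal density is recomputed in full
  by the compiled kernel rather than incrementally: with γ = 0 an edge flip
  perturbs the degree-ratio weights at *every* later entry step, so
  incremental recomputation could save at most a factor ≈ 2 and was not
  worth the complexity.  A pure-Python reference of the density exists and
  kernel/reference equality is unit-tested on random graphs.  Unbiasedness
  of the delayed-acceptance flips was verified against a full-posterior
  enumeration oracle (all graphs × all entry orders × 2-D quadrature over
  β, μ) at m = 4.
* Pairs known present or absent (the transmission pairs, plus any revealed
  by a partial observation) are never proposed; their trace frequencies are
  exactly 1 and 0.

Initialisation: `σ` = epidemic order, `G` = all known-present pairs (always
has finite posterior because every infector precedes its infectee),
`β₀ = (m−1)/E(G₀, Ĩ)` (a method-of-moments value on the initial graph),
`μ₀ = 1`, `γ₀` = prior mean when estimated; all overridable.  Caches
(neighbour counts, exposure, tree log-probability) are refreshed from
scratch every 250 iterations to bound float drift.  One seeded generator
per chain drives every draw in a fixed documented order, so traces are
bit-reproducible; multiple chains use consecutive seed offsets and are
pooled after burn-in.  `γ` is fixed at 0 by default (pure PA), reflecting
its non-identifiability; estimation mode is retained.

The BRG comparison model replaces the network density with
`p^{|G|}(1−p)^{C(m,2)−|G|}`; `p` gets a conjugate Beta(1,1) update, and
edge flips need only O(1) ratios.  The degree-tail diagnostic
`P(X ≥ k), X ~ Binomial(m−1, p̄)` is computed through a numerically stable
survival function.

## Synthetic data and what the tests show

The generator *is* the model: PA network growth followed by the SI
exponential race, relabelled to epidemic order.  Default study conditions
are those of the simulation designs — `β = 0.4`, `μ ∈ {4, 6, 8, 10}`,
`γ ∈ {0, 0.2, 0.5, 0.8, 1}`, `m ∈ {30, 50, 70}`, with the share of
non-tree pairs whose status is revealed in `{0, 0.25, 0.5, 1}`.  Synthetic
data are idealised in ways real cascade data are not: every infection is
observed, times carry no measurement error, the network is static, and the
population is closed.  Passing tests therefore demonstrate correctness of
the inference machinery under the model, not robustness to the
misspecification real data would bring.

Scaled-down chain lengths are used in the automated checks (the package's
own choice of problem sizes): the m = 3/4 oracle chains run 40k iterations;
observed-graph recovery at m = 70 runs 5k; latent-graph identifiability at
m = 50 runs 8k (the sampler reaches its stationary regime within ~2k there,
verified by comparing against 20k-iteration runs and against chains started
from the true dense configuration); the partial-observation grid runs 2k
with a 300-pair partial edge scan and 20 transpositions per iteration.

## Known limitations

* With only the transmission tree observed, the exact posterior
  concentrates on sparse graph configurations with small μ — sparser
  explanations of the same times are intrinsically favoured by the tree
  and times factors, and the entropic mass of denser graphs does not
  overcome them at these sample sizes.  The posterior of μ is then
  insensitive to the true μ (the identifiability phenomenon), and α = β·μ*
  is the quantity to report; its posterior concentrates but can still sit
  a few posterior SDs from the generative value for unlucky data
  realisations at small m, because the posterior SD understates
  between-realisation variability.
* Single-edge flips plus componentwise scalar updates mix within the
  sparse regime quickly, but traversal along the β–μ* ridge relies on the
  adaptive μ step; for very vague priors the ridge's flat large-μ region
  is explored only on the prior scale.
* SIR/SEIR compartments, recovery, right-censored epidemics, multiple
  epidemics sharing one network, and per-individual rates are out of
  scope.
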