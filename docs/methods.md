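# Methods

This note documents the models, estimators and numerical choices behind
`viaspace`, and what the synthetic test universes do and do not establish
about real genome-scale systems.

## Viability model

A genotype over a universe of N reactions is a presence/absence vector; its
phenotype is decided by flux balance analysis.  The LP skeleton for a
(universe, environment, biomass) triple has one column per universe
reaction, one implicit exchange column per external metabolite (ids ending
in `_ext`), and one biomass drain column consuming the biomass constituents
in their stated proportions.  Constraints are steady-state mass balance
S·v = 0 over all metabolites and per-column flux bounds.  A genotype is
imposed by zeroing the bounds of absent reaction columns — contract-identical
to deleting the columns, but it keeps a single LP skeleton for the millions
of solves an MCMC run needs.  The solver is HiGHS via
`scipy.optimize.linprog`.

**Environment convention.**  Exchange flux is positive outward.  The carbon
source gets bounds [−u, U] (uptake capped at u, secretion free), unlimited
inorganics [−U, U], every other external metabolite [0, U] if secretable
and [0, 0] otherwise.  Defaults: U = 1000 and u = 10 in arbitrary flux
units.  For the strict-positivity phenotype any positive finite u induces
the same viable set, because the feasible flux cone scales linearly with
the uptake cap; the magnitudes only matter for the stringent
(`at_least`) viability variant.

**Viability threshold.**  "Strictly positive biomass" must be separated
from LP round-off: a genotype is viable when Z > ε with
ε = 10⁻⁹ × (carbon uptake cap), a scale-relative tolerance robust to unit
choice.  Solver failures raise rather than silently reporting
non-viability.

**Derived screens.**  Essential reactions are found by n single-knockout
LPs; super-essential reactions are the essential set of the full universe
and are necessarily essential for every viable genotype (removing other
reactions can only shrink the feasible cone).  Blocked reactions are found
by flux variability analysis — maximize (and, for reversible reactions,
minimize) each present reaction's flux subject to biomass ≥ ε; a reaction
is blocked when the attainable magnitude stays below 10⁻⁶.  Constraining
biomass to be positive (rather than steady state alone) reflects the
genotype-specific reading of "blocked": the network can grow only with
zero flux through the reaction.  No thermodynamic loop law is imposed;
internal loops may legitimately unblock a reaction.

## Viable-fraction decomposition

P_n = |V(n)|/|Ω(n)| is factored as the probability of containing all s
super-essential reactions — the exact prefactor B(N−s, n−s)/B(N, n) —
times the conditional probability of viability given that containment,
estimated by sampling genotypes seeded with the super-essential set and
filled with uniform random reactions (default 10⁶ samples, Wilson 95%
intervals).  All probability arithmetic is in log₁₀: realistic fractions
underflow doubles.  Binomials are exact big integers below N = 10⁴ and
log-gamma above.  When no sampled genotype is viable the conditional
factor is reported as the rule-of-three upper bound 3/k rather than zero,
and the estimate is flagged as an upper bound.

On enumerable universes the decomposition is an *identity*: prefactor ×
exact conditional equals |V(n)|/C(N, n) as rational numbers, which the
test suite checks exactly.

## Fixed-n MCMC

Moves are reaction swaps (one present bit out, one absent bit in), chosen
uniformly and independently, so every legal transition and its reverse
have equal proposal probability.  Accepting a proposal iff the new
genotype is viable is therefore Metropolis sampling of the uniform
distribution on the swap-connected component of V(n); no Hastings
correction is needed.  Whether that component is all of V(n) is not
decidable in general — estimates are conditional on the accessible
component, and the fixture generator records connectivity so uniformity is
only asserted where it is provable.

Defaults mirror standard practice for this sampler: 10⁶ total steps, 10⁵
burn-in, thinning 10³, super-essential reactions frozen out of proposals
(they can never leave a viable genotype, and freezing them shrinks the
proposal space from n(N−n) to (n−s)(N−n) pairs, raising the acceptance
rate A).  The acceptance rate is recorded over post-burn-in proposals.

**Diagnostics.**  The Hamming distance to the chain start is traced; the
autocorrelation time τ is the first step at which the trace reaches
(1 − 1/e) of its plateau (mean over the final half).  A trace counts as
converged only when its two final quarters agree within 10% of the plateau
and the crossing occurs in the first half — a still-rising trace yields a
not-converged flag instead of a τ.  The heuristic expectation τ ≈ n/A
(one effectively independent genotype per ~n accepted swaps) holds within
a small factor on the fixtures.  Errors of sample averages use
delete-one-block jackknife over consecutive saved states with variable
window sizes; the error at the largest window is the reported plateau
value.

**Initial state.**  The support of an optimal flux vector of the full
universe (union over configured environments), padded with random absent
reactions to exactly n bits; restriction to a support preserves that flux
vector, so the start is viable by construction.

**Two-headed walk.**  Two independently initialized heads alternate swap
proposals; a proposal is accepted iff viable *and* the inter-head Hamming
distance does not decrease (distance-preserving moves are accepted — the
non-decreasing constraint is taken literally, which lets the pair slide
around ridges).  A replicate stops when the distance has not increased
during the most recent third of elapsed steps (after a 60-step grace
period), capped at the configured step budget; the default 5 replicates
use seeds seed+r and the maximum final distance is reported.  The result
is a lower bound of the true diameter of the accessible space, never an
overestimate, and on enumerable fixtures it attains the exhaustive
diameter.

## Ensemble statistics

* **Robustness.**  R_μ per sampled genotype via knockout screens; with
  several environments a reaction counts as essential if essential in any
  of them.  The binomial-normal approximation treats the n − s
  non-super-essential reactions as independent Bernoulli trials with
  non-essentiality probability p = n·r/(n−s), giving variance
  p(1−p)(n−s)/n²; when the observed mean pushes p outside [0, 1] the
  approximation is flagged rather than clamped.  Histogram bins default to
  width 1/n (single-reaction resolution).  Reference-genotype comparisons
  report the add-one empirical tail p-value, so the minimum reportable p
  is 1/(m+1).
* **Distances.**  Mean and max pairwise Hamming distance; the
  unconstrained-space references are the closed forms 2n(N−n)/N (mean over
  independent uniform pairs in Ω(n)) and 2·min(n, N−n) (maximum).
* **Occurrence.**  Per-reaction occurrence, essential and blocked
  frequencies over the sample; ranks by descending occurrence with ties
  broken lexicographically by reaction id for determinism.  Rank
  histograms are fitted to a + b·exp(−c·r) and a + b·r^(−c) by nonlinear
  least squares; initialization takes a from the mean occurrence of the
  bottom rank decile and b, c from a log-linear regression of the
  residual, which makes convergence reproducible.  Degenerate (zero
  variance) input and non-convergence return flagged results.
* **PCA / clustering.**  Column-centered PCA with the full SVD solver;
  component signs are pinned by making each component's
  largest-magnitude loading positive.  Hierarchical clustering is average
  linkage (inter-cluster distance = mean cross-cluster pairwise distance)
  on Hamming distances.
* **Permutation test.**  D* is the sum of pairwise Euclidean distances
  between cloud centers of mass, computed by default in the full
  N-dimensional binary space: the full-space statistic is
  permutation-invariant by construction, whereas PCA axes depend on the
  pooled sample.  A `pca_plane` switch provides the first-two-PC variant.
  Labels are shuffled preserving cloud sizes; p-values use the add-one
  convention (minimum 1/(K+1) at K permutations).
* **Multi-environment.**  A sample uniform on V_i(n), scored for
  viability in environment j, estimates P(i,j)/P(i); quotients of two such
  estimates give size ratios P(j)/P(i) with errors propagated in
  quadrature from block-jackknife standard errors.  Zero-denominator
  ratios are flagged as unbounded rather than reported as numbers.
  Joint-viability sampling uses a single chain accepting only genotypes
  viable in all environments, which is far more efficient than
  rejection-filtering when the overlap is small.  Absolute P(i,j) values
  are out of scope; only ratios are produced.

## Synthetic fixtures and what they show

The fixture generator builds universes from the structural motifs that
shape real viable spaces: dedicated uptake reactions (super-essential
bottlenecks), `redundancy` parallel one- or two-step paths from a hub
metabolite to each biomass precursor (non-essential redundancy), a single
biomass-assembly reaction, and decoy reactions with unproducible
substrates (blocked everywhere).  Ground truth — super-essential sets,
blocked sets, |V(n)|, diameters, swap-connectivity — is computed by
exhaustive enumeration with a *fresh* LP per subset (columns physically
removed), a deliberately independent code path from the production model;
a boolean reachability oracle, exact for these unit-coefficient
single-product universes, provides a third route.  Universes are capped at
N ≤ 22 and enumerations at 10⁶ subsets.

These fixtures validate correctness of the algorithms, not genome-scale
phenomenology: they have no cofactor coupling, no byproduct-disposal
constraints, no compartments, and their viable fractions are many orders
of magnitude larger than realistic ones.  Passing tests show that the
estimators are unbiased and the sampler uniform where enumeration can
check them — not that any particular organism-scale number is reproduced.

## Problem sizes in the test suite

The oracle-equivalence sweep uses the canonical N = 9 universe plus 20
generated universes with N between 5 and 14 (all 2^N subsets checked
against the fresh-LP oracle); uniformity tests use 10⁵ kept states on an
enumerated 8-member space; multi-environment comparisons run 1.26×10⁵-step
chains thinned to near-independence; permutation-test calibration uses 200
null replicates of 400 permutations.  These sizes were chosen to give the
statistical power the assertions need on a single CPU.

## Known limitations

* Uniformity is guaranteed only on the swap-connected component of V(n).
* The τ estimator needs a saturating distance trace; very short chains
  return not-converged instead of a value.
* Wilson intervals on chain-derived fractions assume near-independent
  kept states; users should thin by several τ (the multi-environment
  helpers propagate jackknife errors as a correlation-aware alternative).
* The FVA blocked-reaction screen inherits the no-loop-law choice; in
  universes with thermodynamically infeasible cycles it can report a
  loop-only reaction as unblocked.
* Elemental balance of reaction equations is accepted as given and not
  checked.
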