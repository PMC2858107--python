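"""Estimating the viable fraction P_n = |V(n)| / |Omega(n)|.

Omega(n), the set of all genotypes with exactly n of the universe's N
reactions, contains C(N, n) genotypes; its viable subset V(n) is
vanishingly small at moderate n, far below the reach of naive Monte
Carlo.  The estimator therefore factorizes

    P_n = Pr[contains all s super-essential reactions]
          x Pr[viable | contains all super-essential reactions].

The first factor is the exact combinatorial prefactor
B(N-s, n-s) / B(N, n) (B the binomial coefficient); the second is
estimated by sampling genotypes built by seeding the super-essential set
and filling up to n reactions at random.  All probability arithmetic is
carried in log10: the fractions of interest underflow double precision
on realistic universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .fba import ViabilityEvaluator
from .genotypes import Genotype, random_genotype
from .universe import BiomassObjective, Environment, ReactionUniverse

#: Above this N the exact big-integer binomials give way to lgamma.
EXACT_BINOMIAL_LIMIT = 10_000

#: Default number of conditional samples (overridable everywhere).
DEFAULT_NUM_SAMPLES = 10**6


@dataclass(frozen=True)
class OmegaSize:
    """Exact size of Omega(n): the binomial coefficient C(N, n)."""

    n: int
    N: int

    @property
    def count(self) -> int:
        return math.comb(self.N, self.n)


@dataclass
class FractionEstimate:
    """Decomposed estimate of P_n (log10 scale).

    ``conditional_estimate`` of 0 is reported as a rule-of-three upper
    bound (``is_upper_bound`` True): with zero viable hits in k samples
    the 95% upper confidence limit is about 3/k, and log10 P_n carries
    that bound rather than -inf.
    """

    n: int
    s: int
    log10_prefactor: float
    conditional_estimate: float
    conditional_ci: tuple[float, float]
    log10_P_n: float
    sample_size: int
    viable_hits: int
    is_upper_bound: bool = False


def prefactor(N: int, s: int, n: int) -> tuple[float, float]:
    """Probability that a uniform size-n genotype contains all s marked
    reactions.

    Returns ``(value, log10_value)`` with the value computed as
    B(N-s, n-s)/B(N, n); exact big-integer arithmetic below
    ``EXACT_BINOMIAL_LIMIT``, log-gamma above.  For n < s the probability
    is zero (no size-n genotype can contain all s reactions).
    """
    if not 0 <= s <= N or n > N or n < 0:
        raise ValueError(f"need 0 <= s <= N and 0 <= n <= N; got N={N}, s={s}, n={n}")
    if n < s:
        return 0.0, -math.inf
    if N <= EXACT_BINOMIAL_LIMIT:
        frac = Fraction(math.comb(N - s, n - s), math.comb(N, n))
        log10 = (
            -math.inf
            if frac == 0
            else math.log10(frac.numerator) - math.log10(frac.denominator)
        )
        return float(frac), log10

    def logc(p: int, q: int) -> float:
        return (
            math.lgamma(p + 1) - math.lgamma(q + 1) - math.lgamma(p - q + 1)
        ) / math.log(10)

    log10 = logc(N - s, n - s) - logc(N, n)
    return 10.0**log10 if log10 > -300 else 0.0, log10


def prefactor_exact(N: int, s: int, n: int) -> Fraction:
    """Exact rational prefactor (for identity checks on small universes)."""
    if n < s:
        return Fraction(0)
    return Fraction(math.comb(N - s, n - s), math.comb(N, n))


def wilson_interval(hits: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(hits, trials, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def _super_essential_indices(evaluator: ViabilityEvaluator) -> frozenset[int]:
    return evaluator.essential_indices(Genotype.full(evaluator.universe.N))


def conditional_viability(
    universe: ReactionUniverse,
    environment: Environment,
    biomass: BiomassObjective,
    n: int,
    num_samples: int = DEFAULT_NUM_SAMPLES,
    seed: int = 0,
    evaluator: ViabilityEvaluator | None = None,
) -> tuple[float, tuple[float, float], int]:
    """Estimate Pr[viable | contains all super-essential reactions].

    Draws ``num_samples`` genotypes that contain the super-essential set
    plus n - s uniform extra reactions and returns (fraction viable,
    Wilson 95% CI, viable hits).
    """
    if num_samples <= 0:
        raise ValueError("num_samples must be positive")
    ev = evaluator or ViabilityEvaluator(universe, environment, biomass)
    required = _super_essential_indices(ev)
    if n < len(required):
        raise ValueError(f"n={n} below super-essential count s={len(required)}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(num_samples):
        g = random_genotype(universe.N, n, required=required, seed=rng)
        hits += ev.viable(g)
    est = hits / num_samples
    return est, wilson_interval(hits, num_samples), hits


def estimate_fraction(
    universe: ReactionUniverse,
    environment: Environment,
    biomass: BiomassObjective,
    n: int,
    num_samples: int = DEFAULT_NUM_SAMPLES,
    seed: int = 0,
    evaluator: ViabilityEvaluator | None = None,
) -> FractionEstimate:
    """Two-factor estimate of P_n: analytic prefactor x sampled conditional."""
    ev = evaluator or ViabilityEvaluator(universe, environment, biomass)
    s = len(_super_essential_indices(ev))
    _, log10_pre = prefactor(universe.N, s, n)
    est, ci, hits = conditional_viability(
        universe, environment, biomass, n, num_samples, seed, evaluator=ev
    )
    if hits == 0:
        cond_bound = 3.0 / num_samples  # rule of three
        return FractionEstimate(
            n, s, log10_pre, 0.0, ci, log10_pre + math.log10(cond_bound),
            num_samples, 0, is_upper_bound=True,
        )
    return FractionEstimate(
        n, s, log10_pre, est, ci, log10_pre + math.log10(est), num_samples, hits
    )


def direct_fraction(
    universe: ReactionUniverse,
    environment: Environment,
    biomass: BiomassObjective,
    n: int,
    num_samples: int = DEFAULT_NUM_SAMPLES,
    seed: int = 0,
    evaluator: ViabilityEvaluator | None = None,
) -> tuple[float, tuple[float, float], int]:
    """Naive Monte-Carlo estimate of P_n over uniform Omega(n) draws.

    Only informative when P_n is within reach of the sample size; zero
    hits yield estimate 0 with the Wilson upper bound as the CI.
    """
    if num_samples <= 0:
        raise ValueError("num_samples must be positive")
    ev = evaluator or ViabilityEvaluator(universe, environment, biomass)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(num_samples):
        g = random_genotype(universe.N, n, seed=rng)
        hits += ev.viable(g)
    return hits / num_samples, wilson_interval(hits, num_samples), hits
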