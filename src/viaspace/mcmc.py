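"""Fixed-n reaction-swap MCMC over viable genotypes.

The sampler walks the viable space V(n) with *reaction swaps*: one present
reaction out, one absent reaction in, so the reaction count n is invariant.
A proposed swap is accepted iff the new genotype is viable (in every
configured environment); otherwise the walk stays where it is.  Because
the proposal distribution is symmetric (each legal (out, in) pair and its
reverse are equally likely), accept-iff-viable is Metropolis sampling of
the *uniform* distribution on the accessible component of V(n) — no
Hastings correction is needed.

Super-essential reactions can never be swapped out of a viable genotype,
so freezing them (the default) shrinks the proposal space and raises the
acceptance rate A without changing the stationary distribution.

Diagnostics follow standard MCMC practice: the autocorrelation time tau
is read off the saturation of the Hamming distance to the chain start
(with the heuristic expectation tau = n/A), and errors of sample averages
use block jackknife over consecutive saved states.

The *two-headed walk* lower-bounds the diameter of V(n): two coupled
viability-preserving walks accept swaps only when their mutual Hamming
distance does not decrease, and the largest distance reached over
replicates is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NoLegalSwapError, NonViableError
from .fba import FbaModel, ViabilityEvaluator
from .genotypes import Genotype, hamming
from .universe import BiomassObjective, Environment, ReactionUniverse


@dataclass
class McmcConfig:
    """Chain parameters; total_steps includes the burn-in phase."""

    n: int
    environments: Sequence[Environment]
    total_steps: int = 10**6
    burn_in: int = 10**5
    thinning: int = 10**3
    seed: int = 0
    freeze_super_essential: bool = True
    viability_mode: str = "positive"
    reference_flux: float | None = None

    def __post_init__(self) -> None:
        if not self.environments:
            raise ValueError("at least one environment required")
        if not 0 <= self.burn_in < self.total_steps:
            raise ValueError("need 0 <= burn_in < total_steps")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class SampleSet:
    """Thinned sample of viable genotypes with its provenance."""

    genotypes: list[Genotype]
    config: McmcConfig
    acceptance: float
    universe_id: str
    environment_ids: tuple[str, ...]


@dataclass
class ChainDiagnostics:
    """Distance-to-start trace and derived autocorrelation estimates."""

    distance_trace: np.ndarray  # columns: step, Hamming distance to start
    acceptance: float
    expected_tau: float  # heuristic n / A
    tau: float | None = None
    converged: bool = False


@dataclass
class DiameterEstimate:
    """Lower bound on the diameter of the accessible space."""

    max_distance: int
    replicate_values: list[int]
    steps_used: list[int]
    converged: list[bool]


@dataclass
class AutocorrelationResult:
    tau: float | None
    plateau: float
    converged: bool


def _evaluator(universe, biomass, config) -> ViabilityEvaluator:
    return ViabilityEvaluator(
        universe,
        list(config.environments),
        biomass,
        mode=config.viability_mode,
        reference_flux=config.reference_flux,
    )


def _joint_super_essential(evaluator: ViabilityEvaluator) -> frozenset[int]:
    """Union of per-environment super-essential index sets."""
    full = Genotype.full(evaluator.universe.N)
    out: set[int] = set()
    for env in evaluator.environments:
        sub = ViabilityEvaluator(evaluator.universe, env, evaluator.biomass,
                                 evaluator.mode, evaluator.reference_flux)
        out |= sub.essential_indices(full)
    return frozenset(out)


def initial_viable_genotype(
    universe: ReactionUniverse,
    environments: Environment | Sequence[Environment],
    biomass: BiomassObjective,
    n: int,
    seed: int | np.random.Generator = 0,
    reference_genotype: Genotype | None = None,
) -> Genotype:
    """Viable size-n starting genotype from an optimal flux support.

    Takes the support (|flux| > tolerance) of an optimal FBA solution of
    the reference genotype (default: the full universe) in each
    environment, unions the supports, and pads with uniformly random
    absent reactions up to n bits.  Restriction to a support preserves
    that optimal flux vector, so the result is viable by monotonicity.
    """
    if isinstance(environments, Environment):
        environments = [environments]
    reference = reference_genotype or Genotype.full(universe.N)
    support: set[int] = set()
    for env in environments:
        model = FbaModel(universe, env, biomass)
        sol = model.maximize_biomass(reference)
        if sol.status != "optimal" or sol.objective <= model.eps:
            raise NonViableError(
                f"reference genotype non-viable in environment {env.id!r}"
            )
        support |= {i for i, v in enumerate(sol.fluxes) if abs(v) > 1e-7}
    if n < len(support):
        raise NonViableError(
            f"n={n} below the optimal-flux support size {len(support)}; "
            "increase n"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .genotypes import random_genotype

    return random_genotype(universe.N, n, required=support, seed=rng)


def run_chain(
    universe: ReactionUniverse,
    biomass: BiomassObjective,
    config: McmcConfig,
    evaluator: ViabilityEvaluator | None = None,
    initial: Genotype | None = None,
    trace_points: int = 2000,
) -> tuple[SampleSet, ChainDiagnostics]:
    """Run the fixed-n swap chain; returns the thinned sample and diagnostics.

    After discarding ``burn_in`` steps, every ``thinning``-th genotype is
    stored; the acceptance rate is computed over post-burn-in proposals.
    Rejected proposals repeat the current genotype (the walk "stays").
    Identical config and seed give an identical sample.
    """
    ev = evaluator or _evaluator(universe, biomass, config)
    rng = np.random.default_rng(config.seed)
    frozen = (
        _joint_super_essential(ev) if config.freeze_super_essential else frozenset()
    )
    current = initial if initial is not None else initial_viable_genotype(
        universe, list(config.environments), biomass, config.n, seed=rng
    )
    if current.n != config.n:
        raise ValueError("initial genotype has wrong reaction count")
    if not ev.viable(current):
        raise NonViableError("initial genotype is not viable")

    N = universe.N
    present_free = np.array(
        [i for i in current.present_indices if i not in frozen], dtype=np.int64
    )
    absent = np.array(current.absent_indices, dtype=np.int64)
    if len(present_free) == 0 or len(absent) == 0:
        raise NoLegalSwapError("chain has no legal swaps (n=N or all bits frozen)")

    start = current
    mask = current.mask
    kept: list[Genotype] = []
    trace_stride = max(1, config.total_steps // trace_points)
    trace: list[tuple[int, int]] = [(0, 0)]
    accepted = proposals = 0

    n_free = len(present_free)
    n_abs = len(absent)
    for step in range(1, config.total_steps + 1):
        i = rng.integers(n_free)
        j = rng.integers(n_abs)
        out_bit, in_bit = int(present_free[i]), int(absent[j])
        new_mask = (mask ^ (1 << out_bit)) | (1 << in_bit)
        ok = ev.viable(Genotype(new_mask, N))
        if step > config.burn_in:
            proposals += 1
            accepted += ok
        if ok:
            mask = new_mask
            present_free[i], absent[j] = in_bit, out_bit
        if step % trace_stride == 0:
            trace.append((step, (mask ^ start.mask).bit_count()))
        if step > config.burn_in and (step - config.burn_in) % config.thinning == 0:
            kept.append(Genotype(mask, N))

    A = accepted / proposals if proposals else 0.0
    sample = SampleSet(
        kept, config, A, universe.id, tuple(e.id for e in config.environments)
    )
    diag = ChainDiagnostics(
        distance_trace=np.array(trace, dtype=float),
        acceptance=A,
        expected_tau=config.n / A if A > 0 else math.inf,
    )
    ac = autocorrelation_time(diag.distance_trace)
    diag.tau, diag.converged = ac.tau, ac.converged
    return sample, diag


def autocorrelation_time(distance_trace: np.ndarray) -> AutocorrelationResult:
    """Autocorrelation time from the saturation of a distance-to-start trace.

    The plateau is the mean distance over the final half of the trace; tau
    is the first step at which the trace reaches (1 - 1/e) of the plateau.
    The trace counts as converged only when that crossing happens in its
    first half (i.e. the walk saturated well before the end) and the
    plateau is positive.
    """
    t = np.asarray(distance_trace, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or len(t) < 4:
        raise ValueError("distance_trace must be a (k >= 4) x 2 array of (step, d)")
    steps, d = t[:, 0], t[:, 1]
    half = len(t) // 2
    plateau = float(d[half:].mean())
    if plateau <= 0:
        return AutocorrelationResult(None, plateau, False)
    # a still-rising trace has no plateau: the two final quarters must agree
    q3 = float(d[half: 3 * len(t) // 4].mean())
    q4 = float(d[3 * len(t) // 4:].mean())
    if abs(q4 - q3) > 0.1 * plateau:
        return AutocorrelationResult(None, plateau, False)
    target = (1.0 - 1.0 / math.e) * plateau
    crossing = np.nonzero(d >= target)[0]
    if len(crossing) == 0 or crossing[0] >= half:
        return AutocorrelationResult(None, plateau, False)
    return AutocorrelationResult(float(steps[crossing[0]]), plateau, True)


@dataclass
class JackknifeResult:
    errors: dict[int, float]  # window size -> standard error of the mean
    plateau: float  # error at the largest window


def jackknife_error(
    series: Sequence[float], window_sizes: Sequence[int]
) -> JackknifeResult:
    """Block-jackknife standard error of the mean for correlated samples.

    For window size w the series is cut into ``len // w`` consecutive
    blocks; the delete-one-block jackknife gives the standard error of
    the overall mean.  Windows must stay well below the series length
    (w < len/2 is enforced); the error at the largest window is reported
    as the plateau value.
    """
    x = np.asarray(series, dtype=float)
    errors: dict[int, float] = {}
    for w in window_sizes:
        if w < 1 or w >= len(x) / 2:
            raise ValueError(f"window {w} must satisfy 1 <= w < len(series)/2")
        nb = len(x) // w
        blocks = x[: nb * w].reshape(nb, w)
        total = blocks.sum()
        leave_out_means = (total - blocks.sum(axis=1)) / ((nb - 1) * w)
        center = leave_out_means.mean()
        var = (nb - 1) / nb * np.sum((leave_out_means - center) ** 2)
        errors[w] = float(np.sqrt(var))
    return JackknifeResult(errors, errors[max(window_sizes)])


def two_headed_walk(
    universe: ReactionUniverse,
    biomass: BiomassObjective,
    config: McmcConfig,
    replicates: int = 5,
    evaluator: ViabilityEvaluator | None = None,
) -> DiameterEstimate:
    """Lower-bound the diameter of V(n) with coupled diverging walks.

    Two independent viable genotypes take turns proposing swaps; a swap is
    accepted iff the new genotype is viable and the inter-head Hamming
    distance does not decrease (distance-preserving swaps are accepted).
    A replicate stops early once the distance has not increased during the
    most recent third of its elapsed steps, and is capped at
    ``config.total_steps``.  Replicate r uses seed + r; the maximum final
    distance over replicates is returned.
    """
    ev = evaluator or _evaluator(universe, biomass, config)
    frozen = (
        _joint_super_essential(ev) if config.freeze_super_essential else frozenset()
    )
    N = universe.N
    values: list[int] = []
    steps_used: list[int] = []
    converged: list[bool] = []
    for r in range(replicates):
        rng = np.random.default_rng(config.seed + r)
        heads = [
            initial_viable_genotype(
                universe, list(config.environments), biomass, config.n, seed=rng
            )
            for _ in range(2)
        ]
        state = []
        for g in heads:
            pf = np.array([i for i in g.present_indices if i not in frozen], dtype=np.int64)
            ab = np.array(g.absent_indices, dtype=np.int64)
            state.append({"mask": g.mask, "pf": pf, "ab": ab})
        if len(state[0]["pf"]) == 0 or len(state[0]["ab"]) == 0:
            values.append(0)
            steps_used.append(0)
            converged.append(True)
            continue
        dist = (state[0]["mask"] ^ state[1]["mask"]).bit_count()
        last_increase = 0
        step = 0
        min_steps = 60  # let the walk leave the start before testing stagnation
        while step < config.total_steps:
            step += 1
            h = state[step % 2]
            other = state[(step + 1) % 2]
            i = rng.integers(len(h["pf"]))
            j = rng.integers(len(h["ab"]))
            out_bit, in_bit = int(h["pf"][i]), int(h["ab"][j])
            new_mask = (h["mask"] ^ (1 << out_bit)) | (1 << in_bit)
            new_dist = (new_mask ^ other["mask"]).bit_count()
            if new_dist >= dist and ev.viable(Genotype(new_mask, N)):
                h["mask"] = new_mask
                h["pf"][i], h["ab"][j] = in_bit, out_bit
                if new_dist > dist:
                    last_increase = step
                dist = new_dist
            if step >= min_steps and (step - last_increase) >= step / 3:
                break
        values.append(dist)
        steps_used.append(step)
        converged.append(step < config.total_steps)
    return DiameterEstimate(max(values), values, steps_used, converged)
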