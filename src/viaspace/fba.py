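"""Flux balance analysis core.

Viability of a metabolic genotype is decided by linear programming:
maximize the biomass flux Z = c·v subject to steady-state mass balance
S·v = 0 and flux bounds a ≤ v ≤ b.  A genotype is *viable* in an
environment when its maximum biomass flux is strictly positive (up to a
scale-relative tolerance), i.e. it can synthesize every biomass compound
at some positive rate.

The LP skeleton for a (universe, environment, biomass) triple is built
once; a genotype is imposed by zeroing the flux bounds of absent
reactions, which is contract-equivalent to deleting the corresponding
columns of S.  Implicit exchange columns connect external metabolites to
the boundary: the carbon source with capped uptake and free secretion,
unlimited inorganics in both directions, all other external metabolites
secretion-only (or closed if not secretable).

Derived screens built on the same LP:

* essential reactions — single knock-outs that abolish viability;
* super-essential reactions — essential for the full universe, hence
  essential for every viable genotype;
* blocked reactions — flux variability analysis at positive biomass
  finds no attainable flux;
* mutational robustness R_mu — fraction of present reactions that are
  not essential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import NonViableError, SolverError
from .genotypes import Genotype
from .universe import (
    DEFAULT_FLUX_BOUND,
    BiomassObjective,
    Environment,
    ReactionUniverse,
)

#: Relative factor separating "strictly positive" biomass from LP round-off.
VIABILITY_EPS_FACTOR = 1e-9

#: Absolute flux magnitude below which a reaction counts as blocked in FVA.
FVA_FLUX_TOL = 1e-6


@dataclass
class FluxSolution:
    """Outcome of one biomass-maximization LP.

    ``fluxes`` is indexed by universe reaction order; exchange and biomass
    drain fluxes are internal columns and are not exposed here.  The LP data
    (objective vector and bounds actually used, over all columns) is echoed
    for audit.
    """

    fluxes: np.ndarray
    objective: float
    status: str  # optimal | infeasible | unbounded | numerical_failure
    objective_vector: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray


@dataclass(frozen=True)
class ViabilityResult:
    viable: bool
    biomass_flux: float
    threshold_used: float


@dataclass(frozen=True)
class EssentialitySummary:
    """Essential and blocked reaction sets of one viable genotype."""

    essential: frozenset[str]
    blocked: frozenset[str]
    robustness: float


class FbaModel:
    """LP skeleton for one (universe, environment, biomass) triple."""

    def __init__(
        self,
        universe: ReactionUniverse,
        environment: Environment,
        biomass: BiomassObjective,
    ):
        environment.validate_against(universe)
        self.universe = universe
        self.environment = environment
        self.biomass = biomass
        self.eps = VIABILITY_EPS_FACTOR * environment.carbon_uptake_limit

        mets = sorted(universe.metabolites | set(biomass.composition))
        self._met_index = {m: i for i, m in enumerate(mets)}
        externals = sorted(universe.external_metabolites)
        N = universe.N
        n_cols = N + len(externals) + 1
        self._n_reactions = N
        self._biomass_col = n_cols - 1

        A = np.zeros((len(mets), n_cols))
        lo = np.zeros(n_cols)
        hi = np.zeros(n_cols)
        for j, r in enumerate(universe.reactions):
            for m, c in r.stoichiometry.items():
                A[self._met_index[m], j] = c
            lo[j], hi[j] = r.bounds
        U = DEFAULT_FLUX_BOUND
        for k, m in enumerate(externals):
            j = N + k
            A[self._met_index[m], j] = -1.0  # positive flux = secretion
            if m == environment.carbon_source:
                lo[j], hi[j] = -environment.carbon_uptake_limit, U
            elif m in environment.unlimited:
                lo[j], hi[j] = -U, U
            elif environment.secretable is None or m in environment.secretable:
                lo[j], hi[j] = 0.0, U
            else:
                lo[j], hi[j] = 0.0, 0.0
        for m, p in biomass.composition.items():
            A[self._met_index[m], self._biomass_col] = -p
        lo[self._biomass_col], hi[self._biomass_col] = 0.0, U

        self._A = A
        self._lo = lo
        self._hi = hi
        self._c = np.zeros(n_cols)
        self._c[self._biomass_col] = 1.0
        self._b_eq = np.zeros(len(mets))

    # -- internals ---------------------------------------------------------
    def _genotype_bounds(self, genotype: Genotype) -> tuple[np.ndarray, np.ndarray]:
        lo = self._lo.copy()
        hi = self._hi.copy()
        if genotype.n < genotype.N:
            absent = np.fromiter(genotype.absent_indices, dtype=np.int64)
            lo[absent] = 0.0
            hi[absent] = 0.0
        return lo, hi

    def _solve(
        self,
        c: np.ndarray,
        lo: np.ndarray,
        hi: np.ndarray,
        maximize: bool,
        A_ub: np.ndarray | None = None,
        b_ub: np.ndarray | None = None,
    ):
        res = linprog(
            -c if maximize else c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self._A,
            b_eq=self._b_eq,
            bounds=np.column_stack([lo, hi]),
            method="highs",
        )
        return res

    # -- public ------------------------------------------------------------
    def maximize_biomass(self, genotype: Genotype) -> FluxSolution:
        if genotype.N != self.universe.N:
            raise ValueError("genotype length does not match universe size")
        lo, hi = self._genotype_bounds(genotype)
        res = self._solve(self._c, lo, hi, maximize=True)
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(
            res.status, "numerical_failure"
        )
        fluxes = (
            res.x[: self._n_reactions]
            if res.x is not None
            else np.full(self._n_reactions, np.nan)
        )
        Z = -res.fun if status == "optimal" else np.nan
        return FluxSolution(fluxes, Z, status, self._c.copy(), lo, hi)

    def biomass_flux(self, genotype: Genotype) -> float:
        sol = self.maximize_biomass(genotype)
        if sol.status != "optimal":
            raise SolverError(
                f"LP did not solve (status={sol.status}) for genotype with "
                f"n={genotype.n} in environment {self.environment.id!r}"
            )
        return sol.objective

    def viable(
        self,
        genotype: Genotype,
        mode: str = "positive",
        reference_flux: float | None = None,
    ) -> ViabilityResult:
        Z = self.biomass_flux(genotype)
        if mode == "positive":
            threshold = self.eps
            return ViabilityResult(Z > threshold, Z, threshold)
        if mode == "at_least":
            if reference_flux is None:
                raise ValueError("at_least mode requires a reference flux")
            slack = 1e-9 * max(1.0, abs(reference_flux))
            return ViabilityResult(Z >= reference_flux - slack, Z, reference_flux)
        raise ValueError(f"unknown viability mode {mode!r}")

    def flux_range(
        self, genotype: Genotype, reaction_index: int, biomass_min: float | None = None
    ) -> tuple[float, float]:
        """Attainable flux range of one reaction (FVA), optionally at
        biomass flux >= biomass_min."""
        lo, hi = self._genotype_bounds(genotype)
        A_ub = b_ub = None
        if biomass_min is not None:
            A_ub = -self._c[None, :]
            b_ub = np.array([-biomass_min])
        c = np.zeros_like(self._c)
        c[reaction_index] = 1.0
        out = []
        for maximize in (False, True):
            res = self._solve(c, lo, hi, maximize=maximize, A_ub=A_ub, b_ub=b_ub)
            if res.status != 0:
                raise SolverError(
                    f"FVA LP failed (status={res.status}) for reaction index "
                    f"{reaction_index}"
                )
            out.append(-res.fun if maximize else res.fun)
        return out[0], out[1]


class ViabilityEvaluator:
    """Memoized joint-viability oracle over one or more environments.

    Viability of a genotype (all environments simultaneously) is cached by
    bitmask, which makes knock-out screens, Monte-Carlo estimators and MCMC
    chains on small universes nearly free after warm-up.
    """

    def __init__(
        self,
        universe: ReactionUniverse,
        environments: Environment | Sequence[Environment],
        biomass: BiomassObjective,
        mode: str = "positive",
        reference_flux: float | None = None,
        max_cache_entries: int = 500_000,
    ):
        if isinstance(environments, Environment):
            environments = [environments]
        if not environments:
            raise ValueError("at least one environment required")
        self.universe = universe
        self.environments = list(environments)
        self.biomass = biomass
        self.mode = mode
        self.reference_flux = reference_flux
        self.models = [FbaModel(universe, e, biomass) for e in self.environments]
        self._cache: dict[int, bool] = {}
        self._max_cache = max_cache_entries

    def viable(self, genotype: Genotype) -> bool:
        mask = genotype.mask
        hit = self._cache.get(mask)
        if hit is not None:
            return hit
        ok = all(
            m.viable(genotype, self.mode, self.reference_flux).viable
            for m in self.models
        )
        if len(self._cache) >= self._max_cache:
            self._cache.clear()
        self._cache[mask] = ok
        return ok

    def essential_indices(self, genotype: Genotype) -> frozenset[int]:
        """Indices whose single knock-out abolishes joint viability."""
        if not self.viable(genotype):
            raise NonViableError("essentiality screen requires a viable genotype")
        ess = []
        for i in genotype.present_indices:  # universe order
            if not self.viable(genotype.with_bit(i, False)):
                ess.append(i)
        return frozenset(ess)

    def robustness(self, genotype: Genotype) -> float:
        """R_mu = 1 − |essential| / n over the joint environment set."""
        return 1.0 - len(self.essential_indices(genotype)) / genotype.n


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def maximize_biomass(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
) -> FluxSolution:
    return FbaModel(universe, environment, biomass).maximize_biomass(genotype)


def is_viable(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
    mode: str = "positive",
    reference_flux: float | None = None,
) -> ViabilityResult:
    return FbaModel(universe, environment, biomass).viable(genotype, mode, reference_flux)


def essential_reactions(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
) -> set[str]:
    """Present reactions whose single removal makes the genotype non-viable."""
    ev = ViabilityEvaluator(universe, environment, biomass)
    ids = universe.reaction_ids
    return {ids[i] for i in ev.essential_indices(genotype)}


def super_essential_reactions(
    universe: ReactionUniverse,
    environment: Environment,
    biomass: BiomassObjective,
) -> set[str]:
    """Reactions essential for the genotype containing the whole universe.

    Such a reaction is necessarily essential in every viable genotype of
    this environment, so no viable genotype can lack it.
    """
    full = Genotype.full(universe.N)
    model = FbaModel(universe, environment, biomass)
    if not model.viable(full).viable:
        raise NonViableError(
            f"full universe non-viable in environment {environment.id!r}; "
            "no viable space exists at any n"
        )
    return essential_reactions(universe, full, environment, biomass)


def blocked_reactions(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
) -> set[str]:
    """Present reactions that cannot carry flux at positive biomass.

    Flux variability analysis: maximize (and for reversible reactions also
    minimize) each present reaction's flux subject to steady state, bounds
    and biomass flux >= eps.  A reaction is blocked when the attainable
    magnitude stays below tolerance; blocked and essential sets are
    disjoint by construction.
    """
    model = FbaModel(universe, environment, biomass)
    if not model.viable(genotype).viable:
        raise NonViableError("blocked-reaction screen requires a viable genotype")
    blocked = set()
    for i in genotype.present_indices:
        rxn = universe.reactions[i]
        fmin, fmax = model.flux_range(genotype, i, biomass_min=model.eps)
        reach = max(fmax, 0.0)
        if rxn.reversible:
            reach = max(reach, -min(fmin, 0.0))
        if reach <= FVA_FLUX_TOL:
            blocked.add(rxn.id)
    return blocked


def mutational_robustness(
    universe: ReactionUniverse,
    genotype: Genotype,
    environments: Environment | Sequence[Environment],
    biomass: BiomassObjective,
) -> float:
    """Fraction of present reactions non-essential in every environment.

    With several environments the union of the per-environment essential
    sets is used, i.e. a reaction counts as essential if it is essential
    in at least one of them.
    """
    if isinstance(environments, Environment):
        environments = [environments]
    essential: set[int] = set()
    for env in environments:
        ev = ViabilityEvaluator(universe, env, biomass)
        essential |= ev.essential_indices(genotype)
    return 1.0 - len(essential) / genotype.n


def essentiality_summary(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
) -> EssentialitySummary:
    ess = essential_reactions(universe, genotype, environment, biomass)
    blk = blocked_reactions(universe, genotype, environment, biomass)
    return EssentialitySummary(
        frozenset(ess), frozenset(blk), 1.0 - len(ess) / genotype.n
    )
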