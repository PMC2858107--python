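"""Synthetic reaction universes with exhaustively known ground truth.

Real genome-scale reaction universes are far too large to enumerate, so
every estimator in this package is validated on small designed universes
(N <= ~22) whose viable spaces V(n) can be listed outright.  The designs
emulate the structural features that shape real viable spaces:

* dedicated nutrient-uptake reactions (super-essential bottlenecks),
* redundant parallel pathways to biomass precursors (non-essential
  reactions),
* a single biomass-assembly reaction (super-essential), and
* blocked decoy reactions whose substrates are unproducible.

Two *independent* viability oracles live here so the streamlined FBA path
can be cross-checked rather than trusted:

* :func:`subset_viable_lp` rebuilds a fresh LP per subset with the absent
  reaction columns physically removed (not bound-zeroed);
* :func:`reachability_viable` is a boolean forward-closure oracle, exact
  for the all-unit-coefficient, single-product universes generated here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import EnumerationBudgetError, UniverseFormatError
from .genotypes import Genotype, hamming
from .universe import (
    DEFAULT_CARBON_UPTAKE,
    DEFAULT_FLUX_BOUND,
    BiomassObjective,
    Environment,
    Reaction,
    ReactionUniverse,
)

#: Hard cap on the number of subsets an exhaustive enumeration may visit.
ENUMERATION_BUDGET = 10**6


# ---------------------------------------------------------------------------
# Canonical hand-written fixtures
# ---------------------------------------------------------------------------

def toy9() -> tuple[ReactionUniverse, Environment, BiomassObjective]:
    """The canonical 9-reaction fixture.

    A linear trunk C_ext -> A with two biomass precursors P1, P2, each
    producible directly from A or via the hub B (redundant paths), a
    biomass-assembly reaction, a blocked decoy R8 (its substrate X is
    unproducible), and a back-reaction B -> A.  Super-essential reactions
    are R1 (sole uptake path) and R7 (biomass assembly).
    """
    reactions = (
        Reaction("R1", {"C_ext": -1, "A": 1}),
        Reaction("R2", {"A": -1, "P1": 1}),
        Reaction("R3", {"A": -1, "B": 1}),
        Reaction("R4", {"B": -1, "P1": 1}),
        Reaction("R5", {"A": -1, "P2": 1}),
        Reaction("R6", {"B": -1, "P2": 1}),
        Reaction("R7", {"P1": -1, "P2": -1, "BM_ext": 1}),
        Reaction("R8", {"X": -1, "Y": 1}),
        Reaction("R9", {"B": -1, "A": 1}),
    )
    universe = ReactionUniverse(reactions, id="toy9")
    env = Environment(id="toy9_env", carbon_source="C_ext")
    biomass = BiomassObjective({"BM_ext": 1.0}, id="toy9_biomass")
    return universe, env, biomass


def toy9_two_carbon() -> tuple[
    ReactionUniverse, Environment, Environment, BiomassObjective
]:
    """Two-carbon-source variant of the canonical fixture (N=11).

    A second carbon source C2_ext feeds the decoy branch (R10: C2_ext -> X)
    and the branch is given an outlet into the trunk (R11: Y -> A).  In the
    C2 environment the sole route to biomass runs through R10, R8 and R11;
    in the C_ext environment those three reactions are blocked but not
    removable because the second environment unblocks them.
    """
    base, env1, biomass = toy9()
    reactions = base.reactions + (
        Reaction("R10", {"C2_ext": -1, "X": 1}),
        Reaction("R11", {"Y": -1, "A": 1}),
    )
    universe = ReactionUniverse(reactions, id="toy11")
    env2 = Environment(id="toy11_env2", carbon_source="C2_ext")
    env1 = Environment(id="toy11_env1", carbon_source="C_ext")
    return universe, env1, env2, biomass


# ---------------------------------------------------------------------------
# Randomized fixture generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a randomized toy universe.

    ``redundancy`` parallel paths lead from the hub metabolite to each
    biomass precursor (paths beyond the first may be two-step), so path
    reactions beyond the first of each precursor are non-essential;
    uptake and biomass-assembly reactions are super-essential by
    construction; decoys are blocked everywhere.
    """

    num_precursors: int = 2
    redundancy: int = 2
    num_decoys: int = 1
    num_carbon_sources: int = 1
    reversible_fraction: float = 0.0
    seed: int = 0
    max_enumeration_N: int = 22


@dataclass
class GroundTruth:
    """Exhaustively computed truth for a fixture universe."""

    super_essential: dict[str, frozenset[str]]  # env id -> reaction ids
    blocked_full: dict[str, frozenset[str]]  # env id -> blocked in full genotype
    viable_counts: dict[str, dict[int, int]] = field(default_factory=dict)
    diameter: dict[str, dict[int, int]] = field(default_factory=dict)
    swap_connected: dict[str, dict[int, bool]] = field(default_factory=dict)


def generate_fixture(
    spec: FixtureSpec,
    ground_truth_ns: tuple[int, ...] | None = None,
) -> tuple[ReactionUniverse, list[Environment], BiomassObjective, GroundTruth]:
    """Build a randomized universe plus its exhaustive ground truth.

    Deterministic for a given spec (seed included).  Ground-truth viable
    counts/diameters are computed for ``ground_truth_ns`` (default: no
    per-n enumeration — super-essential and blocked sets only).
    """
    rng = np.random.default_rng(spec.seed)
    reactions: list[Reaction] = []

    for k in range(spec.num_carbon_sources):
        reactions.append(Reaction(f"UPT{k + 1}", {f"C{k + 1}_ext": -1, "A": 1}))
    for i in range(spec.num_precursors):
        for j in range(spec.redundancy):
            two_step = j > 0 and rng.random() < 0.5
            if two_step:
                inter = f"I{i + 1}_{j + 1}"
                rev = rng.random() < spec.reversible_fraction
                reactions.append(
                    Reaction(f"P{i + 1}a{j + 1}", {"A": -1, inter: 1}, reversible=rev)
                )
                reactions.append(
                    Reaction(f"P{i + 1}b{j + 1}", {inter: -1, f"P{i + 1}": 1})
                )
            else:
                rev = rng.random() < spec.reversible_fraction
                reactions.append(
                    Reaction(f"P{i + 1}x{j + 1}", {"A": -1, f"P{i + 1}": 1}, reversible=rev)
                )
    reactions.append(
        Reaction("BIO", {f"P{i + 1}": -1 for i in range(spec.num_precursors)} | {"BM_ext": 1})
    )
    for d in range(spec.num_decoys):
        reactions.append(Reaction(f"DEC{d + 1}", {f"X{d + 1}": -1, f"Y{d + 1}": 1}))

    if len(reactions) > spec.max_enumeration_N:
        raise EnumerationBudgetError(
            f"fixture would have N={len(reactions)} > cap {spec.max_enumeration_N}"
        )
    universe = ReactionUniverse(tuple(reactions), id=f"fixture_seed{spec.seed}")
    environments = [
        Environment(id=f"env_C{k + 1}", carbon_source=f"C{k + 1}_ext")
        for k in range(spec.num_carbon_sources)
    ]
    biomass = BiomassObjective({"BM_ext": 1.0}, id="fixture_biomass")

    from .fba import blocked_reactions, is_viable, super_essential_reactions

    full = Genotype.full(universe.N)
    truth = GroundTruth(super_essential={}, blocked_full={})
    for env in environments:
        assert is_viable(universe, full, env, biomass).viable, "fixture must be viable"
        truth.super_essential[env.id] = frozenset(
            super_essential_reactions(universe, env, biomass)
        )
        truth.blocked_full[env.id] = frozenset(
            blocked_reactions(universe, full, env, biomass)
        )
    for env in environments:
        counts: dict[int, int] = {}
        diam: dict[int, int] = {}
        conn: dict[int, bool] = {}
        for n in ground_truth_ns or ():
            members = enumerate_viable(universe, env, biomass, n)
            counts[n] = len(members)
            diam[n] = diameter_of(members)
            conn[n] = swap_connected(members)
        truth.viable_counts[env.id] = counts
        truth.diameter[env.id] = diam
        truth.swap_connected[env.id] = conn
    return universe, environments, biomass, truth


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def subset_viable_lp(
    universe: ReactionUniverse,
    indices: tuple[int, ...],
    environment: Environment,
    biomass: BiomassObjective,
) -> bool:
    """Fresh-LP viability oracle: builds a reduced LP per subset.

    Absent reaction columns are physically removed rather than
    bound-zeroed, so this route shares no model-construction code with
    :class:`~viaspace.fba.FbaModel`.
    """
    mets = sorted(universe.metabolites | set(biomass.composition))
    mi = {m: i for i, m in enumerate(mets)}
    externals = sorted(universe.external_metabolites)
    U = DEFAULT_FLUX_BOUND
    ncols = len(indices) + len(externals) + 1
    A = np.zeros((len(mets), ncols))
    bounds = []
    for col, j in enumerate(indices):
        r = universe.reactions[j]
        for m, c in r.stoichiometry.items():
            A[mi[m], col] = c
        bounds.append(r.bounds)
    for k, m in enumerate(externals):
        col = len(indices) + k
        A[mi[m], col] = -1.0
        if m == environment.carbon_source:
            bounds.append((-environment.carbon_uptake_limit, U))
        elif m in environment.unlimited:
            bounds.append((-U, U))
        elif environment.secretable is None or m in environment.secretable:
            bounds.append((0.0, U))
        else:
            bounds.append((0.0, 0.0))
    for m, p in biomass.composition.items():
        A[mi[m], ncols - 1] = -p
    bounds.append((0.0, U))
    c = np.zeros(ncols)
    c[-1] = -1.0  # maximize drain flux
    res = linprog(c, A_eq=A, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"oracle LP failed with status {res.status}")
    return -res.fun > 1e-9 * environment.carbon_uptake_limit


def reachability_viable(
    universe: ReactionUniverse,
    genotype: Genotype,
    environment: Environment,
    biomass: BiomassObjective,
) -> bool:
    """Boolean forward-closure oracle (unit-coefficient universes only).

    A metabolite is producible if supplied by the environment or made by a
    usable reaction; a reaction is usable if present and all substrates of
    one of its directions are producible.  Viable iff every biomass
    constituent is producible.  Exact whenever reactions have single
    products and unit coefficients (no stoichiometric coupling or
    byproduct-disposal effects), as in the fixtures of this module.
    """
    producible = {environment.carbon_source} | set(environment.unlimited)
    present = [universe.reactions[i] for i in genotype.present_indices]
    changed = True
    while changed:
        changed = False
        for r in present:
            subs = {m for m, c in r.stoichiometry.items() if c < 0}
            prods = {m for m, c in r.stoichiometry.items() if c > 0}
            if subs <= producible and not prods <= producible:
                producible |= prods
                changed = True
            if r.reversible and prods <= producible and not subs <= producible:
                producible |= subs
                changed = True
    return set(biomass.composition) <= producible


def enumerate_viable(
    universe: ReactionUniverse,
    environment: Environment,
    biomass: BiomassObjective,
    n: int,
) -> list[Genotype]:
    """Exhaustive list of viable size-n genotypes via the fresh-LP oracle."""
    N = universe.N
    total = math.comb(N, n)
    if total > ENUMERATION_BUDGET:
        raise EnumerationBudgetError(
            f"C({N},{n}) = {total} exceeds the enumeration budget"
        )
    out = []
    for combo in itertools.combinations(range(N), n):
        if subset_viable_lp(universe, combo, environment, biomass):
            out.append(Genotype.from_indices(combo, N))
    return out


def diameter_of(genotypes: list[Genotype]) -> int:
    """Maximum pairwise Hamming distance (0 for < 2 members)."""
    if len(genotypes) < 2:
        return 0
    return max(hamming(a, b) for a, b in itertools.combinations(genotypes, 2))


def swap_connected(genotypes: list[Genotype]) -> bool:
    """Is the swap graph (edges = Hamming-distance-2 pairs) connected?"""
    m = len(genotypes)
    if m <= 1:
        return True
    adj: dict[int, list[int]] = {i: [] for i in range(m)}
    for i, j in itertools.combinations(range(m), 2):
        if hamming(genotypes[i], genotypes[j]) == 2:
            adj[i].append(j)
            adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == m
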