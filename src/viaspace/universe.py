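"""Reaction universes, minimal environments and biomass objectives.

A *reaction universe* is an ordered table of candidate reactions from which
metabolic genotypes draw their reaction sets.  The order is load-bearing:
genotype bit ``i`` always refers to reaction ``i`` of the universe, so all
file formats preserve it and all outputs use reaction ids rather than raw
indices.

Metabolite ids ending in ``_ext`` are *external*: they may cross the system
boundary through implicit exchange reactions whose bounds are set by the
:class:`Environment` (one limited carbon source, unlimited inorganics,
secretion for everything else).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import UniverseFormatError

#: Default magnitude for unconstrained flux bounds (arbitrary flux units).
DEFAULT_FLUX_BOUND = 1000.0

#: Default cap on carbon-source uptake (arbitrary flux units).
DEFAULT_CARBON_UPTAKE = 10.0

EXTERNAL_SUFFIX = "_ext"

_EQN_RE = re.compile(r"^\s*(.*?)\s*(<->|->)\s*(.*?)\s*$")
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


@dataclass(frozen=True)
class Reaction:
    """A single reaction: signed stoichiometry plus flux bounds.

    Negative stoichiometric coefficients denote consumption.  Irreversible
    reactions must have a non-negative lower bound.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lb: float | None = None
    ub: float | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise UniverseFormatError(f"reaction {self.id!r}: empty stoichiometry")
        lb, ub = self.bounds
        if lb > ub:
            raise UniverseFormatError(f"reaction {self.id!r}: lb > ub")
        if not self.reversible and lb < 0:
            raise UniverseFormatError(
                f"reaction {self.id!r}: irreversible reaction with negative lower bound"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        """Effective (lower, upper) flux bounds, applying defaults."""
        lb = self.lb if self.lb is not None else (-DEFAULT_FLUX_BOUND if self.reversible else 0.0)
        ub = self.ub if self.ub is not None else DEFAULT_FLUX_BOUND
        return lb, ub

    def equation(self) -> str:
        """Render the stoichiometry as an equation string (stable order)."""
        subs = sorted((m, -c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)

        def side(terms: list[tuple[str, float]]) -> str:
            return " + ".join(f"{_fmt(c)} {m}" for m, c in terms)

        arrow = "<->" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}"


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class ReactionUniverse:
    """Ordered set of N reactions with declared metabolites."""

    reactions: tuple[Reaction, ...]
    id: str = "universe"

    def __post_init__(self) -> None:
        if not self.reactions:
            raise UniverseFormatError("a universe must contain at least one reaction")
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise UniverseFormatError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)

    @property
    def N(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def metabolites(self) -> frozenset[str]:
        mets: set[str] = set()
        for r in self.reactions:
            mets.update(r.stoichiometry)
        return frozenset(mets)

    @property
    def external_metabolites(self) -> frozenset[str]:
        return frozenset(m for m in self.metabolites if m.endswith(EXTERNAL_SUFFIX))

    def index_of(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def subset(self, reaction_ids: set[str], id: str | None = None) -> "ReactionUniverse":
        """Universe restricted to the given ids, preserving order."""
        kept = tuple(r for r in self.reactions if r.id in reaction_ids)
        return ReactionUniverse(kept, id=id or self.id)


@dataclass(frozen=True)
class Environment:
    """A minimal chemical environment.

    One carbon source with a finite uptake cap, a set of unlimited
    (inorganic) external metabolites, and a set of secretable external
    metabolites (``None`` means every external metabolite may be secreted).
    """

    id: str
    carbon_source: str
    carbon_uptake_limit: float = DEFAULT_CARBON_UPTAKE
    unlimited: frozenset[str] = frozenset()
    secretable: frozenset[str] | None = None  # None = all external

    def __post_init__(self) -> None:
        if self.carbon_uptake_limit <= 0:
            raise UniverseFormatError(
                f"environment {self.id!r}: carbon_uptake_limit must be positive"
            )

    def validate_against(self, universe: ReactionUniverse) -> None:
        ext = universe.external_metabolites
        missing = ({self.carbon_source} | set(self.unlimited)) - ext
        if missing:
            raise UniverseFormatError(
                f"environment {self.id!r}: metabolites {sorted(missing)} are not "
                f"external metabolites of universe {universe.id!r}"
            )


@dataclass(frozen=True)
class BiomassObjective:
    """Biomass composition: metabolite -> strictly positive proportion."""

    composition: dict[str, float]
    id: str = "biomass"

    def __post_init__(self) -> None:
        if not self.composition:
            raise UniverseFormatError("biomass objective needs at least one component")
        for m, p in self.composition.items():
            if p <= 0:
                raise UniverseFormatError(f"biomass component {m!r}: proportion must be > 0")


def perturb_biomass(
    biomass: BiomassObjective, max_fraction: float, seed: int
) -> BiomassObjective:
    """Multiply each proportion by an independent uniform factor.

    Each component's proportion is scaled by a factor drawn uniformly from
    ``[1 - max_fraction, 1 + max_fraction]``; the component set is unchanged
    and the result is deterministic for a given seed.
    """
    if not 0 <= max_fraction < 1:
        raise ValueError("max_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    items = list(biomass.composition.items())
    factors = rng.uniform(1 - max_fraction, 1 + max_fraction, size=len(items))
    return replace(
        biomass,
        composition={m: p * f for (m, p), f in zip(items, factors)},
    )


# ---------------------------------------------------------------------------
# Equation parsing and TSV I/O
# ---------------------------------------------------------------------------

def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``1 A + 2 B -> 1 C`` into (stoichiometry, reversible)."""
    m = _EQN_RE.match(text)
    if not m:
        raise UniverseFormatError(f"malformed equation: {text!r}")
    lhs, arrow, rhs = m.groups()
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        if not side.strip():
            return
        for term in side.split("+"):
            tm = _TERM_RE.match(term)
            if not tm:
                raise UniverseFormatError(f"malformed term {term!r} in equation {text!r}")
            coeff = float(tm.group(1)) if tm.group(1) else 1.0
            met = tm.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add(lhs, -1.0)
    add(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, arrow == "<->"


def read_universe(path) -> ReactionUniverse:
    """Read a reaction-table TSV.

    Columns: ``reaction_id``, ``equation``, and optional ``lb``/``ub``
    overrides.  Reaction order equals file order.
    """
    reactions: list[Reaction] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["reaction_id", "equation"]:
                    raise UniverseFormatError(
                        f"{path}: first columns must be reaction_id, equation"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                stoich, rev = parse_equation(row["equation"])
            except UniverseFormatError as exc:
                raise UniverseFormatError(f"{path}:{lineno}: {exc}") from None
            lb = float(row["lb"]) if row.get("lb", "") not in ("", None) else None
            ub = float(row["ub"]) if row.get("ub", "") not in ("", None) else None
            reactions.append(
                Reaction(row["reaction_id"], stoich, reversible=rev, lb=lb, ub=ub)
            )
    ids = [r.id for r in reactions]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise UniverseFormatError(f"{path}: duplicate reaction id(s) {sorted(dupes)}")
    import os

    name = os.path.splitext(os.path.basename(str(path)))[0]
    return ReactionUniverse(tuple(reactions), id=name)


def write_universe(universe: ReactionUniverse, path) -> None:
    """Write a universe as a reaction-table TSV (round-trips with read)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tlb\tub\n")
        for r in universe.reactions:
            lb = _fmt(r.lb) if r.lb is not None else ""
            ub = _fmt(r.ub) if r.ub is not None else ""
            fh.write(f"{r.id}\t{r.equation()}\t{lb}\t{ub}\n")


def read_environment(path) -> Environment:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "carbon_source" not in data:
        raise UniverseFormatError(f"{path}: environment file needs a carbon_source key")
    secretable = data.get("secretable", "all_external")
    import os

    return Environment(
        id=data.get("id", os.path.splitext(os.path.basename(str(path)))[0]),
        carbon_source=data["carbon_source"],
        carbon_uptake_limit=float(data.get("carbon_uptake_limit", DEFAULT_CARBON_UPTAKE)),
        unlimited=frozenset(data.get("unlimited", []) or []),
        secretable=None if secretable == "all_external" else frozenset(secretable),
    )


def write_environment(env: Environment, path) -> None:
    data = {
        "id": env.id,
        "carbon_source": env.carbon_source,
        "carbon_uptake_limit": env.carbon_uptake_limit,
        "unlimited": sorted(env.unlimited),
        "secretable": "all_external" if env.secretable is None else sorted(env.secretable),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_biomass(path) -> BiomassObjective:
    comp: dict[str, float] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["metabolite", "proportion"]:
                    raise UniverseFormatError(
                        f"{path}: biomass file columns must be metabolite, proportion"
                    )
                continue
            comp[fields[0]] = float(fields[1])
    import os

    return BiomassObjective(comp, id=os.path.splitext(os.path.basename(str(path)))[0])


def write_biomass(biomass: BiomassObjective, path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\tproportion\n")
        for m, p in biomass.composition.items():
            fh.write(f"{m}\t{p!r}\n")


def prune_universe(
    universe: ReactionUniverse,
    environments: list[Environment],
    biomass: BiomassObjective,
) -> ReactionUniverse:
    """Remove reactions blocked in *every* supplied environment.

    A reaction is removable when flux variability analysis of the full
    genotype finds it unable to carry flux (at nonzero biomass) in all
    environments.  Pruning is idempotent and preserves the relative order
    (hence the id ↔ index mapping can be reconstructed from ids).
    """
    from .fba import blocked_reactions, is_viable
    from .genotypes import Genotype

    if not environments:
        raise ValueError("at least one environment is required")
    full = Genotype.full(universe.N)
    viable_envs = [
        e for e in environments if is_viable(universe, full, e, biomass).viable
    ]
    if not viable_envs:
        raise NonViableAnchor(
            "full universe is non-viable in every supplied environment; "
            "nothing to anchor the pruning on"
        )
    blocked_everywhere: set[str] | None = None
    for env in viable_envs:
        b = blocked_reactions(universe, full, env, biomass)
        blocked_everywhere = b if blocked_everywhere is None else blocked_everywhere & b
    # A reaction unblocked in some viable environment is kept; environments in
    # which the full universe is non-viable cannot unblock anything.
    keep = set(universe.reaction_ids) - (blocked_everywhere or set())
    return universe.subset(keep)


class NonViableAnchor(UniverseFormatError):
    """Raised by prune_universe when no environment supports the full universe."""
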