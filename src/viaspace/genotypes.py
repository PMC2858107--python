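"""Genotypes as fixed-length presence/absence vectors and their geometry.

A genotype over a universe of N reactions is a binary string of length N
with n bits set.  Genotypes are immutable values backed by a Python integer
bitmask (bit i = reaction i of the universe order), which makes Hamming
distances, hashing and set algebra cheap, plus a cached tuple of present
indices for O(1) uniform swap selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import NoLegalSwapError
from .universe import ReactionUniverse


@dataclass(frozen=True)
class Genotype:
    """Immutable presence/absence vector of length N (bitmask-backed)."""

    mask: int
    N: int

    def __post_init__(self) -> None:
        if self.mask < 0 or self.mask >> self.N:
            raise ValueError("bitmask has bits outside [0, N)")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_indices(cls, indices: Iterable[int], N: int) -> "Genotype":
        mask = 0
        for i in indices:
            if not 0 <= i < N:
                raise ValueError(f"index {i} outside [0, {N})")
            mask |= 1 << i
        return cls(mask, N)

    @classmethod
    def from_ids(cls, ids: Iterable[str], universe: ReactionUniverse) -> "Genotype":
        return cls.from_indices((universe.index_of(r) for r in ids), universe.N)

    @classmethod
    def full(cls, N: int) -> "Genotype":
        return cls((1 << N) - 1, N)

    @classmethod
    def empty(cls, N: int) -> "Genotype":
        return cls(0, N)

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of present reactions (popcount)."""
        return self.mask.bit_count()

    @property
    def present_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.N) if self.mask >> i & 1)

    @property
    def absent_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.N) if not self.mask >> i & 1)

    def to_ids(self, universe: ReactionUniverse) -> tuple[str, ...]:
        ids = universe.reaction_ids
        return tuple(ids[i] for i in self.present_indices)

    def to_array(self) -> np.ndarray:
        return np.array([(self.mask >> i) & 1 for i in range(self.N)], dtype=np.uint8)

    def __contains__(self, index: int) -> bool:
        return bool(self.mask >> index & 1)

    # -- algebra -----------------------------------------------------------
    def with_bit(self, index: int, value: bool) -> "Genotype":
        mask = self.mask | (1 << index) if value else self.mask & ~(1 << index)
        return Genotype(mask, self.N)

    def swap(self, out_index: int, in_index: int) -> "Genotype":
        """Remove one present reaction and add one absent reaction."""
        if out_index not in self or in_index in self:
            raise ValueError("swap requires a present out-bit and an absent in-bit")
        return Genotype(self.mask ^ (1 << out_index) | (1 << in_index), self.N)

    def issubset(self, other: "Genotype") -> bool:
        return self.mask & ~other.mask == 0


def hamming(g1: Genotype, g2: Genotype) -> int:
    """Hamming distance between two genotypes of equal length."""
    if g1.N != g2.N:
        raise ValueError(f"length mismatch: {g1.N} != {g2.N}")
    return (g1.mask ^ g2.mask).bit_count()


def expected_hamming_omega(n: int, N: int) -> float:
    """Mean Hamming distance between two uniform random members of Ω(n).

    Closed form 2·n·(N−n)/N: each of the n set bits of the first genotype
    misses the second with probability (N−n)/N, and mismatches come in
    pairs because both genotypes have the same weight.
    """
    _check_n(n, N)
    if N == 0:
        return 0.0
    return 2.0 * n * (N - n) / N

def max_hamming_omega(n: int, N: int) -> int:
    """Maximum Hamming distance within Ω(n): 2·min(n, N−n)."""
    _check_n(n, N)
    return 2 * min(n, N - n)


def _check_n(n: int, N: int) -> None:
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")


def random_genotype(
    N: int,
    n: int,
    required: Iterable[int] = (),
    seed: int | np.random.Generator = 0,
) -> Genotype:
    """Uniform random size-n genotype containing all ``required`` indices.

    The n − |required| free bits are drawn uniformly without replacement
    from the complement of the required set.
    """
    req = sorted(set(required))
    _check_n(n, N)
    if len(req) > n:
        raise ValueError(f"n={n} smaller than required set of size {len(req)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    req_set = set(req)
    pool = np.array([i for i in range(N) if i not in req_set], dtype=np.int64)
    extra = rng.choice(pool, size=n - len(req), replace=False) if n > len(req) else []
    return Genotype.from_indices(list(req) + list(extra), N)


def propose_swap(
    genotype: Genotype,
    frozen: Iterable[int] = (),
    rng: np.random.Generator | int = 0,
) -> Genotype:
    """Propose a uniform reaction swap, never touching frozen bits.

    One present non-frozen bit is cleared and one absent bit is set, each
    chosen uniformly and independently, so the proposal distribution is
    symmetric: the reverse swap has the same probability.  The result is
    always at Hamming distance 2 from the input.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    frozen_set = set(frozen)
    outs = [i for i in genotype.present_indices if i not in frozen_set]
    ins = genotype.absent_indices
    if not outs or not ins:
        raise NoLegalSwapError(
            "no legal swap: need a present non-frozen bit and an absent bit"
        )
    out = outs[rng.integers(len(outs))]
    inn = ins[rng.integers(len(ins))]
    return genotype.swap(out, inn)


# ---------------------------------------------------------------------------
# Sample-file format
# ---------------------------------------------------------------------------

def write_sample_file(
    path,
    genotypes: Sequence[Genotype],
    universe: ReactionUniverse,
    environment_ids: Sequence[str],
    n: int,
    seed: int,
    acceptance: float,
) -> None:
    """Write genotypes as comma-separated reaction ids with a header.

    Header lines: ``#universe=`` ``#environment=`` ``#n=`` ``#seed=``
    ``#acceptance=``; genotypes are listed in canonical universe order.
    """
    with open(path, "w") as fh:
        fh.write(f"#universe={universe.id}\n")
        fh.write(f"#environment={','.join(environment_ids)}\n")
        fh.write(f"#n={n}\n#seed={seed}\n#acceptance={acceptance:.6g}\n")
        for g in genotypes:
            fh.write(",".join(g.to_ids(universe)) + "\n")


def read_sample_file(path, universe: ReactionUniverse):
    """Read a genotype sample file; returns (genotypes, header dict)."""
    genotypes: list[Genotype] = []
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key] = value
                continue
            genotypes.append(Genotype.from_ids(line.split(","), universe))
    return genotypes, header
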