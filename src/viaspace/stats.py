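"""Ensemble statistics over samples of viable genotypes.

Everything here consumes a sample of genotypes (typically the thinned
output of the fixed-n MCMC) and produces the descriptive statistics of
the viable space: the distribution of mutational robustness and its
binomial-normal approximation, pairwise Hamming distances, per-reaction
occurrence with essential/blocked frequencies and rank-histogram curve
fits, PCA and average-linkage hierarchical clustering of the bit-string
representations, a permutation test on cluster centers of mass, and
multi-environment viability profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .fba import FbaModel, ViabilityEvaluator
from .genotypes import Genotype, hamming
from .mcmc import SampleSet
from .universe import BiomassObjective, Environment, ReactionUniverse


def _genotypes(sample) -> list[Genotype]:
    return sample.genotypes if isinstance(sample, SampleSet) else list(sample)


def _bit_matrix(genotypes: Sequence[Genotype]) -> np.ndarray:
    return np.stack([g.to_array() for g in genotypes]).astype(float)


# ---------------------------------------------------------------------------
# Mutational robustness
# ---------------------------------------------------------------------------

def binomial_robustness_variance(r: float, n: int, s: int) -> float:
    """Variance of R_mu under the independent-reaction binomial argument.

    Super-essential reactions contribute no variability (they are always
    essential), so only the n - s remaining reactions are treated as
    independent Bernoulli trials with non-essentiality probability
    p = n r / (n - s); the variance of the mean of those trials, rescaled
    to the full genotype, is p (1 - p) (n - s) / n^2.
    """
    if not 0 <= s < n:
        raise ValueError("need 0 <= s < n")
    p = n * r / (n - s)
    return p * (1.0 - p) * (n - s) / n**2


@dataclass
class RobustnessStats:
    values: np.ndarray
    mean: float
    variance: float
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges (width 1/n)
    n: int
    s: int
    normal_mean: float
    normal_variance: float | None  # None when p = n r/(n-s) leaves [0, 1]
    p_flagged: bool
    reference_value: float | None = None
    reference_p_value: float | None = None


def robustness_stats(
    universe: ReactionUniverse,
    sample,
    environments: Environment | Sequence[Environment],
    biomass: BiomassObjective,
    reference: Genotype | None = None,
) -> RobustnessStats:
    """Per-genotype R_mu over the sample, with the normal approximation.

    With several environments a reaction counts as essential when it is
    essential in at least one of them (the union).  If a reference
    genotype is supplied, its robustness and the one-sided add-one
    empirical p-value of a sampled genotype matching or exceeding it are
    reported.
    """
    if isinstance(environments, Environment):
        environments = [environments]
    genotypes = _genotypes(sample)
    if not genotypes:
        raise ValueError("empty sample")
    evs = [ViabilityEvaluator(universe, e, biomass) for e in environments]
    full = Genotype.full(universe.N)
    s = len(frozenset().union(*[ev.essential_indices(full) for ev in evs]))

    def r_mu(g: Genotype) -> float:
        essential: set[int] = set()
        for ev in evs:
            essential |= ev.essential_indices(g)
        return 1.0 - len(essential) / g.n

    values = np.array([r_mu(g) for g in genotypes])
    n = genotypes[0].n
    r = float(values.mean())
    var = float(values.var(ddof=1)) if len(values) > 1 else 0.0
    edges = np.arange(0.0, 1.0 + 1.0 / n, 1.0 / n)
    hist = np.histogram(values, bins=edges)
    p = n * r / (n - s) if n > s else np.nan
    flagged = not 0.0 <= p <= 1.0
    normal_var = None if flagged else binomial_robustness_variance(r, n, s)
    ref_val = ref_p = None
    if reference is not None:
        ref_val = r_mu(reference)
        ref_p = (int(np.sum(values >= ref_val)) + 1) / (len(values) + 1)
    return RobustnessStats(
        values, r, var, hist, n, s, r, normal_var, flagged, ref_val, ref_p
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceStats:
    mean: float
    max: int
    pair_count: int


def distance_stats(sample) -> DistanceStats:
    """Mean and maximum Hamming distance over all genotype pairs."""
    genotypes = _genotypes(sample)
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    d = pdist(_bit_matrix(genotypes), metric="hamming") * genotypes[0].N
    return DistanceStats(float(d.mean()), int(round(d.max())), len(d))


# ---------------------------------------------------------------------------
# Reaction occurrence
# ---------------------------------------------------------------------------

def occurrence_table(
    universe: ReactionUniverse,
    sample,
    environment: Environment,
    biomass: BiomassObjective,
) -> pd.DataFrame:
    """Occurrence, essential and blocked frequencies per reaction.

    occurrence: fraction of sampled genotypes containing the reaction;
    essential_freq / blocked_freq: fraction of sampled genotypes in which
    it is present *and* essential / blocked.  Ranks run from 1 (highest
    occurrence) downward, ties broken by reaction id.
    """
    genotypes = _genotypes(sample)
    if not genotypes:
        raise ValueError("empty sample")
    ev = ViabilityEvaluator(universe, environment, biomass)
    model = FbaModel(universe, environment, biomass)
    N = universe.N
    occ = np.zeros(N)
    ess = np.zeros(N)
    blk = np.zeros(N)
    blocked_cache: dict[int, frozenset[int]] = {}
    for g in genotypes:
        for i in g.present_indices:
            occ[i] += 1
        for i in ev.essential_indices(g):
            ess[i] += 1
        cached = blocked_cache.get(g.mask)
        if cached is None:
            cached = frozenset(
                i
                for i in g.present_indices
                if _is_blocked(model, universe, g, i)
            )
            blocked_cache[g.mask] = cached
        for i in cached:
            blk[i] += 1
    m = len(genotypes)
    df = pd.DataFrame(
        {
            "reaction_id": universe.reaction_ids,
            "occurrence": occ / m,
            "essential_freq": ess / m,
            "blocked_freq": blk / m,
        }
    )
    df = df.sort_values(
        ["occurrence", "reaction_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, N + 1)
    return df


def _is_blocked(model: FbaModel, universe, genotype, index: int) -> bool:
    from .fba import FVA_FLUX_TOL

    fmin, fmax = model.flux_range(genotype, index, biomass_min=model.eps)
    reach = max(fmax, 0.0)
    if universe.reactions[index].reversible:
        reach = max(reach, -min(fmin, 0.0))
    return reach <= FVA_FLUX_TOL


# ---------------------------------------------------------------------------
# Rank-histogram curve fits
# ---------------------------------------------------------------------------

@dataclass
class RankFitResult:
    model: str  # constant_plus_exponential | constant_plus_power
    a: float
    b: float
    c: float
    r_squared: float
    converged: bool
    message: str = ""


def _exp_model(r, a, b, c):
    return a + b * np.exp(-c * r)


def _power_model(r, a, b, c):
    return a + b * np.power(r, -c)


def fit_rank_histogram(table: pd.DataFrame) -> tuple[RankFitResult, RankFitResult]:
    """Fit occurrence-vs-rank to constant+exponential and constant+power.

    Both f(r) = a + b exp(-c r) and f(r) = a + b r^(-c) are fitted by
    nonlinear least squares so the caller can compare their coefficients
    of determination.  Initialization: a from the mean occurrence of the
    bottom decile of ranks, b and c from a log-linear regression of the
    residual occurrence.  Degenerate input (constant occurrence) and
    non-convergence are returned as flagged results, not exceptions.
    """
    df = table.sort_values("rank")
    r = df["rank"].to_numpy(dtype=float)
    f = df["occurrence"].to_numpy(dtype=float)
    if len(np.unique(r)) < 10:
        raise ValueError("need at least 10 distinct ranks to fit")
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot == 0.0:
        flat = RankFitResult("", f[0], 0.0, 0.0, np.nan, False, "zero total variance")
        return (
            RankFitResult("constant_plus_exponential", f[0], 0.0, 0.0, np.nan, False,
                          "zero total variance"),
            RankFitResult("constant_plus_power", f[0], 0.0, 0.0, np.nan, False,
                          "zero total variance"),
        )

    a0 = float(f[r >= np.quantile(r, 0.9)].mean())
    resid = f - a0
    pos = resid > 1e-12
    out = []
    for name, func, xfun in (
        ("constant_plus_exponential", _exp_model, lambda x: x),
        ("constant_plus_power", _power_model, np.log),
    ):
        try:
            if pos.sum() >= 2:
                slope, intercept = np.polyfit(xfun(r[pos]), np.log(resid[pos]), 1)
                p0 = [a0, float(np.exp(intercept)), float(-slope)]
            else:
                p0 = [a0, 1.0, 0.01]
            params, _ = curve_fit(func, r, f, p0=p0, maxfev=20000)
            pred = func(r, *params)
            r2 = 1.0 - float(np.sum((f - pred) ** 2)) / ss_tot
            out.append(RankFitResult(name, *map(float, params), r2, True))
        except (RuntimeError, ValueError) as exc:
            out.append(RankFitResult(name, np.nan, np.nan, np.nan, np.nan, False, str(exc)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# PCA and clustering
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray  # rows x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x columns


def pca(matrix, orientation: str = "genotypes") -> PcaResult:
    """Column-centered PCA of a genotype-by-reaction binary matrix.

    ``orientation='reactions'`` transposes first, so that rows are
    reaction presence profiles across genotypes.  Component signs are
    fixed by making the largest-magnitude loading of each component
    positive, which pins down the usual sign ambiguity of the SVD.
    """
    if isinstance(matrix, (SampleSet, list)):
        matrix = _bit_matrix(_genotypes(matrix))
    X = np.asarray(matrix, dtype=float)
    if orientation == "reactions":
        X = X.T
    elif orientation != "genotypes":
        raise ValueError("orientation must be 'genotypes' or 'reactions'")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for PCA")
    k = min(X.shape[0] - 1, X.shape[1])
    if np.allclose(X, X[0]):
        return PcaResult(
            np.zeros((X.shape[0], k)), np.zeros(k), np.zeros((k, X.shape[1]))
        )
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    for comp in range(k):
        j = int(np.argmax(np.abs(loadings[comp])))
        if loadings[comp, j] < 0:
            loadings[comp] *= -1
            scores[:, comp] *= -1
    return PcaResult(scores, model.explained_variance_ratio_, loadings)


def hierarchical_clustering(sample) -> np.ndarray:
    """Average-linkage agglomerative clustering on Hamming distances.

    The inter-cluster distance is the mean pairwise distance between
    members of different clusters (UPGMA).  Returns the SciPy linkage
    matrix (merge list with non-decreasing heights).
    """
    genotypes = _genotypes(sample)
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    d = pdist(_bit_matrix(genotypes), metric="hamming") * genotypes[0].N
    return linkage(d, method="average")


# ---------------------------------------------------------------------------
# Permutation test on cluster centers of mass
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    observed: float  # D*: sum of pairwise distances between centers of mass
    null_values: np.ndarray
    p_value: float


def permutation_test(
    clouds: Sequence,
    num_permutations: int = 10**4,
    seed: int = 0,
    pca_plane: bool = False,
) -> PermutationTestResult:
    """Are labeled genotype clouds more separated than chance?

    D* is the sum of pairwise Euclidean distances between the clouds'
    centers of mass, computed in the full binary-vector space (or, with
    ``pca_plane=True``, in the plane of the first two principal
    components of the pooled points).  Labels are shuffled preserving
    cloud sizes; the p-value uses the add-one convention, so its minimum
    is 1/(num_permutations + 1).
    """
    arrays = []
    for cloud in clouds:
        a = cloud if isinstance(cloud, np.ndarray) else _bit_matrix(_genotypes(cloud))
        arrays.append(np.asarray(a, dtype=float))
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two clouds of at least two points each")
    X = np.vstack(arrays)
    if pca_plane:
        X = pca(X).scores[:, :2]
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)

    def statistic(M: np.ndarray) -> float:
        coms = [M[bounds[i]: bounds[i + 1]].mean(axis=0) for i in range(len(sizes))]
        return float(
            sum(
                np.linalg.norm(ca - cb)
                for ca, cb in itertools.combinations(coms, 2)
            )
        )

    observed = statistic(X)
    rng = np.random.default_rng(seed)
    null = np.empty(num_permutations)
    for k in range(num_permutations):
        null[k] = statistic(X[rng.permutation(len(X))])
    p = (int(np.sum(null >= observed)) + 1) / (num_permutations + 1)
    return PermutationTestResult(observed, null, p)


# ---------------------------------------------------------------------------
# Multi-environment viability profile
# ---------------------------------------------------------------------------

def viability_profile(
    universe: ReactionUniverse,
    sample,
    environment_list: Sequence[Environment],
    biomass: BiomassObjective,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype count of environments supporting viability.

    Returns (counts per genotype, histogram over 0..len(environments)).
    """
    if not environment_list:
        raise ValueError("environment list must be non-empty")
    genotypes = _genotypes(sample)
    evs = [ViabilityEvaluator(universe, e, biomass) for e in environment_list]
    counts = np.array(
        [sum(ev.viable(g) for ev in evs) for g in genotypes], dtype=int
    )
    hist = np.bincount(counts, minlength=len(environment_list) + 1)
    return counts, hist
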