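"""Conditional viability across environments and relative space sizes.

Absolute sizes of the viable spaces V_i(n) for different environments are
out of reach, but *ratios* are not: a uniform sample from V_i(n) scored
for viability in environment j estimates P(i,j)/P(i), and the quotient of
two such estimates gives the size ratio

    P(j)/P(i) = [P(i,j)/P(i)] / [P(i,j)/P(j)].

Statistical errors are propagated from block-jackknife standard errors of
the underlying viability indicator series (the samples are thinned MCMC
output, hence weakly correlated).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fba import ViabilityEvaluator
from .fraction import wilson_interval
from .mcmc import SampleSet, jackknife_error
from .universe import BiomassObjective, Environment, ReactionUniverse


@dataclass
class MultiEnvEstimate:
    """Cross-environment viability estimates at one genotype size n.

    ``conditional.loc[i, j]`` estimates P(i,j)/P(i) — equivalently the
    conditional probability of viability in j given viability in i, since
    each row-i sample is uniform over V_i(n).  ``ratio.loc[i, j]``
    estimates P(j)/P(i); ``ratio_se`` carries propagated jackknife
    errors (NaN where a zero denominator makes the ratio unbounded —
    those entries are listed in ``unbounded``).
    """

    n: int
    environment_ids: tuple[str, ...]
    conditional: pd.DataFrame
    conditional_ci: dict[tuple[str, str], tuple[float, float]]
    ratio: pd.DataFrame
    ratio_se: pd.DataFrame
    triple_ratios: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    unbounded: list[tuple[str, str]] = field(default_factory=list)


def conditional_probability(
    universe: ReactionUniverse,
    biomass: BiomassObjective,
    sample_on_env1: SampleSet | Sequence,
    env2: Environment,
    evaluator: ViabilityEvaluator | None = None,
) -> tuple[float, tuple[float, float], int]:
    """P(2|1): fraction of an env-1 viable sample also viable in env 2.

    Returns (estimate, Wilson 95% CI, hit count).
    """
    env2.validate_against(universe)
    genotypes = (
        sample_on_env1.genotypes
        if isinstance(sample_on_env1, SampleSet)
        else list(sample_on_env1)
    )
    if not genotypes:
        raise ValueError("empty sample")
    ev = evaluator or ViabilityEvaluator(universe, env2, biomass)
    hits = sum(ev.viable(g) for g in genotypes)
    return hits / len(genotypes), wilson_interval(hits, len(genotypes)), hits


def size_ratios(
    universe: ReactionUniverse,
    biomass: BiomassObjective,
    samples: Sequence[SampleSet | Sequence],
    environments: Sequence[Environment],
    n: int | None = None,
    jackknife_window: int = 10,
) -> MultiEnvEstimate:
    """Relative sizes of the viable spaces from per-environment samples.

    ``samples[i]`` must be a uniform sample of V_i(n) for
    ``environments[i]``; all samples must share the same n.  For each
    ordered pair the cross-viability fraction is estimated, ratios are
    formed as quotients, and errors propagate in quadrature from
    block-jackknife standard errors of the indicator series.
    """
    if len(samples) != len(environments) or len(environments) < 2:
        raise ValueError("need one sample per environment, at least two")
    genotype_lists = [
        s.genotypes if isinstance(s, SampleSet) else list(s) for s in samples
    ]
    ns = {g.n for gl in genotype_lists for g in gl}
    if len(ns) != 1:
        raise ValueError(f"samples mix genotype sizes: {sorted(ns)}")
    n = n or ns.pop()
    ids = tuple(e.id for e in environments)
    evs = [ViabilityEvaluator(universe, e, biomass) for e in environments]

    cond = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    se = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    cis: dict[tuple[str, str], tuple[float, float]] = {}
    indicators: dict[tuple[int, int], np.ndarray] = {}
    for i, gl in enumerate(genotype_lists):
        for j, ev in enumerate(evs):
            if i == j:
                continue
            ind = np.array([float(ev.viable(g)) for g in gl])
            indicators[(i, j)] = ind
            p = float(ind.mean())
            cond.iloc[i, j] = p
            cis[(ids[i], ids[j])] = wilson_interval(int(ind.sum()), len(ind))
            if len(ind) >= 4:
                w = min(jackknife_window, max(1, len(ind) // 4))
                se.iloc[i, j] = jackknife_error(ind, [w]).plateau
            else:
                se.iloc[i, j] = np.nan

    ratio = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    ratio_se = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    unbounded: list[tuple[str, str]] = []
    for i, j in itertools.permutations(range(len(ids)), 2):
        p_ij, p_ji = cond.iloc[i, j], cond.iloc[j, i]
        if p_ji == 0.0:
            ratio.iloc[i, j] = np.inf
            ratio_se.iloc[i, j] = np.nan
            unbounded.append((ids[i], ids[j]))
            continue
        r = p_ij / p_ji
        ratio.iloc[i, j] = r
        rel = 0.0
        if p_ij > 0:
            rel = np.hypot(se.iloc[i, j] / p_ij, se.iloc[j, i] / p_ji)
        ratio_se.iloc[i, j] = r * rel

    triples: dict[tuple[str, tuple[str, str]], float] = {}
    if len(ids) >= 3:
        for i in range(len(ids)):
            others = [k for k in range(len(ids)) if k != i]
            for j, k in itertools.combinations(others, 2):
                joint = np.array(
                    [
                        float(evs[j].viable(g) and evs[k].viable(g))
                        for g in genotype_lists[i]
                    ]
                )
                triples[(ids[i], (ids[j], ids[k]))] = float(joint.mean())
    return MultiEnvEstimate(
        n, ids, cond, cis, ratio, ratio_se, triples, unbounded
    )
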