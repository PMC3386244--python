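"""Vectorised multi-iteration engine for the competition simulator.

Building a likelihood grid needs tens of thousands of bottle replicates, so
this engine tracks every iteration's population as counts over the 16 ordered
(maternal, paternal) haplotype-pair classes per sex, and advances all
iterations at once with vectorised binomial / hypergeometric / multinomial
draws.  It is distributionally equivalent to :mod:`introsim.simulate` (each
offspring independently draws a uniform surviving mother and father, so
offspring genotypes are i.i.d. from the product of the sex-specific gamete
pools), which the test suite verifies against the deterministic oracle and
the individual-based engine.
"""

from __future__ import annotations

import numpy as np

from .params import ExperimentDesign, SelectionParams
from .simulate import (
    FitnessScheme,
    HAP_SECH_COUPLING,
    HAP_SIM_COUPLING,
    _female_gamete_matrix,
    _male_gamete_matrix,
    fitness_weights,
)

# per ordered-pair class: survival weight index and marker-allele count
_FIT_COUNT = np.array([(a & 1) + (b & 1) for a in range(4) for b in range(4)])
_MARKER_COUNT = np.array([(a >> 1) + (b >> 1) for a in range(4) for b in range(4)])


def _multivariate_hypergeometric(
    rng: np.random.Generator, counts: np.ndarray, nsample: np.ndarray
) -> np.ndarray:
    """Row-wise multivariate hypergeometric draw.

    ``counts`` is (I, K); ``nsample`` is (I,) with ``nsample <= counts.sum(1)``
    wherever it is positive.
    """
    out = np.zeros_like(counts)
    rem = counts.sum(axis=1)
    need = nsample.astype(np.int64).copy()
    for j in range(counts.shape[1]):
        good = counts[:, j]
        rem = rem - good
        active = need > 0
        draw = rng.hypergeometric(
            np.where(active, good, 1),
            np.where(active, rem, 1),
            np.where(active, np.minimum(need, good + rem), 1),
        )
        take = np.where(active, np.minimum(draw, good), 0)
        out[:, j] = take
        need -= take
    return out


def simulate_batch(
    params: SelectionParams,
    design: ExperimentDesign,
    n_iterations: int,
    rng: np.random.Generator,
    scheme: FitnessScheme = "standard",
) -> dict[int, np.ndarray]:
    """Simulate ``n_iterations`` independent replicates.

    Returns, for each scheduled sample generation, the array of sampled sech
    marker frequencies (one per iteration).  Semantics match
    :func:`introsim.simulate.run_replicate`: reproduction -> selection ->
    destructive sampling, founder generation unselected, terminal states
    absorbed at the last observed frequency.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    I = int(n_iterations)
    w = fitness_weights(params, scheme)
    W16 = w[_FIT_COUNT]
    Gf = _female_gamete_matrix(params.c)
    Gm = _male_gamete_matrix()
    founder_class = 4 * HAP_SECH_COUPLING + HAP_SIM_COUPLING

    males = np.zeros((I, 16), dtype=np.int64)
    females = np.zeros((I, 16), dtype=np.int64)
    males[:, founder_class] = design.n_males
    females[:, founder_class] = design.n_females

    done = np.zeros(I, dtype=bool)
    frozen = np.full(I, np.nan)
    sample_set = set(design.sample_generations)
    results: dict[int, np.ndarray] = {}

    def pop_freq(m: np.ndarray, f: np.ndarray) -> np.ndarray:
        tot = m.sum(axis=1) + f.sum(axis=1)
        alleles = (m + f) @ _MARKER_COUNT
        return np.where(tot > 0, alleles / np.maximum(2 * tot, 1), frozen)

    for gen in range(design.n_generations + 1):
        if gen > 0:
            pre_freq = pop_freq(males, females)
            males = rng.binomial(males, W16[np.newaxis, :])
            females = rng.binomial(females, W16[np.newaxis, :])
            extinct = ~done & ((males.sum(axis=1) == 0) | (females.sum(axis=1) == 0))
            frozen[extinct] = pre_freq[extinct]
            done |= extinct

        if gen in sample_set:
            short = ~done & (
                (males.sum(axis=1) <= design.sample_males)
                | (females.sum(axis=1) <= design.sample_females)
            )
            if short.any():
                frozen[short] = pop_freq(males, females)[short]
                done |= short
            active = ~done
            take_m = _multivariate_hypergeometric(
                rng, males, np.where(active, design.sample_males, 0)
            )
            take_f = _multivariate_hypergeometric(
                rng, females, np.where(active, design.sample_females, 0)
            )
            sampled = (take_m + take_f) @ _MARKER_COUNT
            freqs = sampled / design.n_sampled_alleles
            results[gen] = np.where(active, freqs, frozen)
            males -= take_m
            females -= take_f

        if gen < design.n_generations:
            pool_f = females @ Gf
            pool_m = males @ Gm
            tot_f = pool_f.sum(axis=1, keepdims=True)
            tot_m = pool_m.sum(axis=1, keepdims=True)
            # absorbed iterations get a dummy uniform pool; their draws are discarded
            pool_f = np.where(tot_f > 0, pool_f / np.maximum(tot_f, 1e-300), 0.25)
            pool_m = np.where(tot_m > 0, pool_m / np.maximum(tot_m, 1e-300), 0.25)
            pair_p = (pool_f[:, :, np.newaxis] * pool_m[:, np.newaxis, :]).reshape(I, 16)
            pair_p /= pair_p.sum(axis=1, keepdims=True)
            males = rng.multinomial(design.n_males, pair_p)
            females = rng.multinomial(design.n_females, pair_p)

    return results
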