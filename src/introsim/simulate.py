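"""Individual-based forward simulator of a marker linked to a selected locus.

The model tracks a diploid population through discrete generations of
viability selection, destructive sampling and random mating.  Each haplotype
carries two biallelic loci: a neutral marker and a fitness locus, each with a
*sim* (resident) or *sech* (introgressed) allele.  Recombination between the
two loci happens in females only (Drosophila males are achiasmate).

Haplotypes are encoded as integers 0..3: ``2 * marker + fitness`` where an
allele is 1 for *sech* and 0 for *sim*.  A population stores each sex as an
``(n, 2)`` integer array of haplotype codes, one row per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .params import ExperimentDesign, SelectionParams

SIM = 0
SECH = 1

#: Coupling-phase haplotype carrying the sech allele at both loci.
HAP_SECH_COUPLING = 2 * SECH + SECH  # == 3
#: Coupling-phase haplotype carrying the sim allele at both loci.
HAP_SIM_COUPLING = 2 * SIM + SIM  # == 0

FitnessScheme = Literal["standard", "literal"]


class ExtinctionError(RuntimeError):
    """Raised when viability selection (or breeding) leaves a sex empty."""


class InsufficientSurvivorsError(RuntimeError):
    """Raised when a sex has too few survivors to take the scheduled sample."""


@dataclass(frozen=True)
class Haplotype:
    marker_allele: int
    fitness_allele: int

    def __post_init__(self) -> None:
        if self.marker_allele not in (SIM, SECH) or self.fitness_allele not in (SIM, SECH):
            raise ValueError("alleles must be SIM (0) or SECH (1)")

    @property
    def code(self) -> int:
        return 2 * self.marker_allele + self.fitness_allele

    @classmethod
    def from_code(cls, code: int) -> "Haplotype":
        return cls(marker_allele=(code >> 1) & 1, fitness_allele=code & 1)


@dataclass(frozen=True)
class Individual:
    haplotype_1: Haplotype
    haplotype_2: Haplotype
    sex: Literal["male", "female"]

    @property
    def n_sech_fitness(self) -> int:
        return self.haplotype_1.fitness_allele + self.haplotype_2.fitness_allele

    @property
    def n_sech_marker(self) -> int:
        return self.haplotype_1.marker_allele + self.haplotype_2.marker_allele


@dataclass
class Population:
    """Diploid population split by sex.

    ``males`` and ``females`` are ``(n, 2)`` arrays of haplotype codes.
    """

    males: np.ndarray
    females: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.males = np.asarray(self.males, dtype=np.int8).reshape(-1, 2)
        self.females = np.asarray(self.females, dtype=np.int8).reshape(-1, 2)

    @property
    def n_males(self) -> int:
        return self.males.shape[0]

    @property
    def n_females(self) -> int:
        return self.females.shape[0]

    @property
    def size(self) -> int:
        return self.n_males + self.n_females

    def individuals(self) -> list[Individual]:
        out: list[Individual] = []
        for arr, sex in ((self.males, "male"), (self.females, "female")):
            for h1, h2 in arr:
                out.append(
                    Individual(Haplotype.from_code(int(h1)), Haplotype.from_code(int(h2)), sex)
                )
        return out


@dataclass(frozen=True)
class TrajectoryObservation:
    """Marker allele frequency observed in one destructive sample."""

    experiment_id: str
    replicate_id: str
    generation: int
    sech_marker_count: int
    n_alleles: int

    def __post_init__(self) -> None:
        if not 0 <= self.sech_marker_count <= self.n_alleles:
            raise ValueError(
                f"sech count {self.sech_marker_count} outside [0, {self.n_alleles}]"
            )

    @property
    def frequency(self) -> float:
        return self.sech_marker_count / self.n_alleles


def _marker_count(arr: np.ndarray) -> int:
    # marker allele is bit 1 of the haplotype code
    return int((arr >> 1).sum())


def marker_frequency(pop: Population) -> float:
    """Sech marker allele frequency over the whole population."""
    total = 2 * pop.size
    if total == 0:
        raise ValueError("empty population has no marker frequency")
    return (_marker_count(pop.males) + _marker_count(pop.females)) / total


def fitness_weights(params: SelectionParams, scheme: FitnessScheme = "standard") -> np.ndarray:
    """Survival probability indexed by the count of sech fitness alleles (0..2).

    The standard scheme is ``w = (1, 1 - h*s, 1 - s)``.  The literal scheme
    ``w = (1, h*s, s)`` treats the printed survival probabilities at face
    value and is kept only as a configuration switch for sensitivity checks.
    """
    if scheme == "standard":
        return np.array([1.0, 1.0 - params.h * params.s, 1.0 - params.s])
    if scheme == "literal":
        return np.array([1.0, params.h * params.s, params.s])
    raise ValueError(f"unknown fitness scheme: {scheme!r}")


def genotype_fitness(
    ind: Individual, params: SelectionParams, scheme: FitnessScheme = "standard"
) -> float:
    """Survival probability of an individual; depends only on the fitness locus."""
    return float(fitness_weights(params, scheme)[ind.n_sech_fitness])


def make_founder_population(design: ExperimentDesign) -> Population:
    """Generation-0 population of coupling-phase double heterozygotes.

    Every founder carries one sech/sech and one sim/sim haplotype, so the
    marker frequency is exactly 0.5 and marker and fitness alleles start in
    full coupling.
    """
    male_row = [HAP_SECH_COUPLING, HAP_SIM_COUPLING]
    males = np.tile(male_row, (design.n_males, 1))
    females = np.tile(male_row, (design.n_females, 1))
    return Population(males=males, females=females, generation=0)


def viability_selection(
    pop: Population,
    params: SelectionParams,
    rng: np.random.Generator,
    scheme: FitnessScheme = "standard",
) -> Population:
    """Retain each individual independently with its genotype's survival probability.

    Raises
    ------
    ExtinctionError
        If either sex has zero survivors.
    """
    if pop.size == 0:
        raise ValueError("cannot select on an empty population")
    w = fitness_weights(params, scheme)
    survivors = []
    for arr in (pop.males, pop.females):
        probs = w[(arr & 1).sum(axis=1)]
        keep = rng.random(arr.shape[0]) < probs
        survivors.append(arr[keep])
    if survivors[0].shape[0] == 0 or survivors[1].shape[0] == 0:
        raise ExtinctionError(
            f"a sex went extinct under selection at generation {pop.generation}"
        )
    return Population(males=survivors[0], females=survivors[1], generation=pop.generation)


def make_gamete(parent: Individual, c: float, rng: np.random.Generator) -> Haplotype:
    """Draw one gamete from a parent.

    Males always transmit an intact haplotype (1/2 each).  Females transmit a
    recombinant with probability ``c`` (each of the two recombinants at
    ``c/2``), otherwise an intact haplotype (each at ``(1 - c)/2``).
    """
    first, second = parent.haplotype_1, parent.haplotype_2
    if rng.random() < 0.5:
        first, second = second, first
    if parent.sex == "female" and rng.random() < c:
        return Haplotype(first.marker_allele, second.fitness_allele)
    return first


def _gametes_from(
    parents: np.ndarray,
    idx: np.ndarray,
    c: float,
    rng: np.random.Generator,
    recombine: bool,
) -> np.ndarray:
    """Vectorised gamete draw for the chosen parent rows (same law as make_gamete)."""
    n = idx.shape[0]
    pick = rng.integers(0, 2, size=n)
    first = parents[idx, pick]
    if not recombine or c == 0.0:
        return first
    second = parents[idx, 1 - pick]
    rec = rng.random(n) < c
    recombinant = (first & 2) | (second & 1)  # marker from first, fitness from second
    return np.where(rec, recombinant, first)


def reproduce(
    survivors: Population,
    design: ExperimentDesign,
    params: SelectionParams,
    rng: np.random.Generator,
) -> Population:
    """Random mating with replacement to restore the census.

    Each offspring independently draws a uniform surviving mother and father
    and receives one gamete from each; exactly ``n_males`` sons and
    ``n_females`` daughters are produced and the generation index increments.
    """
    if survivors.n_males == 0 or survivors.n_females == 0:
        raise ExtinctionError("no breeding pair available")
    n_off = design.n_males + design.n_females
    mothers = rng.integers(0, survivors.n_females, size=n_off)
    fathers = rng.integers(0, survivors.n_males, size=n_off)
    maternal = _gametes_from(survivors.females, mothers, params.c, rng, recombine=True)
    paternal = _gametes_from(survivors.males, fathers, params.c, rng, recombine=False)
    offspring = np.stack([maternal, paternal], axis=1)
    return Population(
        males=offspring[: design.n_males],
        females=offspring[design.n_males :],
        generation=survivors.generation + 1,
    )


def sample_marker_frequency(
    pop: Population,
    design: ExperimentDesign,
    rng: np.random.Generator,
    experiment_id: str = "",
    replicate_id: str = "",
) -> tuple[TrajectoryObservation, Population]:
    """Destructively sample flies and record the sech marker frequency.

    Removes ``sample_males`` + ``sample_females`` individuals uniformly
    without replacement; the returned population excludes them.

    Raises
    ------
    InsufficientSurvivorsError
        If a sex has no more survivors than its sample size (breeding would
        be impossible after removal).
    """
    if pop.n_males <= design.sample_males or pop.n_females <= design.sample_females:
        raise InsufficientSurvivorsError(
            f"survivors ({pop.n_males} M, {pop.n_females} F) too few for sample "
            f"({design.sample_males} M, {design.sample_females} F)"
        )
    count = 0
    remaining = []
    for arr, k in ((pop.males, design.sample_males), (pop.females, design.sample_females)):
        perm = rng.permutation(arr.shape[0])
        taken, kept = perm[:k], perm[k:]
        count += _marker_count(arr[taken])
        remaining.append(arr[kept])
    obs = TrajectoryObservation(
        experiment_id=experiment_id,
        replicate_id=replicate_id,
        generation=pop.generation,
        sech_marker_count=count,
        n_alleles=design.n_sampled_alleles,
    )
    return obs, Population(males=remaining[0], females=remaining[1], generation=pop.generation)


def _frozen_observation(
    freq: float, generation: int, design: ExperimentDesign, experiment_id: str, replicate_id: str
) -> TrajectoryObservation:
    n_alleles = design.n_sampled_alleles
    return TrajectoryObservation(
        experiment_id=experiment_id,
        replicate_id=replicate_id,
        generation=generation,
        sech_marker_count=int(round(freq * n_alleles)),
        n_alleles=n_alleles,
    )


def run_replicate(
    params: SelectionParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
    scheme: FitnessScheme = "standard",
    experiment_id: str = "sim",
    replicate_id: str = "1",
) -> list[TrajectoryObservation]:
    """Run one bottle replicate and return one observation per scheduled sample.

    The per-generation cycle is reproduction -> viability selection ->
    (destructive sampling if scheduled).  Selection is skipped on the founder
    generation: founders are the already-adult F1 and, being genotypically
    uniform, selection could only rescale their number.  Terminal states are
    absorbed: if a sex goes extinct the marker frequency of the last living
    flies is recorded for all remaining scheduled generations, and likewise
    if too few survivors remain to take a sample.
    """
    pop = make_founder_population(design)
    sample_set = set(design.sample_generations)
    observations: list[TrajectoryObservation] = []
    frozen: float | None = None

    for gen in range(design.n_generations + 1):
        if frozen is None and gen > 0:
            pre_freq = marker_frequency(pop)
            try:
                pop = viability_selection(pop, params, rng, scheme)
            except ExtinctionError:
                frozen = pre_freq
        if gen in sample_set:
            if frozen is None:
                try:
                    obs, pop = sample_marker_frequency(
                        pop, design, rng, experiment_id, replicate_id
                    )
                    observations.append(obs)
                except InsufficientSurvivorsError:
                    frozen = marker_frequency(pop)
            if frozen is not None:
                observations.append(
                    _frozen_observation(frozen, gen, design, experiment_id, replicate_id)
                )
        if frozen is None and gen < design.n_generations:
            try:
                pop = reproduce(pop, design, params, rng)
            except ExtinctionError:
                frozen = marker_frequency(pop)
    return observations


# ---------------------------------------------------------------------------
# Deterministic infinite-population oracle
# ---------------------------------------------------------------------------

def _female_gamete_matrix(c: float) -> np.ndarray:
    """(16, 4) matrix: ordered parent genotype (4*a + b) -> gamete distribution."""
    G = np.zeros((16, 4))
    for a in range(4):
        for b in range(4):
            g = 4 * a + b
            G[g, a] += (1.0 - c) / 2.0
            G[g, b] += (1.0 - c) / 2.0
            G[g, (a & 2) | (b & 1)] += c / 2.0
            G[g, (b & 2) | (a & 1)] += c / 2.0
    return G


def _male_gamete_matrix() -> np.ndarray:
    return _female_gamete_matrix(0.0)


def expected_trajectory(
    params: SelectionParams,
    p0: float = 0.5,
    n_generations: int = 20,
    scheme: FitnessScheme = "standard",
) -> np.ndarray:
    """Deterministic marker-frequency trajectory in an infinite population.

    Tracks the joint distribution of ordered (maternal, paternal) haplotype
    pairs under female-only recombination and viability selection.  The
    founder generation is the maximally heterozygous coupling-phase
    population with marker frequency ``p0`` (all double heterozygotes when
    ``p0 = 0.5``, matching the simulator's founder).  Returns an array of
    length ``n_generations + 1`` of post-selection marker frequencies, entry
    0 being ``p0``.

    With ``c = 0`` this reduces to the single-locus recursion
    ``q' = [q^2 (1-s) + p q (1-h s)] / [p^2 + 2 p q (1-h s) + q^2 (1-s)]``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    w = fitness_weights(params, scheme)
    W16 = np.array([w[(a & 1) + (b & 1)] for a in range(4) for b in range(4)])
    M16 = np.array([((a >> 1) + (b >> 1)) / 2.0 for a in range(4) for b in range(4)])
    Gf = _female_gamete_matrix(params.c)
    Gm = _male_gamete_matrix()

    # founder: het share 2*min(p0, 1-p0) in coupling phase, rest coupling homozygote
    F = np.zeros(16)
    het = 2.0 * min(p0, 1.0 - p0)
    F[4 * HAP_SECH_COUPLING + HAP_SIM_COUPLING] += het / 2.0
    F[4 * HAP_SIM_COUPLING + HAP_SECH_COUPLING] += het / 2.0
    if p0 > 0.5:
        F[4 * HAP_SECH_COUPLING + HAP_SECH_COUPLING] += 1.0 - het
    else:
        F[4 * HAP_SIM_COUPLING + HAP_SIM_COUPLING] += 1.0 - het

    freqs = [float(F @ M16)]
    for _ in range(n_generations):
        gf = F @ Gf
        gm = F @ Gm
        F = np.outer(gf, gm).ravel() * W16
        total = F.sum()
        if total == 0.0:
            # all offspring die: frequency is absorbed at the last recorded value
            freqs.extend([freqs[-1]] * (n_generations + 1 - len(freqs)))
            break
        F /= total
        freqs.append(float(F @ M16))
    return np.array(freqs)
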