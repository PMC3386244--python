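"""Parameter containers shared across the simulator and the inference stage."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SelectionParams:
    """Selection regime for the two-locus model.

    Parameters
    ----------
    s : float
        Selection coefficient against the introgressed (sechellia) fitness
        allele, in ``[0, 1]``.
    h : float
        Dominance of the deleterious effect, in ``[0, 1]`` (0 = recessive,
        1 = dominant).
    c : float
        Recombination fraction between the neutral marker and the fitness
        locus per female meiosis, in ``[0, 0.5]``. Males do not recombine.
    """

    s: float
    h: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must be in [0, 1], got {self.h}")
        if not 0.0 <= self.c <= 0.5:
            raise ValueError(f"c must be in [0, 0.5], got {self.c}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Census sizes, generation count and destructive-sampling schedule."""

    n_males: int = 150
    n_females: int = 150
    n_generations: int = 20
    sample_generations: tuple[int, ...] = (7, 14, 20)
    sample_males: int = 20
    sample_females: int = 20
    n_replicates: int = 5

    def __post_init__(self) -> None:
        counts = (
            self.n_males,
            self.n_females,
            self.n_generations,
            self.sample_males,
            self.sample_females,
            self.n_replicates,
        )
        if any(int(v) != v or v <= 0 for v in counts):
            raise ValueError(f"all design counts must be positive integers: {self}")
        object.__setattr__(
            self, "sample_generations", tuple(sorted(set(int(g) for g in self.sample_generations)))
        )
        if not self.sample_generations:
            raise ValueError("at least one sample generation is required")
        if min(self.sample_generations) < 0:
            raise ValueError("sample generations must be non-negative")
        if max(self.sample_generations) > self.n_generations:
            raise ValueError(
                f"max sample generation {max(self.sample_generations)} exceeds "
                f"n_generations {self.n_generations}"
            )
        if self.sample_males > self.n_males or self.sample_females > self.n_females:
            raise ValueError("sample sizes must not exceed census sizes")

    @property
    def n_sampled(self) -> int:
        return self.sample_males + self.sample_females

    @property
    def n_sampled_alleles(self) -> int:
        return 2 * self.n_sampled


#: Default inference grid values for the recombination fraction.
DEFAULT_C_VALUES: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5)
#: Default inference grid values for the selection coefficient.
DEFAULT_S_VALUES: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
#: Default dominance levels, each fitted separately.
DEFAULT_H_VALUES: tuple[float, ...] = (0.0, 0.5, 0.9, 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid over which the likelihood is evaluated."""

    c_values: tuple[float, ...] = DEFAULT_C_VALUES
    s_values: tuple[float, ...] = DEFAULT_S_VALUES
    h_values: tuple[float, ...] = DEFAULT_H_VALUES

    def __post_init__(self) -> None:
        for name, values, lo, hi in (
            ("c_values", self.c_values, 0.0, 0.5),
            ("s_values", self.s_values, 0.0, 1.0),
            ("h_values", self.h_values, 0.0, 1.0),
        ):
            values = tuple(float(v) for v in values)
            object.__setattr__(self, name, values)
            if not values:
                raise ValueError(f"{name} must be non-empty")
            if any(not lo <= v <= hi for v in values):
                raise ValueError(f"{name} entries must lie in [{lo}, {hi}]: {values}")

    @property
    def n_cells(self) -> int:
        return len(self.c_values) * len(self.s_values) * len(self.h_values)
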