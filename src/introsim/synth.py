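"""Synthetic-data generators mirroring the experiment's structure.

Everything the downstream stages consume — replicate marker trajectories,
mating-pair count tables, and fertility replicate tables — can be generated
here under known ground-truth parameters, so the whole pipeline is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ExperimentDesign, SelectionParams
from .simulate import FitnessScheme, run_replicate
from .stats import FertilityRecords, MatingCounts

IntrogressionLabel = Literal["single", "double"]


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    params: SelectionParams
    design: ExperimentDesign = ExperimentDesign()
    label: IntrogressionLabel = "single"

    def __post_init__(self) -> None:
        if self.label not in ("single", "double"):
            raise ValueError(f"label must be 'single' or 'double', got {self.label!r}")


@dataclass(frozen=True)
class SyntheticStudySpec:
    experiments: tuple[ExperimentSpec, ...]
    seed: int = 0
    scheme: FitnessScheme = "standard"

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("at least one experiment is required")
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate experiment ids: {ids}")


def default_study(seed: int = 0) -> SyntheticStudySpec:
    """Six-experiment layout: three single- and three double-introgression
    competitions, five bottles each, with plausible ground-truth parameters."""
    mk = ExperimentSpec
    return SyntheticStudySpec(
        experiments=(
            mk("A", SelectionParams(s=0.5, h=0.5, c=0.2), label="single"),
            mk("B", SelectionParams(s=0.3, h=0.5, c=0.0001), label="single"),
            mk("C", SelectionParams(s=0.4, h=0.5, c=0.0001), label="single"),
            mk("D", SelectionParams(s=0.9, h=0.5, c=0.0001), label="double"),
            mk("E", SelectionParams(s=0.6, h=0.5, c=0.0001), label="double"),
            mk("F", SelectionParams(s=0.2, h=0.5, c=0.0001), label="double"),
        ),
        seed=seed,
    )


TRAJECTORY_COLUMNS = (
    "experiment_id",
    "replicate_id",
    "generation",
    "n_alleles",
    "sech_count",
    "frequency",
)


def generate_marker_dataset(spec: SyntheticStudySpec) -> pd.DataFrame:
    """Simulate every experiment's replicate bottles at its true parameters.

    Returns a long-format trajectory frame (one row per bottle x sampled
    generation).  Deterministic under ``spec.seed``: each replicate gets its
    own generator spawned from the study seed.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = iter(root.spawn(sum(e.design.n_replicates for e in spec.experiments)))
    rows = []
    for exp in spec.experiments:
        for rep in range(1, exp.design.n_replicates + 1):
            rng = np.random.default_rng(next(streams))
            for obs in run_replicate(
                exp.params,
                exp.design,
                rng,
                scheme=spec.scheme,
                experiment_id=exp.experiment_id,
                replicate_id=str(rep),
            ):
                rows.append(
                    {
                        "experiment_id": obs.experiment_id,
                        "replicate_id": obs.replicate_id,
                        "generation": obs.generation,
                        "n_alleles": obs.n_alleles,
                        "sech_count": obs.sech_marker_count,
                        "frequency": obs.frequency,
                    }
                )
    return pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))


@dataclass(frozen=True)
class MatingModelSpec:
    """Relative mating success of introgression vs wild-type flies.

    Pair-type probabilities are proportional to (female-type weight) x
    (male-type weight), with wild type at weight 1 and the introgression sex
    at its success ratio.  The timed trial is modelled as a fixed total
    number of scored matings.
    """

    female_success_ratio: float = 1.0
    male_success_ratio: float = 1.0
    n_matings: int = 120

    def __post_init__(self) -> None:
        if self.female_success_ratio <= 0 or self.male_success_ratio <= 0:
            raise ValueError("success ratios must be positive")
        if self.n_matings <= 0:
            raise ValueError("n_matings must be positive")

    def pair_probabilities(self) -> np.ndarray:
        """Probabilities for (SS, SI, IS, II) pair types."""
        f, m = self.female_success_ratio, self.male_success_ratio
        weights = np.array([1.0, m, f, f * m])
        return weights / weights.sum()


def generate_mating_counts(
    model: MatingModelSpec, rng: np.random.Generator, line: str = "synthetic"
) -> MatingCounts:
    """Multinomial draw of the four pair-type counts."""
    n_ss, n_si, n_is, n_ii = rng.multinomial(model.n_matings, model.pair_probabilities())
    return MatingCounts(line=line, n_ss=int(n_ss), n_si=int(n_si), n_is=int(n_is), n_ii=int(n_ii))


def generate_fertility_records(
    line_means: Mapping[str, float],
    sd: float,
    n_replicates: int,
    rng: np.random.Generator,
) -> FertilityRecords:
    """Per line, ``n_replicates`` progeny counts ~ Normal(mean, sd), truncated
    at zero and rounded to integers."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    records: dict[str, list[int]] = {}
    for line, mean in line_means.items():
        draws = rng.normal(mean, sd, size=n_replicates)
        records[line] = [int(round(max(v, 0.0))) for v in draws]
    return FertilityRecords(records=records)
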