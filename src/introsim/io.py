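"""File round-tripping, configuration, and pipeline orchestration.

CSV dialect is UTF-8, comma-separated, '.' decimal, mandatory header row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .likelihood import fit_grid, format_summary_table, summarize_mle_table
from .params import ExperimentDesign, GridSpec, SelectionParams
from .simulate import FitnessScheme
from .stats import (
    FertilityRecords,
    MatingCounts,
    aggregate_mating,
    fertility_summary,
    round_half_up,
    sign_test_one_tailed,
)
from .synth import (
    TRAJECTORY_COLUMNS,
    MatingModelSpec,
    SyntheticStudySpec,
    default_study,
    generate_fertility_records,
    generate_marker_dataset,
    generate_mating_counts,
)

log = logging.getLogger("introsim")


class TrajectoryReadError(ValueError):
    """Base class for trajectory-file validation failures."""


class MissingColumnError(TrajectoryReadError):
    pass


class CountMismatchError(TrajectoryReadError):
    pass


class ValueRangeError(TrajectoryReadError):
    pass


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trajectory CSV.

    An empty file (header only, or zero bytes) yields an empty frame with a
    warning rather than an error, so partially staged studies can be read.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return pd.DataFrame(columns=list(TRAJECTORY_COLUMNS))
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise MissingColumnError(f"{path}: missing columns {sorted(missing)}")
    frame = frame.astype({"experiment_id": str, "replicate_id": str})
    if frame.empty:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return frame
    if (frame["sech_count"] > frame["n_alleles"]).any() or (frame["sech_count"] < 0).any():
        raise CountMismatchError(f"{path}: sech_count outside [0, n_alleles]")
    if ((frame["frequency"] < 0) | (frame["frequency"] > 1)).any():
        raise ValueRangeError(f"{path}: frequency outside [0, 1]")
    expected = frame["sech_count"] / frame["n_alleles"]
    if not np.allclose(frame["frequency"], expected, atol=1e-9):
        raise CountMismatchError(f"{path}: frequency does not match sech_count / n_alleles")
    return frame


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    grid: GridSpec = field(default_factory=GridSpec)
    n_iterations: int = 10_000
    desk_iterations: int = 500
    scheme: FitnessScheme = "standard"

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.desk_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.scheme not in ("standard", "literal"):
            raise ValueError(f"unknown fitness scheme {self.scheme!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    design = ExperimentDesign(**raw.get("design", {}))
    grid_raw = {k: tuple(v) for k, v in raw.get("grid", {}).items()}
    grid = GridSpec(**grid_raw)
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        design=design,
        grid=grid,
        n_iterations=int(raw.get("n_iterations", 10_000)),
        desk_iterations=int(raw.get("desk_iterations", 500)),
        scheme=raw.get("scheme", "standard"),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def mating_report(lines: list[MatingCounts]) -> pd.DataFrame:
    """Per-line and average introgression shares, rounded as printed."""
    summary = aggregate_mating(lines)
    frame = summary.per_line.copy()
    for col in ("overall", "female", "male"):
        frame[col] = frame[col].map(lambda v: round_half_up(v, 2))
    avg = {
        "line": "Average",
        "n_total": frame["n_total"].mean(),
        "overall": round_half_up(summary.mean_overall, 2),
        "female": round_half_up(summary.mean_female, 2),
        "male": round_half_up(summary.mean_male, 2),
    }
    return pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)


def fertility_report(records: FertilityRecords) -> pd.DataFrame:
    summary = fertility_summary(records)
    frame = summary.per_line.copy()
    avg = {
        "line": "Average",
        "n": frame["n"].mean(),
        "mean": summary.grand_mean,
        "se": float("nan"),
    }
    return pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    study: SyntheticStudySpec | None = None,
) -> Path:
    """Run synth -> simulate -> fit -> stats -> report end to end.

    All stochastic stages derive their streams from ``config.seed``; rerunning
    with an identical config reproduces every CSV byte for byte.  On stage
    failure, partial outputs are kept and a ``FAILED`` marker names the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if study is None:
            study = default_study(seed=config.seed)

        stage = "synth"
        log.info("stage %s", stage)
        trajectories = generate_marker_dataset(study)
        write_observations(trajectories, outdir / "trajectories.csv")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        mating = [
            generate_mating_counts(
                MatingModelSpec(female_success_ratio=1.0, male_success_ratio=0.8),
                rng,
                line=exp.experiment_id,
            )
            for exp in study.experiments
        ]
        pd.DataFrame(
            [
                {"line": m.line, "n_ss": m.n_ss, "n_si": m.n_si, "n_is": m.n_is, "n_ii": m.n_ii}
                for m in mating
            ]
        ).to_csv(outdir / "mating_counts.csv", index=False)
        fertility = generate_fertility_records(
            {exp.experiment_id: 300.0 for exp in study.experiments},
            sd=60.0,
            n_replicates=10,
            rng=rng,
        )

        stage = "fit"
        log.info("stage %s (%d iterations/cell)", stage, config.desk_iterations)
        mle_rows = []
        grid_frames = []
        for exp in study.experiments:
            obs = trajectories[trajectories["experiment_id"] == exp.experiment_id]
            grids = fit_grid(
                obs,
                config.grid,
                exp.design,
                config.desk_iterations,
                seed=config.seed,
                scheme=config.scheme,
            )
            for g in grids:
                s_hat, c_hat = g.mle
                mle_rows.append({"marker": exp.experiment_id, "h": g.h, "c": c_hat, "s": s_hat})
                grid_frames.append(g.to_frame().assign(marker=exp.experiment_id))
        pd.concat(grid_frames, ignore_index=True).to_csv(
            outdir / "likelihood_grids.csv", index=False
        )
        mles = pd.DataFrame(mle_rows)
        summary = summarize_mle_table(mles)
        format_summary_table(summary).to_csv(outdir / "mle_summary.tsv", sep="\t", index=False)

        stage = "stats"
        log.info("stage %s", stage)
        mating_report(mating).to_csv(outdir / "mating_report.tsv", sep="\t", index=False)
        fertility_report(fertility).to_csv(outdir / "fertility_report.tsv", sep="\t", index=False)
        agg = aggregate_mating(mating)
        sign_p = sign_test_one_tailed(agg.n_lines_below_half, len(mating))
        with (outdir / "headline_stats.json").open("w") as fh:
            json.dump(
                {
                    "mean_introgression_share": agg.mean_overall,
                    "lines_below_half": agg.n_lines_below_half,
                    "sign_test_p": sign_p,
                    "grand_mean_s": summary.grand_mean_s,
                    "grand_mean_c": summary.grand_mean_c,
                    "near_zero_c_fraction": summary.near_zero_c_fraction,
                },
                fh,
                indent=2,
            )

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "introsim_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "design": asdict(config.design),
            "grid": asdict(config.grid),
            "desk_iterations": config.desk_iterations,
            "scheme": config.scheme,
            "experiments": [
                {
                    "experiment_id": e.experiment_id,
                    "label": e.label,
                    "true_s": e.params.s,
                    "true_h": e.params.h,
                    "true_c": e.params.c,
                }
                for e in study.experiments
            ],
        }
        with (outdir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, exc) from exc
    return outdir
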