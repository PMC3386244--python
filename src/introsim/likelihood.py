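"""Binned frequency distributions and grid-search maximum likelihood.

For each parameter combination the simulator is run for many iterations and
the sampled marker frequencies of each scheduled generation are binned into
40 equal-width bins.  An observed set of replicate frequencies is scored per
generation by pooling the distinct bins it occupies: the summed bin count
over the iteration total, logged.  Generational log terms are summed, and
the maximum over the (s, c) grid is reported separately for each dominance
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .batch import simulate_batch
from .params import ExperimentDesign, GridSpec, SelectionParams
from .simulate import FitnessScheme

N_BINS = 40
BIN_WIDTH = 1.0 / N_BINS

LikelihoodMode = Literal["union", "per_replicate"]


def bin_index(freq: float) -> int:
    """Map a frequency in [0, 1] to its bin in ``[0, 39]``.

    Bins are half-open ``[k/40, (k+1)/40)`` with the last bin closed at 1.
    Sampled frequencies are exact multiples of 1/80, so boundary hits are
    resolved exactly rather than at the mercy of float rounding.
    """
    arr = bin_indices(np.asarray(freq, dtype=float))
    return int(arr)


def bin_indices(freqs: np.ndarray) -> np.ndarray:
    """Vectorised :func:`bin_index`."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0.0) | (freqs > 1.0)) or np.any(np.isnan(freqs)):
        bad = freqs[(freqs < 0.0) | (freqs > 1.0) | np.isnan(freqs)]
        raise ValueError(f"frequencies outside [0, 1]: {bad}")
    scaled = freqs * N_BINS
    nearest = np.rint(scaled)
    on_edge = np.abs(scaled - nearest) < 1e-9
    idx = np.where(on_edge, nearest, np.floor(scaled)).astype(np.int64)
    return np.minimum(idx, N_BINS - 1)


@dataclass(frozen=True)
class FrequencyDistribution:
    """Binned sampled-frequency distributions, one histogram per generation."""

    params: SelectionParams
    n_iterations: int
    bins: Mapping[int, np.ndarray]  # generation -> (40,) int counts

    def __post_init__(self) -> None:
        for gen, counts in self.bins.items():
            counts = np.asarray(counts)
            if counts.shape != (N_BINS,):
                raise ValueError(f"generation {gen}: expected {N_BINS} bins")
            if counts.sum() != self.n_iterations:
                raise ValueError(
                    f"generation {gen}: bin counts sum to {counts.sum()}, "
                    f"expected {self.n_iterations}"
                )

    @property
    def generations(self) -> tuple[int, ...]:
        return tuple(sorted(self.bins))


def build_distribution(
    params: SelectionParams,
    design: ExperimentDesign,
    n_iterations: int,
    rng: np.random.Generator,
    scheme: FitnessScheme = "standard",
) -> FrequencyDistribution:
    """Run the batch simulator and bin each generation's sampled frequencies."""
    freqs = simulate_batch(params, design, n_iterations, rng, scheme)
    bins = {
        gen: np.bincount(bin_indices(f), minlength=N_BINS)
        for gen, f in freqs.items()
    }
    return FrequencyDistribution(params=params, n_iterations=n_iterations, bins=bins)


def _as_frequency_map(observations) -> dict[int, np.ndarray]:
    """Accept a mapping gen -> frequencies or a long-format trajectory frame."""
    if isinstance(observations, pd.DataFrame):
        return {
            int(gen): grp["frequency"].to_numpy(dtype=float)
            for gen, grp in observations.groupby("generation")
        }
    return {int(g): np.asarray(v, dtype=float) for g, v in observations.items()}


def observation_log_likelihood(
    observations,
    dist: FrequencyDistribution,
    mode: LikelihoodMode = "union",
) -> float:
    """Log-likelihood of observed replicate frequencies under a distribution.

    ``union`` mode (the default) pools, per generation, the distinct bins
    containing any replicate's frequency and scores their combined mass once;
    replicates falling in an already-counted bin add nothing.  The
    ``per_replicate`` alternative multiplies individual bin probabilities and
    exists for sensitivity analysis.  Zero observed mass is floored at
    ``1 / (n_iterations + 1)`` so grids stay finite and comparable.
    """
    obs = _as_frequency_map(observations)
    missing = set(obs) - set(dist.bins)
    if missing:
        raise ValueError(f"observations at generations {sorted(missing)} not in distribution")
    floor = 1.0 / (dist.n_iterations + 1)
    total = 0.0
    for gen, freqs in obs.items():
        counts = dist.bins[gen]
        idx = bin_indices(freqs)
        if mode == "union":
            mass = counts[np.unique(idx)].sum() / dist.n_iterations
            total += float(np.log(max(mass, floor)))
        elif mode == "per_replicate":
            probs = np.maximum(counts[idx] / dist.n_iterations, floor)
            total += float(np.log(probs).sum())
        else:
            raise ValueError(f"unknown likelihood mode: {mode!r}")
    return total


@dataclass(frozen=True)
class LikelihoodGrid:
    """Log-likelihood surface over (s, c) at a fixed dominance level."""

    h: float
    s_values: tuple[float, ...]
    c_values: tuple[float, ...]
    loglik: np.ndarray  # shape (len(s_values), len(c_values))
    n_iterations: int

    @property
    def mle(self) -> tuple[float, float]:
        """Arg-max (s, c); ties broken toward smaller s, then smaller c."""
        best = (0, 0)
        best_val = -np.inf
        for i, _ in enumerate(self.s_values):
            for j, _ in enumerate(self.c_values):
                if self.loglik[i, j] > best_val:
                    best_val = self.loglik[i, j]
                    best = (i, j)
        return self.s_values[best[0]], self.c_values[best[1]]

    def to_frame(self) -> pd.DataFrame:
        s_mle, c_mle = self.mle
        rows = []
        for i, s in enumerate(self.s_values):
            for j, c in enumerate(self.c_values):
                rows.append(
                    {
                        "h": self.h,
                        "s": s,
                        "c": c,
                        "loglik": self.loglik[i, j],
                        "is_mle": (s == s_mle and c == c_mle),
                    }
                )
        return pd.DataFrame(rows)


def fit_grid(
    observations,
    grid: GridSpec,
    design: ExperimentDesign,
    n_iterations: int,
    seed: int,
    scheme: FitnessScheme = "standard",
    mode: LikelihoodMode = "union",
) -> list[LikelihoodGrid]:
    """Score every (s, c, h) grid cell against the observations.

    A fresh distribution is simulated for each cell with a seed derived
    deterministically from ``seed``, so identical inputs give identical
    grids.  One :class:`LikelihoodGrid` is returned per dominance level.
    """
    obs = _as_frequency_map(observations)
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(grid.h_values) * len(grid.s_values) * len(grid.c_values)))
    out = []
    for h in grid.h_values:
        loglik = np.empty((len(grid.s_values), len(grid.c_values)))
        for i, s in enumerate(grid.s_values):
            for j, c in enumerate(grid.c_values):
                rng = np.random.default_rng(next(children))
                dist = build_distribution(
                    SelectionParams(s=s, h=h, c=c), design, n_iterations, rng, scheme
                )
                loglik[i, j] = observation_log_likelihood(obs, dist, mode)
        out.append(
            LikelihoodGrid(
                h=h,
                s_values=grid.s_values,
                c_values=grid.c_values,
                loglik=loglik,
                n_iterations=n_iterations,
            )
        )
    return out


# ---------------------------------------------------------------------------
# MLE summary table
# ---------------------------------------------------------------------------

#: Grid values of c at or below this are displayed as 0 in summary output.
NEAR_ZERO_C = 0.01


@dataclass(frozen=True)
class MleSummary:
    """Per-marker MLEs with row/column/grand averages."""

    table: pd.DataFrame  # columns: marker, h, c, s (raw grid values)
    per_marker: pd.DataFrame  # marker -> mean c, mean s over h
    per_h: pd.DataFrame  # h -> mean c, mean s over markers
    grand_mean_c: float
    grand_mean_s: float
    n_markers: int
    near_zero_c_markers: int

    @property
    def near_zero_c_fraction(self) -> float:
        return self.near_zero_c_markers / self.n_markers


def summarize_mle_table(mles: pd.DataFrame) -> MleSummary:
    """Aggregate per-marker (c, s) estimates across dominance levels.

    ``mles`` needs columns ``marker``, ``h``, ``c``, ``s``.  Averages are
    plain arithmetic means of the entries.  A marker counts as "near-zero c"
    when its c estimate is <= 0.01 at every dominance level (the small grid
    values 0.0001-0.01 are reported as 0 in display output).
    """
    required = {"marker", "h", "c", "s"}
    if mles.empty:
        raise ValueError("empty MLE table")
    if not required.issubset(mles.columns):
        raise ValueError(f"MLE table needs columns {sorted(required)}")
    per_marker = mles.groupby("marker", sort=False)[["c", "s"]].mean()
    per_h = mles.groupby("h", sort=True)[["c", "s"]].mean()
    near_zero = (
        mles.assign(zero=mles["c"] <= NEAR_ZERO_C + 1e-12).groupby("marker")["zero"].all()
    )
    return MleSummary(
        table=mles.reset_index(drop=True),
        per_marker=per_marker,
        per_h=per_h,
        grand_mean_c=float(mles["c"].mean()),
        grand_mean_s=float(mles["s"].mean()),
        n_markers=int(per_marker.shape[0]),
        near_zero_c_markers=int(near_zero.sum()),
    )


def format_summary_table(summary: MleSummary) -> pd.DataFrame:
    """Wide display table: one marker per row, c and s columns per h, averages."""
    def show_c(v: float) -> float:
        return 0.0 if v <= NEAR_ZERO_C + 1e-12 else v

    hs = sorted(summary.table["h"].unique())
    rows = []
    for marker, grp in summary.table.groupby("marker", sort=False):
        row: dict[str, object] = {"marker": marker}
        by_h = grp.set_index("h")
        for h in hs:
            row[f"c_h{h:g}"] = show_c(float(by_h.loc[h, "c"]))
            row[f"s_h{h:g}"] = float(by_h.loc[h, "s"])
        row["c_avg"] = float(np.mean([show_c(float(by_h.loc[h, "c"])) for h in hs]))
        row["s_avg"] = float(by_h["s"].mean())
        rows.append(row)
    avg: dict[str, object] = {"marker": "Average"}
    frame = pd.DataFrame(rows)
    for col in frame.columns[1:]:
        avg[col] = float(frame[col].mean())
    return pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)
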