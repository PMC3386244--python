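"""Published empirical tables from the fly introgression competition study.

Three small tables ship with the package as CSV:

* ``mating_counts`` — multiple-choice mating-pair counts per introgression
  line (female type x male type; S = wild type, I = introgression).
* ``fertility_lines`` — per-line mean progeny counts (+/- SE) from the
  fertility assay; the line lost before testing has empty fields.
* ``mle_estimates`` — the published per-marker maximum-likelihood estimates
  of the recombination fraction c and selection coefficient s at each of the
  four dominance levels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import FertilityRecords, MatingCounts


def _read(name: str) -> pd.DataFrame:
    with resources.files("introsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_mating_counts() -> list[MatingCounts]:
    """The eight assayed lines' mating-pair counts."""
    frame = _read("mating_counts.csv")
    return [
        MatingCounts(
            line=row.line,
            n_ss=int(row.n_ss),
            n_si=int(row.n_si),
            n_is=int(row.n_is),
            n_ii=int(row.n_ii),
        )
        for row in frame.itertuples()
    ]


def load_fertility_line_means(group: str = "introgression") -> dict[str, float | None]:
    """Per-line mean progeny counts; lost lines map to ``None``."""
    frame = _read("fertility_lines.csv")
    frame = frame[frame["group"] == group]
    return {
        str(row.line): (None if pd.isna(row.progeny_mean) else float(row.progeny_mean))
        for row in frame.itertuples()
    }


def load_mle_estimates() -> pd.DataFrame:
    """Published per-marker (c, s) estimates; columns marker, h, c, s."""
    return _read("mle_estimates.csv")
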