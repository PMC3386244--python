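"""Table-level statistics: mating-share decomposition, fertility summaries,
linkage-disequilibrium permutation testing, and group comparison."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables do (0.525 -> 0.53)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Mating success
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatingCounts:
    """Mating-pair counts for one line (S = wild type, I = introgression;
    first letter is the female's type, second the male's)."""

    line: str
    n_ss: int
    n_si: int
    n_is: int
    n_ii: int

    def __post_init__(self) -> None:
        if min(self.n_ss, self.n_si, self.n_is, self.n_ii) < 0:
            raise ValueError("mating counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_ss + self.n_si + self.n_is + self.n_ii


@dataclass(frozen=True)
class MatingShares:
    overall: float
    female: float
    male: float


def mating_shares(counts: MatingCounts) -> MatingShares:
    """Introgression individuals' share of mating participants.

    overall = (n_si + n_is + 2 n_ii) / (2 n_total): the fraction of the
    2*n_total mating participants that came from the introgression line.
    The per-sex shares are the fraction of matings involving an introgression
    female (or male).  Overall is algebraically the mean of the two.
    """
    n = counts.n_total
    if n == 0:
        raise ValueError(f"line {counts.line}: zero matings")
    return MatingShares(
        overall=(counts.n_si + counts.n_is + 2 * counts.n_ii) / (2 * n),
        female=(counts.n_is + counts.n_ii) / n,
        male=(counts.n_si + counts.n_ii) / n,
    )


@dataclass(frozen=True)
class MatingSummary:
    per_line: pd.DataFrame
    mean_overall: float
    mean_female: float
    mean_male: float
    n_lines_below_half: int
    female_differential: float
    male_differential: float


def aggregate_mating(lines: Sequence[MatingCounts]) -> MatingSummary:
    """Unweighted across-line averages of the introgression shares.

    The differential for a sex is (wild-type share) - (introgression share)
    of that sex's matings, i.e. ``(1 - mean) - mean``.
    """
    if not lines:
        raise ValueError("need at least one line")
    rows = []
    for counts in lines:
        sh = mating_shares(counts)
        rows.append(
            {
                "line": counts.line,
                "n_total": counts.n_total,
                "overall": sh.overall,
                "female": sh.female,
                "male": sh.male,
            }
        )
    frame = pd.DataFrame(rows)
    mean_overall = float(frame["overall"].mean())
    mean_female = float(frame["female"].mean())
    mean_male = float(frame["male"].mean())
    return MatingSummary(
        per_line=frame,
        mean_overall=mean_overall,
        mean_female=mean_female,
        mean_male=mean_male,
        n_lines_below_half=int((frame["overall"] < 0.5).sum()),
        female_differential=(1.0 - mean_female) - mean_female,
        male_differential=(1.0 - mean_male) - mean_male,
    )


def sign_test_one_tailed(k_below: int, n: int) -> float:
    """Exact binomial upper tail P(X >= k_below | n, 1/2)."""
    if not 0 <= k_below <= n:
        raise ValueError(f"k_below must be in [0, {n}], got {k_below}")
    return float(sps.binom.sf(k_below - 1, n, 0.5))


# ---------------------------------------------------------------------------
# Fertility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FertilityRecords:
    """Replicate progeny counts per line; a ``None`` entry marks a lost line."""

    records: Mapping[str, Sequence[int] | None]

    def available(self) -> dict[str, np.ndarray]:
        return {
            line: np.asarray(vals, dtype=float)
            for line, vals in self.records.items()
            if vals is not None
        }


@dataclass(frozen=True)
class FertilitySummary:
    per_line: pd.DataFrame  # line, n, mean, se
    grand_mean: float  # unweighted mean of available per-line means
    anova_f: float
    anova_p: float


def fertility_grand_mean(line_means: Mapping[str, float | None]) -> float:
    """Unweighted mean of the available per-line mean progeny counts."""
    means = [m for m in line_means.values() if m is not None]
    if not means:
        raise ValueError("no line means available")
    return float(np.mean(means))


def fertility_summary(records: FertilityRecords) -> FertilitySummary:
    """Per-line mean +/- SE, grand mean over lines, and one-way ANOVA."""
    data = records.available()
    if not data:
        raise ValueError("all lines missing")
    rows = []
    for line, vals in data.items():
        if vals.size < 1:
            raise ValueError(f"line {line}: no replicates")
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append({"line": line, "n": vals.size, "mean": float(vals.mean()), "se": se})
    frame = pd.DataFrame(rows)
    groups = [v for v in data.values() if v.size > 1]
    if len(groups) >= 2:
        f_stat, p = sps.f_oneway(*groups)
    else:
        f_stat, p = float("nan"), float("nan")
    return FertilitySummary(
        per_line=frame,
        grand_mean=float(frame["mean"].mean()),
        anova_f=float(f_stat),
        anova_p=float(p),
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoLocusGenotypeTable:
    """3x3 joint genotype counts for two markers (rows = locus A genotypes)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ValueError(f"expected a 3x3 table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _log_table_probability(counts: np.ndarray) -> float:
    """Log conditional probability of a contingency table given its margins."""
    n = counts.sum()
    return float(
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(counts.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def ld_permutation_test(
    table: TwoLocusGenotypeTable,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Exact-style probability test of genotypic independence by permutation.

    Individuals' genotype labels at the second locus are shuffled against the
    first; the p-value is the fraction of shuffles whose table is at most as
    probable (conditional on margins) as the observed one.  Uses the add-one
    Monte-Carlo estimator, so p is never exactly 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    counts = table.counts
    n = table.n
    locus_a = np.repeat(np.arange(3), counts.sum(axis=1))
    locus_b = np.repeat(
        np.tile(np.arange(3), 3), counts.ravel()
    )
    obs_logp = _log_table_probability(counts)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(locus_b)
        t = np.bincount(locus_a * 3 + perm, minlength=9).reshape(3, 3)
        if _log_table_probability(t) <= obs_logp + 1e-9:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    difference: float
    t_stat: float
    f_stat: float
    p_value: float


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-sample comparison of replicate frequency means (pooled-variance t).

    ``f_stat`` is the equivalent one-way ANOVA statistic (t squared).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t_stat=float(t),
        f_stat=float(t) ** 2,
        p_value=float(p),
    )
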