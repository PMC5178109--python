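"""Urgency-by-resource-use contingency analysis.

Builds the urgency level x resource-count-bin table (bins 0 / 1 / 2 /
>=3), computes row and frequency percentages, and tests independence
with Pearson's chi-square (optionally a Monte-Carlo p-value under fixed
margins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .levels import LEVELS_ASCENDING, UrgencyLevel

__all__ = [
    "RESOURCE_BINS",
    "ContingencyTable",
    "ChiSquareResult",
    "build_table",
    "row_percentages",
    "frequency_percentages",
    "column_total_percentages",
    "chi_square_independence",
]

#: Display labels of the resource-count bins.
RESOURCE_BINS = ("0", "1", "2", ">=3")


def _bin_index(count: int) -> int:
    if count < 0:
        raise InvalidInputError(f"resource count must be >= 0, got {count}")
    return min(count, 3)


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    missing_count: int = 0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if (counts < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if counts.sum() == 0:
            raise InvalidInputError("grand total must be positive")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def retained(self) -> "ContingencyTable":
        """Drop all-zero rows and columns."""
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            row_labels=tuple(np.array(self.row_labels)[rows]),
            col_labels=tuple(np.array(self.col_labels)[cols]),
            counts=self.counts[np.ix_(rows, cols)],
            missing_count=self.missing_count,
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    warnings: tuple[str, ...] = ()
    mc_p_value: Optional[float] = None
    mc_replicates: Optional[int] = None
    mc_seed: Optional[int] = None


def build_table(
    results: Iterable[tuple[Optional[UrgencyLevel], Optional[int]]],
) -> ContingencyTable:
    """Tabulate (urgency, resource count) pairs into level x bin counts.

    A pair with a missing level or missing resource count is tallied in
    ``missing_count`` and excluded from the matrix.
    """
    counts = np.zeros((len(LEVELS_ASCENDING), len(RESOURCE_BINS)), dtype=np.int64)
    missing = 0
    for level, resources in results:
        if level is None or resources is None:
            missing += 1
            continue
        counts[int(level), _bin_index(int(resources))] += 1
    return ContingencyTable(
        row_labels=tuple(lv.name for lv in LEVELS_ASCENDING),
        col_labels=RESOURCE_BINS,
        counts=counts,
        missing_count=missing,
    )


def row_percentages(
    table: ContingencyTable, decimals: Optional[int] = 1
) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-row percentages for rows with a positive total.

    Zero-total rows are dropped with a warning.  ``decimals=None`` skips
    display rounding.
    """
    totals = table.counts.sum(axis=1)
    keep = totals > 0
    dropped = [lbl for lbl, k in zip(table.row_labels, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-total rows: {dropped}", stacklevel=2)
    pct = 100.0 * table.counts[keep] / totals[keep, None]
    if decimals is not None:
        pct = np.round(pct, decimals)
    return tuple(np.array(table.row_labels)[keep]), pct


def frequency_percentages(
    table: ContingencyTable, decimals: Optional[int] = 1
) -> dict[str, float]:
    """Per-level frequencies on the full base (classified + missing).

    Mirrors a frequency column whose denominator includes records with
    missing resource data; the ``missing`` key reports that remainder.
    """
    base = table.grand_total + table.missing_count
    out = {
        lbl: 100.0 * int(n) / base
        for lbl, n in zip(table.row_labels, table.counts.sum(axis=1))
    }
    out["missing"] = 100.0 * table.missing_count / base
    if decimals is not None:
        out = {k: round(v, decimals) for k, v in out.items()}
    return out


def column_total_percentages(
    table: ContingencyTable, decimals: Optional[int] = 1
) -> dict[str, float]:
    """Column totals as percentages of the classified (non-missing) base."""
    base = table.grand_total
    out = {
        lbl: 100.0 * int(n) / base for lbl, n in zip(table.col_labels, table.counts.sum(axis=0))
    }
    if decimals is not None:
        out = {k: round(v, decimals) for k, v in out.items()}
    return out


def chi_square_independence(
    table: ContingencyTable,
    mc_replicates: Optional[int] = None,
    seed: Optional[int] = None,
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on the retained table.

    All-zero rows/columns are dropped first.  Emits a small-expected-count
    warning when any expected cell is below 5; in that case the optional
    Monte-Carlo p-value (``mc_replicates`` tables resampled under fixed
    margins) is the robust alternative.
    """
    retained = table.retained()
    obs = retained.counts
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError("need at least 2 retained rows and columns")
    res = stats.chi2_contingency(obs, correction=yates)
    warn: list[str] = []
    n_small = int((res.expected_freq < 5).sum())
    if n_small:
        warn.append(
            f"{n_small} of {obs.size} expected cells are < 5; "
            "asymptotic p-value may be unreliable (consider mc_replicates)"
        )
    mc_p = None
    if mc_replicates:
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
        sims = sampler.rvs(mc_replicates, random_state=rng)
        exp = res.expected_freq
        sim_stats = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
        mc_p = float((1 + np.sum(sim_stats >= res.statistic - 1e-12)) / (1 + mc_replicates))
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(min(max(res.pvalue, np.nextafter(0.0, 1.0)), 1.0)),
        expected=res.expected_freq,
        warnings=tuple(warn),
        mc_p_value=mc_p,
        mc_replicates=mc_replicates,
        mc_seed=seed,
    )
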