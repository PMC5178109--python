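"""Multi-rater agreement statistics for vignette studies.

Implements Fleiss' kappa for m raters assigning N cases to k nominal
categories, with per-category components and the large-sample standard
error under the null hypothesis of chance agreement, plus a simulator
for rater panels of configurable fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .levels import UrgencyLevel

__all__ = ["RaterMatrix", "KappaResult", "fleiss_kappa", "simulate_raters"]


@dataclass(frozen=True)
class RaterMatrix:
    """Case-by-category counts: cell (i, j) = raters putting case i in category j."""

    counts: np.ndarray
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D matrix")
        if counts.shape[0] < 2:
            raise InvalidInputError("need at least 2 cases")
        if (counts < 0).any():
            raise InvalidInputError("counts must be non-negative")
        row_sums = counts.sum(axis=1)
        if row_sums.min() < 2 or len(set(row_sums.tolist())) != 1:
            raise InvalidInputError("every case needs the same number of raters (>= 2)")
        if not self.categories:
            object.__setattr__(
                self, "categories", tuple(f"cat{j}" for j in range(counts.shape[1]))
            )
        if len(self.categories) != counts.shape[1]:
            raise InvalidInputError("category labels must match matrix width")

    @property
    def n_cases(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())


@dataclass(frozen=True)
class KappaResult:
    overall: float
    per_category: Mapping[str, float]  # categories with zero marginal omitted
    se_overall: float
    z: float
    p_value: float


def fleiss_kappa(ratings: RaterMatrix) -> KappaResult:
    """Fleiss' kappa with per-category components.

    Overall kappa is ``(Pbar - Pe) / (1 - Pe)`` where ``Pbar`` is the mean
    per-case pairwise agreement and ``Pe = sum_j p_j**2``.  The standard
    error is the large-sample value under the null of chance agreement;
    the p-value is the upper normal tail (agreement above chance).
    Categories to which no rater assigned any case have an undefined
    component and are omitted from ``per_category``.
    """
    x = ratings.counts.astype(np.float64)
    n, k = x.shape
    m = ratings.n_raters
    p = x.sum(axis=0) / (n * m)  # category marginals
    if np.count_nonzero(p) < 2:
        raise DegenerateInputError("all raters used a single category; kappa undefined")
    pe = float(np.sum(p**2))
    p_i = (np.sum(x * (x - 1), axis=1)) / (m * (m - 1))
    pbar = float(p_i.mean())
    kappa = (pbar - pe) / (1.0 - pe)

    per_category: dict[str, float] = {}
    for j, label in enumerate(ratings.categories):
        pj = p[j]
        if pj == 0.0 or pj == 1.0:
            continue  # undefined, not zero
        num = float(np.sum(x[:, j] * (m - x[:, j])))
        per_category[label] = 1.0 - num / (n * m * (m - 1) * pj * (1.0 - pj))

    # Fleiss (1971) large-sample variance under the null
    sum_p2 = pe
    sum_p3 = float(np.sum(p**3))
    var0 = (
        2.0
        / (n * m * (m - 1))
        * (sum_p2 - (2 * m - 3) * sum_p2**2 + 2 * (m - 2) * sum_p3)
        / (1.0 - sum_p2) ** 2
    )
    se = float(np.sqrt(var0))
    z = kappa / se if se > 0 else float("inf")
    p_value = float(stats.norm.sf(z))
    p_value = min(max(p_value, np.nextafter(0.0, 1.0)), 1.0)
    return KappaResult(
        overall=float(kappa),
        per_category=per_category,
        se_overall=se,
        z=float(z),
        p_value=p_value,
    )


def simulate_raters(
    truth: Sequence[UrgencyLevel],
    m: int,
    fidelity: float,
    seed: Optional[int] = None,
    k: int = len(UrgencyLevel),
) -> RaterMatrix:
    """Simulate m independent raters against known true categories.

    Each rater reports the true category with probability ``fidelity``,
    otherwise one of the remaining ``k - 1`` categories uniformly.
    """
    if len(truth) == 0:
        raise InvalidInputError("truth must be non-empty")
    if not 0.0 <= fidelity <= 1.0:
        raise InvalidInputError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth)
    counts = np.zeros((n, k), dtype=np.int64)
    off = (1.0 - fidelity) / (k - 1)
    for i, t in enumerate(truth):
        probs = np.full(k, off)
        probs[int(t)] = fidelity
        counts[i] = rng.multinomial(m, probs)
    labels = tuple(level.name for level in UrgencyLevel)[:k] if k == len(UrgencyLevel) else ()
    return RaterMatrix(counts=counts, categories=labels)
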