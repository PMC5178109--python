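"""Age-stratified vital-sign score (VIPE) and its urgency color.

The score sums three sub-scores (respiratory rate, heart rate, SpO2)
looked up in age-stratified band tables, then subtracts a temperature
correction when the heart rate is elevated.  All thresholds live in a
versioned YAML configuration (:mod:`clariped.data`); this module contains
no numeric cut points.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import (
    IncompleteMeasurementError,
    InvalidInputError,
    TableConfigError,
)
from .levels import UrgencyLevel

logger = logging.getLogger(__name__)

__all__ = [
    "AgeStratum",
    "Parameter",
    "VitalSigns",
    "VipeResult",
    "VipeTables",
    "BandOverlapWarning",
    "load_tables",
    "default_tables",
    "assign_stratum",
    "score_parameter",
    "temperature_correction",
    "vipe_score",
    "color_from_total",
]


class AgeStratum(enum.Enum):
    """Age groups of the score tables (values match the config ids)."""

    NB_2MO = "NB_2MO"
    MO_3_11 = "3_11MO"
    Y_1_4 = "1_4Y"
    Y_5_12 = "5_12Y"
    GT_12Y = "GT_12Y"


class Parameter(enum.Enum):
    RR = "RR"
    HR = "HR"
    SPO2 = "SPO2"


class BandOverlapWarning(UserWarning):
    """Two bands of one table claim the same value (resolved worst-case)."""


@dataclass(frozen=True)
class VitalSigns:
    """The four measurements required for scoring (``None`` = missing)."""

    rr: Optional[float] = None
    hr: Optional[float] = None
    spo2: Optional[float] = None
    axtemp: Optional[float] = None

    def require_complete(self) -> None:
        for field in ("rr", "hr", "spo2", "axtemp"):
            if getattr(self, field) is None:
                raise IncompleteMeasurementError(field)
        if self.spo2 is not None and self.spo2 > 100:
            raise InvalidInputError(f"spo2 must be <= 100, got {self.spo2}")


@dataclass(frozen=True)
class VipeResult:
    rr_score: int
    hr_score: int
    spo2_score: int
    temp_correction: int
    total: int
    color: UrgencyLevel


@dataclass(frozen=True)
class _Band:
    lo: Optional[int]  # inclusive; None = open
    hi: Optional[int]  # inclusive; None = open
    score: int

    def contains(self, v: int) -> bool:
        if self.lo is not None and v < self.lo:
            return False
        if self.hi is not None and v > self.hi:
            return False
        return True


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


class VipeTables:
    """Validated score-band configuration.

    Loaded from YAML; validation enforces stratum coverage, band coverage
    of the measurement domain, a unique zero-score band with sub-scores
    non-decreasing away from it, and reports band overlaps as
    :class:`BandOverlapWarning` (resolved in favour of the higher score).
    """

    def __init__(self, doc: Mapping):
        self.version = str(doc.get("version", "unversioned"))
        self.strata: list[tuple[AgeStratum, int, Optional[int]]] = []
        for sid, lo, hi in doc["strata"]:
            self.strata.append((AgeStratum(sid), int(lo), None if hi is None else int(hi)))
        self.domains: dict[Parameter, tuple[int, int]] = {
            Parameter(p): (int(lo), int(hi)) for p, (lo, hi) in doc["domains"].items()
        }
        self.bands: dict[tuple[AgeStratum, Parameter], tuple[_Band, ...]] = {}
        for sid, by_param in doc["bands"].items():
            stratum = AgeStratum(sid)
            for pname, rows in by_param.items():
                param = Parameter(pname)
                bands = tuple(
                    _Band(
                        None if lo is None else int(lo),
                        None if hi is None else int(hi),
                        int(score),
                    )
                    for lo, hi, score in rows
                )
                self.bands[(stratum, param)] = bands
        tc = doc["temp_correction"]
        self.hr_score_gate = int(tc["hr_score_gate"])
        self.minus_one = (float(tc["minus_one"][0]), float(tc["minus_one"][1]))
        self.minus_two_above = float(tc["minus_two_above"])
        self.color_map: list[tuple[int, int, UrgencyLevel]] = [
            (int(lo), int(hi), UrgencyLevel.from_name(color))
            for lo, hi, color in doc["color_map"]
        ]
        self.policy: dict[UrgencyLevel, tuple[int, str]] = {
            UrgencyLevel.from_name(level): (int(wait), str(dest))
            for level, (wait, dest) in doc["policy"].items()
        }
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        self._validate_strata()
        for (stratum, param), bands in self.bands.items():
            self._validate_bands(stratum, param, bands)
        expected = {(s, p) for s, _, _ in self.strata for p in Parameter}
        if set(self.bands) != expected:
            raise TableConfigError("band tables must cover every (stratum, parameter) pair")
        if len(self.policy) != len(UrgencyLevel):
            raise TableConfigError("policy must map every urgency level")

    def _validate_strata(self) -> None:
        edges = sorted(self.strata, key=lambda t: t[1])
        if edges[0][1] != 0:
            raise TableConfigError("strata must start at age 0")
        for (_, _, hi), (_, lo2, _) in zip(edges, edges[1:]):
            if hi != lo2:
                raise TableConfigError("strata must be contiguous and disjoint")
        if edges[-1][2] is not None:
            raise TableConfigError("last stratum must be unbounded")

    def _validate_bands(self, stratum: AgeStratum, param: Parameter, bands: Sequence[_Band]) -> None:
        lo, hi = self.domains[param]
        coverage = [0] * (hi - lo + 1)
        for b in bands:
            blo = lo if b.lo is None else max(lo, b.lo)
            bhi = hi if b.hi is None else min(hi, b.hi)
            for v in range(blo, bhi + 1):
                coverage[v - lo] += 1
        gaps = [v + lo for v, c in enumerate(coverage) if c == 0]
        if gaps:
            raise TableConfigError(
                f"{stratum.value}/{param.value}: values {gaps[:5]} not covered by any band"
            )
        overlaps = [v + lo for v, c in enumerate(coverage) if c > 1]
        if overlaps:
            warnings.warn(
                f"{stratum.value}/{param.value}: bands overlap at {overlaps}; "
                "resolved in favour of the higher score",
                BandOverlapWarning,
                stacklevel=4,
            )
        scores = [b.score for b in bands]
        if scores.count(0) != 1:
            raise TableConfigError(f"{stratum.value}/{param.value}: exactly one zero band required")
        z = scores.index(0)
        left, right = scores[: z + 1], scores[z:]
        if left != sorted(left, reverse=True) or right != sorted(right):
            raise TableConfigError(
                f"{stratum.value}/{param.value}: scores must be non-decreasing away from the zero band"
            )

    # -- helpers ------------------------------------------------------

    def overlap_report(self) -> list[str]:
        """Re-run band validation and collect overlap warnings as strings."""
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", BandOverlapWarning)
            for (stratum, param), bands in self.bands.items():
                self._validate_bands(stratum, param, bands)
        return [str(w.message) for w in caught if issubclass(w.category, BandOverlapWarning)]


def load_tables(path) -> VipeTables:
    with open(path, "r", encoding="utf-8") as fh:
        return VipeTables(yaml.safe_load(fh))


_DEFAULT: Optional[VipeTables] = None


def default_tables() -> VipeTables:
    """Tables shipped with the package (loaded once, overlap warning suppressed)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("clariped.data").joinpath("vipe_tables.yaml").read_text("utf-8")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BandOverlapWarning)
            _DEFAULT = VipeTables(yaml.safe_load(text))
    return _DEFAULT


# ---------------------------------------------------------------------
# Operations


def assign_stratum(age_days: int, tables: Optional[VipeTables] = None) -> AgeStratum:
    """Map an age in days to its (unique) stratum."""
    if age_days < 0:
        raise InvalidInputError(f"age_days must be >= 0, got {age_days}")
    tables = tables or default_tables()
    for stratum, lo, hi in tables.strata:
        if age_days >= lo and (hi is None or age_days < hi):
            return stratum
    raise TableConfigError(f"no stratum covers age {age_days} days")  # pragma: no cover


def score_parameter(
    value: float,
    parameter: Parameter,
    stratum: AgeStratum,
    tables: Optional[VipeTables] = None,
) -> int:
    """Sub-score of the band containing *value* (rounded to an integer).

    Overlapping bands resolve to the higher (more urgent) score.
    """
    tables = tables or default_tables()
    v = _round_half_away(float(value))
    matches = [b.score for b in tables.bands[(stratum, parameter)] if b.contains(v)]
    if not matches:
        raise TableConfigError(
            f"{stratum.value}/{parameter.value}: no band contains {v} (table misconfigured)"
        )
    return max(matches)


def temperature_correction(
    axtemp: float, hr_score: int, tables: Optional[VipeTables] = None
) -> int:
    """0, -1 or -2 depending on axillary temperature, gated on the HR sub-score."""
    tables = tables or default_tables()
    if hr_score not in (0, 1, 2, 3, 4):
        raise InvalidInputError(f"hr_score must be 0..4, got {hr_score}")
    if not (30.0 <= axtemp <= 43.0):
        logger.warning("axillary temperature %.1f C outside physiologic range 30-43", axtemp)
    if hr_score < tables.hr_score_gate:
        return 0
    if axtemp > tables.minus_two_above:
        return -2
    lo, hi = tables.minus_one
    if lo <= axtemp <= hi:
        return -1
    return 0


def color_from_total(total: int, tables: Optional[VipeTables] = None) -> UrgencyLevel:
    """Legend mapping of a 0-12 total to its urgency color."""
    tables = tables or default_tables()
    lo_all = min(lo for lo, _, _ in tables.color_map)
    hi_all = max(hi for _, hi, _ in tables.color_map)
    if not (lo_all <= total <= hi_all):
        raise InvalidInputError(f"total must be in [{lo_all}, {hi_all}], got {total}")
    for lo, hi, color in tables.color_map:
        if lo <= total <= hi:
            return color
    raise TableConfigError(f"color map does not cover total {total}")  # pragma: no cover


def vipe_score(
    vitals: VitalSigns, age_days: int, tables: Optional[VipeTables] = None
) -> VipeResult:
    """Full score: three sub-scores, temperature correction, clamped total, color."""
    tables = tables or default_tables()
    vitals.require_complete()
    stratum = assign_stratum(age_days, tables)
    rr = score_parameter(vitals.rr, Parameter.RR, stratum, tables)
    hr = score_parameter(vitals.hr, Parameter.HR, stratum, tables)
    spo2 = score_parameter(vitals.spo2, Parameter.SPO2, stratum, tables)
    corr = temperature_correction(vitals.axtemp, hr, tables)
    total = max(0, rr + hr + spo2 + corr)
    return VipeResult(rr, hr, spo2, corr, total, color_from_total(total, tables))


def band_representatives(
    stratum: AgeStratum, parameter: Parameter, tables: Optional[VipeTables] = None
) -> Iterable[tuple[int, int]]:
    """One (value, score) per band, clipped to the measurement domain.

    Used by exhaustive-enumeration checks and the synthetic generator.
    """
    tables = tables or default_tables()
    dlo, dhi = tables.domains[parameter]
    for b in tables.bands[(stratum, parameter)]:
        lo = dlo if b.lo is None else max(dlo, b.lo)
        hi = dhi if b.hi is None else min(dhi, b.hi)
        yield (lo + hi) // 2, b.score
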