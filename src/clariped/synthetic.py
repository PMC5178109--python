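"""Synthetic encounter cohorts, rater panels, and vignette sets.

Everything here is exact-by-construction: vital signs are synthesized by
inverting the score-band tables so that re-scoring reproduces the
requested total, and injected findings realize an intended urgency level
precisely (single-finding presence guards only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .discriminators import DiscriminatorCatalog, Encounter, default_catalog
from .errors import InvalidInputError
from .levels import LEVELS_ASCENDING, UrgencyLevel
from .vipe import AgeStratum, Parameter, VipeTables, VitalSigns, default_tables, vipe_score

__all__ = ["CohortSpec", "LabeledEncounter", "synth_vitals_for_total", "synth_cohort", "synth_vignettes"]

_AGE_CAP_DAYS = 6570  # sampling cap for the unbounded oldest stratum (18 y)


def _probvec(v: Sequence[float], size: int, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (size,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise InvalidInputError(f"{name} must be {size} non-negative values summing to 1")
    return arr


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    seed: int = 0
    #: probability of each urgency level, BLUE..RED
    urgency_mix: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: probability of each age stratum, youngest..oldest
    age_mix: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: chance that the intended level is realized by a discriminator one
    #: level above the vital-sign color instead of by the score itself
    discriminator_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    #: per-level probabilities over resource bins 0 / 1 / 2 / >=3
    resource_model: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=lambda: {lv.name: (0.25, 0.25, 0.25, 0.25) for lv in LEVELS_ASCENDING}
    )

    @model_validator(mode="after")
    def _check(self):
        _probvec(self.urgency_mix, 5, "urgency_mix")
        _probvec(self.age_mix, 5, "age_mix")
        for lv in LEVELS_ASCENDING:
            if lv.name not in self.resource_model:
                raise InvalidInputError(f"resource_model missing level {lv.name}")
            _probvec(self.resource_model[lv.name], 4, f"resource_model[{lv.name}]")
        return self


@dataclass(frozen=True)
class LabeledEncounter:
    encounter: Encounter
    intended_level: UrgencyLevel
    resource_bin: int  # 0..3 (3 = ">=3")


# ---------------------------------------------------------------------
# Vital-sign synthesis by table inversion


def _value_in_band(band, domain: tuple[int, int], rng: np.random.Generator) -> int:
    lo = domain[0] if band.lo is None else max(domain[0], band.lo)
    hi = domain[1] if band.hi is None else min(domain[1], band.hi)
    return int(rng.integers(lo, hi + 1))


def _sample_param(
    stratum: AgeStratum,
    param: Parameter,
    score: int,
    tables: VipeTables,
    rng: np.random.Generator,
) -> int:
    from .vipe import score_parameter  # local import to avoid cycle at module load

    bands = [b for b in tables.bands[(stratum, param)] if b.score == score]
    band = bands[int(rng.integers(len(bands)))]
    value = _value_in_band(band, tables.domains[param], rng)
    if score_parameter(value, param, stratum, tables) == score:
        return value
    # overlapping bands resolve worst-case, so an edge value can score
    # higher than its band; scan the band for a value that scores right
    lo = tables.domains[param][0] if band.lo is None else band.lo
    hi = tables.domains[param][1] if band.hi is None else band.hi
    for v in range(lo, hi + 1):
        if score_parameter(v, param, stratum, tables) == score:
            return v
    raise InvalidInputError(
        f"band for score {score} of {stratum.value}/{param.value} is fully shadowed"
    )


def _decompositions(
    stratum: AgeStratum, target: int, tables: VipeTables, require_rr_zero: bool
) -> list[tuple[int, int, int, int]]:
    avail = {
        p: sorted({b.score for b in tables.bands[(stratum, p)]}) for p in Parameter
    }
    out = []
    for r in avail[Parameter.RR]:
        if require_rr_zero and r != 0:
            continue
        for h in avail[Parameter.HR]:
            for s in avail[Parameter.SPO2]:
                for c in (0, -1, -2):
                    if c < 0 and h < tables.hr_score_gate:
                        continue
                    if r + h + s + c == target:
                        out.append((r, h, s, c))
    return out


def synth_vitals_for_total(
    stratum: AgeStratum,
    target_total: int,
    seed: Optional[int] = None,
    tables: Optional[VipeTables] = None,
    rng: Optional[np.random.Generator] = None,
    require_rr_zero: bool = False,
) -> VitalSigns:
    """Vitals whose score total equals ``target_total`` exactly.

    Samples uniformly over feasible (rr, hr, spo2, correction) sub-score
    decompositions and then over band interiors; the result is verified
    by re-scoring before being returned.
    """
    tables = tables or default_tables()
    rng = rng if rng is not None else np.random.default_rng(seed)
    decomps = _decompositions(stratum, target_total, tables, require_rr_zero)
    if not decomps:
        raise InvalidInputError(
            f"no sub-score decomposition reaches total {target_total} in {stratum.value}"
        )
    r, h, s, c = decomps[int(rng.integers(len(decomps)))]
    rr = _sample_param(stratum, Parameter.RR, r, tables, rng)
    hr = _sample_param(stratum, Parameter.HR, h, tables, rng)
    spo2 = _sample_param(stratum, Parameter.SPO2, s, tables, rng)
    if c == 0:
        axtemp = round(float(rng.uniform(36.0, 37.4)), 1)
    elif c == -1:
        axtemp = round(float(rng.uniform(37.5, 38.5)), 1)
    else:
        axtemp = round(float(rng.uniform(38.6, 40.5)), 1)
    vitals = VitalSigns(rr=float(rr), hr=float(hr), spo2=float(spo2), axtemp=axtemp)
    # verify by re-scoring at a representative age of the stratum
    age = _representative_age(stratum, tables)
    check = vipe_score(vitals, age, tables)
    assert check.total == target_total, "table inversion produced a mismatching total"
    return vitals


def _representative_age(stratum: AgeStratum, tables: VipeTables) -> int:
    for s, lo, hi in tables.strata:
        if s == stratum:
            return lo if hi is None else (lo + hi - 1) // 2
    raise InvalidInputError(f"unknown stratum {stratum}")


def _sample_age(
    stratum: AgeStratum, tables: VipeTables, rng: np.random.Generator, min_age: int = 0
) -> int:
    for s, lo, hi in tables.strata:
        if s == stratum:
            hi = _AGE_CAP_DAYS if hi is None else hi
            lo = max(lo, min_age)
            return int(rng.integers(lo, hi))
    raise InvalidInputError(f"unknown stratum {stratum}")


def _level_total_range(level: UrgencyLevel, tables: VipeTables) -> tuple[int, int]:
    for lo, hi, color in tables.color_map:
        if color == level:
            return lo, hi
    raise InvalidInputError(f"no total band for level {level}")


def _injectable_codes(catalog: DiscriminatorCatalog, level: UrgencyLevel) -> list:
    """Entries realizable by a single finding with no side conditions."""
    out = []
    for e in catalog.entries:
        if e.level == level and len(e.guard) == 1 and e.guard[0].finding is not None:
            out.append(e)
    return sorted(out, key=lambda e: e.code)


# ---------------------------------------------------------------------
# Cohort and vignette generation


def synth_cohort(
    spec: CohortSpec,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
) -> list[LabeledEncounter]:
    """Generate a cohort whose classified levels match the intended labels.

    Each record's intended level is realized either through the
    vital-sign score alone or (with probability ``discriminator_rate``)
    through a single injected finding one level above the score color.
    Resource-use bins are drawn from the per-level resource model.
    Reproducible under ``spec.seed``.
    """
    catalog = catalog or default_catalog()
    tables = tables or default_tables()
    rng = np.random.default_rng(spec.seed)
    levels = rng.choice(5, size=spec.n, p=np.asarray(spec.urgency_mix))
    strata_idx = rng.choice(5, size=spec.n, p=np.asarray(spec.age_mix))
    strata_order = [s for s, _, _ in tables.strata]
    out: list[LabeledEncounter] = []
    for i in range(spec.n):
        level = UrgencyLevel(int(levels[i]))
        stratum = strata_order[int(strata_idx[i])]
        inject = level > UrgencyLevel.BLUE and rng.random() < spec.discriminator_rate
        vitals_level = UrgencyLevel(int(level) - 1) if inject else level
        lo, hi = _level_total_range(vitals_level, tables)
        target = int(rng.integers(lo, hi + 1))
        # keep RR points out of low-urgency records: a nonzero RR
        # sub-score would itself trigger the tachypnea discriminator
        require_rr_zero = level < UrgencyLevel.YELLOW or (inject and vitals_level < UrgencyLevel.YELLOW)
        vitals = synth_vitals_for_total(
            stratum, target, tables=tables, rng=rng, require_rr_zero=require_rr_zero
        )
        findings: list[str] = []
        if inject:
            candidates = _injectable_codes(catalog, level)
            entry = candidates[int(rng.integers(len(candidates)))]
            findings.append(entry.guard[0].finding)
        # newborn age would mandatorily assert YELLOW; avoid it when the
        # intended level is below that
        min_age = 29 if level < UrgencyLevel.YELLOW else 0
        age = _sample_age(stratum, tables, rng, min_age=min_age)
        rbin = int(rng.choice(4, p=np.asarray(spec.resource_model[level.name])))
        resource_count = rbin if rbin < 3 else int(rng.integers(3, 6))
        enc = Encounter(
            id=f"synth-{i:05d}",
            age_days=age,
            rr=vitals.rr,
            hr=vitals.hr,
            spo2=vitals.spo2,
            axtemp_c=vitals.axtemp,
            pain_level=0,
            general_appearance="well",
            findings=frozenset(findings),
            resource_count=resource_count,
        )
        out.append(LabeledEncounter(encounter=enc, intended_level=level, resource_bin=rbin))
    return out


def synth_vignettes(
    n_cases: int,
    mix: Sequence[float],
    seed: Optional[int] = None,
    tables: Optional[VipeTables] = None,
) -> tuple[list[UrgencyLevel], list[dict]]:
    """Labeled hypothetical cases for agreement studies.

    Returns the true urgency labels (drawn from ``mix``, BLUE..RED) and
    printable vignette rows carrying the synthesized age and vitals.
    """
    if n_cases < 1:
        raise InvalidInputError("n_cases must be >= 1")
    probs = _probvec(mix, 5, "mix")
    tables = tables or default_tables()
    rng = np.random.default_rng(seed)
    labels = [UrgencyLevel(int(j)) for j in rng.choice(5, size=n_cases, p=probs)]
    strata_order = [s for s, _, _ in tables.strata]
    rows = []
    for i, level in enumerate(labels):
        stratum = strata_order[int(rng.integers(5))]
        lo, hi = _level_total_range(level, tables)
        target = int(rng.integers(lo, hi + 1))
        vitals = synth_vitals_for_total(stratum, target, tables=tables, rng=rng)
        min_age = 29 if level < UrgencyLevel.YELLOW else 0
        rows.append(
            {
                "case": i + 1,
                "age_days": _sample_age(stratum, tables, rng, min_age=min_age),
                "rr": vitals.rr,
                "hr": vitals.hr,
                "spo2": vitals.spo2,
                "axtemp_c": vitals.axtemp,
                "intended_level": level.name,
            }
        )
    return labels, rows
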