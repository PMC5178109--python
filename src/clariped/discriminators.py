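"""Data-driven discriminator catalog and evaluation engine.

Discriminators assert a minimum urgency level when their guard — a
conjunction of finding-presence, numeric and age conditions — holds for
an encounter.  The default catalog (``clariped/data/catalog.yaml``)
encodes the mandatory general discriminators and the complaint-triggered
ones; the engine itself is rule-agnostic.

Guard safety: a condition that references an absent optional measurement
never raises — the entry is simply not triggered, and a "measurement
indicated but absent" advisory is recorded when every other condition of
the guard already holds.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Any, FrozenSet, Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import CatalogError, IncompleteEncounterError, InvalidInputError
from .levels import UrgencyLevel
from .vipe import Parameter, VipeTables, VitalSigns, assign_stratum, default_tables, score_parameter

logger = logging.getLogger(__name__)

__all__ = [
    "Appearance",
    "BurnCategory",
    "Encounter",
    "GuardCondition",
    "Discriminator",
    "DiscriminatorCatalog",
    "Triggered",
    "Advisory",
    "load_catalog",
    "default_catalog",
    "evaluate_mandatory",
    "evaluate_complaints",
    "evaluate_all",
    "max_discriminator_level",
]


class Appearance(str, enum.Enum):
    CRITICAL = "critical"
    VERY_ILL = "very_ill"
    ILL = "ill"
    LITTLE_ILL = "little_ill"
    WELL = "well"


class BurnCategory(str, enum.Enum):
    FACE_INHALATION = "face_inhalation"
    ELECTRICAL_CIRCUMFERENTIAL_CHEMICAL = "electrical_circumferential_chemical"
    MODERATE_GT20 = "moderate_gt20"
    MILD_LT10 = "mild_lt10"


class Encounter(BaseModel):
    """One patient presentation.

    Vital signs and assessment fields are optional at the model level so
    that partially filled rows can be represented; the operations that
    require them raise named errors when they are missing.
    """

    model_config = ConfigDict(frozen=True)

    id: Optional[str] = None
    age_days: int = Field(ge=0)
    rr: Optional[float] = Field(default=None, ge=0)
    hr: Optional[float] = Field(default=None, ge=0)
    spo2: Optional[float] = Field(default=None, ge=0, le=100)
    axtemp_c: Optional[float] = None
    pain_level: Optional[int] = Field(default=None, ge=0, le=10)
    general_appearance: Optional[Appearance] = None
    fever_report_max_c: Optional[float] = None
    returns_24h: int = Field(default=0, ge=0)
    returns_72h: int = Field(default=0, ge=0)
    findings: FrozenSet[str] = frozenset()
    cbg_mg_dl: Optional[float] = Field(default=None, ge=0)
    bp_systolic: Optional[float] = Field(default=None, ge=0)
    bp_diastolic: Optional[float] = Field(default=None, ge=0)
    injury_age_hours: Optional[float] = Field(default=None, ge=0)
    burn_category: Optional[BurnCategory] = None
    resource_count: Optional[int] = Field(default=None, ge=0)

    @field_validator("findings", mode="before")
    @classmethod
    def _coerce_findings(cls, v):
        if isinstance(v, str):
            v = [tok.strip() for tok in v.split(";") if tok.strip()]
        return frozenset(v)

    @property
    def vitals(self) -> VitalSigns:
        return VitalSigns(rr=self.rr, hr=self.hr, spo2=self.spo2, axtemp=self.axtemp_c)


_OPS = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
    "between": lambda a, b: b[0] <= a <= b[1],
}


@dataclass(frozen=True)
class GuardCondition:
    """One conjunct: finding presence or a field comparison."""

    finding: Optional[str] = None
    field: Optional[str] = None
    op: Optional[str] = None
    value: Any = None

    def __post_init__(self):
        if (self.finding is None) == (self.field is None):
            raise CatalogError("condition must have exactly one of 'finding' or 'field'")
        if self.field is not None and self.op not in _OPS:
            raise CatalogError(f"unknown operator {self.op!r}")
        if isinstance(self.value, list):
            object.__setattr__(self, "value", tuple(self.value))

    def evaluate(self, context: Mapping[str, Any], findings: FrozenSet[str]) -> Optional[bool]:
        """True/False, or ``None`` when a referenced field is absent."""
        if self.finding is not None:
            return self.finding in findings
        actual = context.get(self.field)
        if actual is None:
            return None
        if isinstance(actual, enum.Enum):
            actual = actual.value
        return _OPS[self.op](actual, self.value)


@dataclass(frozen=True)
class Discriminator:
    code: str
    label: str
    category: str
    level: UrgencyLevel
    guard: tuple[GuardCondition, ...]
    mandatory: bool = False
    prov: str = ""


@dataclass(frozen=True)
class Triggered:
    discriminator: Discriminator
    level: UrgencyLevel

    @property
    def code(self) -> str:
        return self.discriminator.code


@dataclass(frozen=True)
class Advisory:
    """A guard's measurable conditions held but a measurement was absent."""

    code: str
    field: str


#: Categories whose entries may be flagged mandatory.
MANDATORY_CATEGORIES = frozenset({"general"})


@dataclass
class DiscriminatorCatalog:
    version: str
    entries: tuple[Discriminator, ...]
    vocabulary: FrozenSet[str]
    census: Mapping[str, int]
    fever_threshold_c: float = 37.5
    _by_code: dict = dc_field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_code = {e.code: e for e in self.entries}
        self._validate()

    def _validate(self) -> None:
        if len(self._by_code) != len(self.entries):
            raise CatalogError("duplicate discriminator codes")
        for e in self.entries:
            if e.mandatory and e.category not in MANDATORY_CATEGORIES:
                raise CatalogError(f"{e.code}: only general entries may be mandatory")
            for cond in e.guard:
                if cond.finding is not None and cond.finding not in self.vocabulary:
                    raise CatalogError(f"{e.code}: finding {cond.finding!r} not in vocabulary")

    def __getitem__(self, code: str) -> Discriminator:
        return self._by_code[code]

    def by_level(self, level: UrgencyLevel) -> tuple[Discriminator, ...]:
        return tuple(e for e in self.entries if e.level == level)

    def lint(self) -> dict:
        """Census and provenance checks; returns a machine-readable report.

        Counts one anchor per distinct provenance string per category (an
        entry set that splits a single rule into several guards shares one
        anchor) and compares against the declared census.
        """
        anchors: dict[str, set[str]] = {}
        missing_prov = [e.code for e in self.entries if not e.prov]
        for e in self.entries:
            anchors.setdefault(e.category, set()).add(e.prov)
        observed = {cat: len(provs) for cat, provs in anchors.items()}
        mismatches = {
            cat: {"expected": self.census.get(cat, 0), "observed": observed.get(cat, 0)}
            for cat in set(self.census) | set(observed)
            if self.census.get(cat, 0) != observed.get(cat, 0)
        }
        return {
            "version": self.version,
            "n_entries": len(self.entries),
            "n_anchors": sum(observed.values()),
            "census_observed": observed,
            "census_mismatches": mismatches,
            "entries_missing_provenance": missing_prov,
            "ok": not mismatches and not missing_prov,
        }


def _parse_entry(raw: Mapping) -> Discriminator:
    guard = tuple(
        GuardCondition(
            finding=c.get("finding"),
            field=c.get("field"),
            op=c.get("op"),
            value=c.get("value"),
        )
        for c in raw["guard"]
    )
    return Discriminator(
        code=raw["code"],
        label=raw["label"],
        category=raw["category"],
        level=UrgencyLevel.from_name(raw["level"]),
        guard=guard,
        mandatory=bool(raw.get("mandatory", False)),
        prov=raw.get("prov", ""),
    )


def load_catalog(path) -> DiscriminatorCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _catalog_from_doc(doc)


def _catalog_from_doc(doc: Mapping) -> DiscriminatorCatalog:
    return DiscriminatorCatalog(
        version=str(doc.get("version", "unversioned")),
        entries=tuple(_parse_entry(raw) for raw in doc["entries"]),
        vocabulary=frozenset(doc["vocabulary"]),
        census=dict(doc.get("census", {})),
        fever_threshold_c=float(doc.get("context", {}).get("fever_threshold_c", 37.5)),
    )


_DEFAULT: Optional[DiscriminatorCatalog] = None


def default_catalog() -> DiscriminatorCatalog:
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("clariped.data").joinpath("catalog.yaml").read_text("utf-8")
        _DEFAULT = _catalog_from_doc(yaml.safe_load(text))
    return _DEFAULT


# ---------------------------------------------------------------------
# Evaluation


def guard_context(
    enc: Encounter,
    catalog: DiscriminatorCatalog,
    tables: Optional[VipeTables] = None,
) -> dict[str, Any]:
    """Field values visible to guards, including derived ones.

    Derived fields: ``rr_score`` (respiratory-rate sub-score, present only
    when RR is measured) and ``fever_present`` (measured or reported
    temperature at/above the fever threshold; absent when neither source
    is available).
    """
    ctx: dict[str, Any] = {
        "age_days": enc.age_days,
        "pain_level": enc.pain_level,
        "general_appearance": enc.general_appearance,
        "fever_report_max_c": enc.fever_report_max_c,
        "returns_24h": enc.returns_24h,
        "returns_72h": enc.returns_72h,
        "cbg_mg_dl": enc.cbg_mg_dl,
        "bp_systolic": enc.bp_systolic,
        "bp_diastolic": enc.bp_diastolic,
        "injury_age_hours": enc.injury_age_hours,
        "burn_category": enc.burn_category,
        "axtemp_c": enc.axtemp_c,
    }
    if enc.rr is not None:
        tables = tables or default_tables()
        stratum = assign_stratum(enc.age_days, tables)
        ctx["rr_score"] = score_parameter(enc.rr, Parameter.RR, stratum, tables)
    thr = catalog.fever_threshold_c
    temps = [t for t in (enc.axtemp_c, enc.fever_report_max_c) if t is not None]
    ctx["fever_present"] = max(temps) >= thr if temps else None
    return ctx


def _evaluate_entries(
    enc: Encounter,
    catalog: DiscriminatorCatalog,
    entries: Iterable[Discriminator],
    tables: Optional[VipeTables] = None,
    advisories: Optional[list[Advisory]] = None,
) -> set[Triggered]:
    unknown = enc.findings - catalog.vocabulary
    if unknown:
        raise InvalidInputError(f"unknown finding codes: {sorted(unknown)}")
    ctx = guard_context(enc, catalog, tables)
    out: set[Triggered] = set()
    for entry in entries:
        verdicts = [cond.evaluate(ctx, enc.findings) for cond in entry.guard]
        if all(v is True for v in verdicts):
            if entry.level > UrgencyLevel.BLUE:  # BLUE entries are the floor
                out.add(Triggered(entry, entry.level))
        elif None in verdicts and all(v is not False for v in verdicts):
            for cond, v in zip(entry.guard, verdicts):
                if v is None:
                    logger.info("measurement %s indicated by %s but absent", cond.field, entry.code)
                    if advisories is not None:
                        advisories.append(Advisory(entry.code, cond.field))
    return out


def evaluate_mandatory(
    enc: Encounter,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
    advisories: Optional[list[Advisory]] = None,
) -> set[Triggered]:
    """Evaluate the mandatory general discriminators.

    Requires pain level and general appearance to be recorded.
    """
    catalog = catalog or default_catalog()
    if enc.pain_level is None:
        raise IncompleteEncounterError("pain_level")
    if enc.general_appearance is None:
        raise IncompleteEncounterError("general_appearance")
    entries = [e for e in catalog.entries if e.mandatory]
    return _evaluate_entries(enc, catalog, entries, tables, advisories)


def evaluate_complaints(
    enc: Encounter,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
    advisories: Optional[list[Advisory]] = None,
) -> set[Triggered]:
    """Evaluate the complaint-triggered discriminators."""
    catalog = catalog or default_catalog()
    entries = [e for e in catalog.entries if not e.mandatory]
    return _evaluate_entries(enc, catalog, entries, tables, advisories)


def evaluate_all(
    enc: Encounter,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
    advisories: Optional[list[Advisory]] = None,
) -> set[Triggered]:
    catalog = catalog or default_catalog()
    return evaluate_mandatory(enc, catalog, tables, advisories) | evaluate_complaints(
        enc, catalog, tables, advisories
    )


def max_discriminator_level(triggered: Iterable[Triggered]) -> Optional[UrgencyLevel]:
    """Maximum asserted level, or ``None`` when nothing triggered."""
    levels = [t.level for t in triggered]
    return max(levels) if levels else None
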