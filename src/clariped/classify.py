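"""Two-step classification: score color, discriminator upgrade, policy.

The final level is the maximum of the vital-sign score color and every
triggered discriminator level — discriminators may only raise the
urgency, never lower it.  The final level indexes the waiting-time /
destination policy, and life-threat (RED) discriminators short-circuit
into a fast path that sends the patient straight to care, with the
classification recorded retrospectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .discriminators import (
    Advisory,
    DiscriminatorCatalog,
    Encounter,
    Triggered,
    default_catalog,
    evaluate_all,
    max_discriminator_level,
)
from .errors import ClaripedError
from .levels import UrgencyLevel
from .vipe import VipeResult, VipeTables, default_tables, vipe_score

__all__ = ["TriageResult", "RowError", "classify", "fast_path_check", "classify_batch"]


@dataclass(frozen=True)
class TriageResult:
    encounter_id: Optional[str]
    vipe: VipeResult
    triggered: tuple[Triggered, ...]
    final_level: UrgencyLevel
    max_wait_minutes: int
    destination: str
    fast_path: bool
    #: which rule set the final level: "vipe" or a discriminator code
    decided_by: str
    advisories: tuple[Advisory, ...] = ()

    @property
    def retrospective_classification(self) -> bool:
        """Fast-path patients are classified after being sent to care."""
        return self.fast_path

    @property
    def triggered_codes(self) -> tuple[str, ...]:
        return tuple(sorted(t.code for t in self.triggered))


@dataclass(frozen=True)
class RowError:
    index: int
    encounter_id: Optional[str]
    message: str


def classify(
    enc: Encounter,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
) -> TriageResult:
    """Classify one encounter end to end.

    Evaluates every discriminator (not only those above the score color)
    so the result carries a full provenance trace; the outcome is
    identical because only the maximum matters.
    """
    catalog = catalog or default_catalog()
    tables = tables or default_tables()
    vipe = vipe_score(enc.vitals, enc.age_days, tables)
    advisories: list[Advisory] = []
    triggered = evaluate_all(enc, catalog, tables, advisories)
    disc_level = max_discriminator_level(triggered)
    if disc_level is not None and disc_level > vipe.color:
        final = disc_level
        winners = sorted(t.code for t in triggered if t.level == disc_level)
        decided_by = winners[0]
    else:
        final = vipe.color
        decided_by = "vipe"
    wait, destination = tables.policy[final]
    fast = any(t.level == UrgencyLevel.RED for t in triggered)
    return TriageResult(
        encounter_id=enc.id,
        vipe=vipe,
        triggered=tuple(sorted(triggered, key=lambda t: (-t.level, t.code))),
        final_level=final,
        max_wait_minutes=wait,
        destination=destination,
        fast_path=fast,
        decided_by=decided_by,
        advisories=tuple(advisories),
    )


def fast_path_check(
    enc: Encounter,
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
) -> bool:
    """True iff a life-threat (RED) discriminator triggers on available fields.

    Uses only the discriminator step, so it can run before any vital sign
    is measured or any administrative procedure happens; mandatory fields
    that are still unrecorded are simply not evaluated.
    """
    catalog = catalog or default_catalog()
    try:
        triggered = evaluate_all(enc, catalog, tables)
    except ClaripedError:
        # before full registration, fall back to what can be evaluated
        from .discriminators import evaluate_complaints

        triggered = evaluate_complaints(enc, catalog, tables)
    return any(t.level == UrgencyLevel.RED for t in triggered)


def classify_batch(
    encounters: Iterable[Encounter],
    catalog: Optional[DiscriminatorCatalog] = None,
    tables: Optional[VipeTables] = None,
) -> tuple[list[TriageResult], list[RowError]]:
    """Classify a stream, collecting per-row failures instead of raising.

    Order-preserving: results appear in input order; a failed row is
    recorded with its index and skipped.
    """
    catalog = catalog or default_catalog()
    tables = tables or default_tables()
    results: list[TriageResult] = []
    errors: list[RowError] = []
    for i, enc in enumerate(encounters):
        try:
            results.append(classify(enc, catalog, tables))
        except ClaripedError as exc:
            errors.append(RowError(index=i, encounter_id=enc.id, message=str(exc)))
    return results, errors
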