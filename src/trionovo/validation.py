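"""Trio de novo classification, control screening, and candidate exclusion.

A candidate causal variant for a sporadic dominant disorder must be de novo
(carried heterozygously by the proband, absent from both parents), absent
from unaffected controls, and technically real (confirmed by an orthogonal
assay — here abstracted as a confirmation oracle, since chromatogram
base-calling is out of scope). ``exclude_non_causal`` applies those three
exclusions jointly; a variant inherited in one carrier but de novo in
another is retained, because a single genuine de novo observation
dominates, whereas a variant inherited in *every* carrier trio is out.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ConfirmationOracle, ControlGenotypes
from .model import CandidateVariant, GenotypeMap, Trio, Variant, Zygosity

__all__ = [
    "TrioClassification",
    "classify_trio",
    "control_screen",
    "confirm_variant",
    "exclude_non_causal",
    "RemovalReason",
    "ExclusionLog",
]


class TrioClassification(enum.Enum):
    de_novo = "de_novo"
    inherited_paternal = "inherited_paternal"
    inherited_maternal = "inherited_maternal"
    inherited_either = "inherited_either"
    unknown_parent = "unknown_parent"
    absent_in_proband = "absent_in_proband"

    @property
    def is_inherited(self) -> bool:
        return self in (
            TrioClassification.inherited_paternal,
            TrioClassification.inherited_maternal,
            TrioClassification.inherited_either,
        )


def classify_trio(
    variant: Variant, trio: Trio, genotypes: GenotypeMap
) -> TrioClassification:
    """Classify a proband call against the parental genotypes.

    Rules, in order: a non-carrier proband is ``absent_in_proband``; a
    carrier parent gives the corresponding inherited status (both carriers:
    ``inherited_either``); otherwise any unavailable or missing parent
    genotype gives ``unknown_parent``; both parents homozygous reference
    gives ``de_novo``. A missing proband genotype is an error, not a class.
    """
    key = variant.key
    proband = genotypes.get(trio.proband_id, key)
    if proband is Zygosity.missing:
        raise ValueError(
            f"proband {trio.proband_id} has no genotype at {key}"
        )
    if not proband.is_carrier:
        return TrioClassification.absent_in_proband

    def parent_zyg(parent_id, available):
        if not available or parent_id is None:
            return None
        zyg = genotypes.get(parent_id, key)
        return None if zyg is Zygosity.missing else zyg

    father = parent_zyg(trio.father_id, trio.father_available)
    mother = parent_zyg(trio.mother_id, trio.mother_available)
    father_carrier = father is not None and father.is_carrier
    mother_carrier = mother is not None and mother.is_carrier
    if father_carrier and mother_carrier:
        return TrioClassification.inherited_either
    if father_carrier:
        return TrioClassification.inherited_paternal
    if mother_carrier:
        return TrioClassification.inherited_maternal
    if father is None or mother is None:
        return TrioClassification.unknown_parent
    return TrioClassification.de_novo


def control_screen(variant: Variant, controls: ControlGenotypes) -> int:
    """Number of control individuals carrying at least one alt allele."""
    return len(controls.carriers(variant.key))


def confirm_variant(candidate: CandidateVariant, oracle: ConfirmationOracle) -> bool:
    """Check every carrier call against the confirmation oracle.

    The candidate is confirmed when at least one carrier call validates;
    an oracle with no entry for a queried call raises (no silent pass).
    """
    outcomes = [
        oracle.confirmed(candidate.variant.key, carrier)
        for carrier in candidate.carrier_ids
    ]
    return any(outcomes)


class RemovalReason(enum.Enum):
    confirmation_failed = "confirmation_failed"
    control_carriers = "control_carriers"
    inherited_in_all_carriers = "inherited_in_all_carriers"


@dataclass
class ExclusionLog:
    removed: dict = field(default_factory=dict)  # VariantKey -> RemovalReason

    def record(self, candidate: CandidateVariant, reason: RemovalReason) -> None:
        self.removed[candidate.variant.key] = reason


def exclude_non_causal(
    candidates: Sequence[CandidateVariant],
    trios: Iterable[Trio],
    genotypes: GenotypeMap,
    controls: ControlGenotypes,
    oracle: ConfirmationOracle,
    log: ExclusionLog | None = None,
) -> list[CandidateVariant]:
    """Drop unconfirmed, control-carried, and uniformly inherited candidates.

    Each surviving candidate is annotated in place with its per-carrier trio
    classification, control carrier count and confirmation status. A
    candidate whose carrier statuses are all ``unknown_parent`` survives but
    is flagged ``unvalidated``.
    """
    trio_by_proband: Mapping[str, Trio] = {t.proband_id: t for t in trios}
    log = log if log is not None else ExclusionLog()
    survivors: list[CandidateVariant] = []
    for cand in candidates:
        cand.sanger_confirmed = confirm_variant(cand, oracle)
        cand.control_carrier_count = control_screen(cand.variant, controls)
        statuses = {}
        for carrier in cand.carrier_ids:
            trio = trio_by_proband.get(carrier)
            if trio is None:
                statuses[carrier] = TrioClassification.unknown_parent
            else:
                statuses[carrier] = classify_trio(cand.variant, trio, genotypes)
        cand.de_novo_status = statuses
        if not cand.sanger_confirmed:
            log.record(cand, RemovalReason.confirmation_failed)
            continue
        if cand.control_carrier_count >= 1:
            log.record(cand, RemovalReason.control_carriers)
            continue
        carrier_statuses = [
            s for s in statuses.values() if s is not TrioClassification.absent_in_proband
        ]
        if carrier_statuses and all(s.is_inherited for s in carrier_statuses):
            log.record(cand, RemovalReason.inherited_in_all_carriers)
            continue
        cand.unvalidated = not any(
            s is TrioClassification.de_novo for s in carrier_statuses
        )
        survivors.append(cand)
    return survivors
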