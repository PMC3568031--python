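"""Core domain types for trio-cohort variant prioritization.

The central object is a :class:`Variant`: one genomic substitution or small
indel with its gene, consequence, and protein-change annotation. Variant
*identity* is the 4-tuple ``(chromosome, position, ref, alt)``; annotations
are attributes, not identity. This distinction matters: two different
substitutions at the same position (e.g. D801N and D801Y of ATP1A3, both at
chr19:42474557) are different variants, and conflating them — matching a
query against a known-variant database by position alone — is exactly the
failure mode the filter cascade exposes via its ``position_only`` mode.

Coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "Consequence",
    "Zygosity",
    "VariantKey",
    "Variant",
    "GenotypeCall",
    "GenotypeMap",
    "Trio",
    "KnownVariantRecord",
    "KnownVariantDB",
    "GeneSet",
    "StageCounts",
    "CascadeReport",
    "CandidateVariant",
    "PhenotypeRecord",
    "PHENOTYPE_SCHEMA",
    "VariantTable",
    "ModelError",
    "VocabularyError",
]


class ModelError(ValueError):
    """Invariant violation in a core domain object."""


class VocabularyError(ModelError):
    """A term outside one of the closed vocabularies."""


class Consequence(enum.Enum):
    """Closed consequence vocabulary, one annotation per variant.

    When a source supplies several annotations for one variant, the most
    severe by the order of this listing is kept.
    """

    missense = "missense"
    synonymous = "synonymous"
    splice_acceptor = "splice_acceptor"
    splice_donor = "splice_donor"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    other = "other"

    @classmethod
    def from_term(cls, term: str) -> "Consequence":
        try:
            return cls(term.strip().lower())
        except ValueError:
            raise VocabularyError(
                f"unknown consequence term {term!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


#: Severity rank used to pick one annotation per variant (lower = kept).
CONSEQUENCE_SEVERITY = {c: i for i, c in enumerate(Consequence)}

#: Protein-altering / splice consequence classes retained by the cascade.
NSSS_CLASSES = frozenset(
    {
        Consequence.missense,
        Consequence.splice_acceptor,
        Consequence.splice_donor,
        Consequence.frameshift_indel,
        Consequence.inframe_indel,
    }
)


class Zygosity(enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    @classmethod
    def from_term(cls, term: str) -> "Zygosity":
        try:
            return cls(term.strip().lower())
        except ValueError:
            raise VocabularyError(f"unknown zygosity {term!r}") from None

    @property
    def is_carrier(self) -> bool:
        return self in (Zygosity.het, Zygosity.hom_alt)


VariantKey = tuple  # (chromosome, position, ref_allele, alt_allele)

_NUC = set("ACGTN")


@dataclass(frozen=True)
class Variant:
    """One annotated substitution or small indel.

    ``protein_change`` uses the single-letter short form ("D801N") and is
    present exactly when the consequence is missense or synonymous.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str] = None
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    consequence: Consequence = Consequence.other

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ModelError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ModelError(
                f"ref and alt alleles are identical ({self.ref_allele!r}) at "
                f"{self.chromosome}:{self.position}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele.upper()) <= _NUC:
                raise ModelError(f"malformed allele {allele!r}")
        coding = self.consequence in (Consequence.missense, Consequence.synonymous)
        if coding and not self.protein_change:
            raise ModelError(
                f"{self.consequence.value} variant at {self.chromosome}:"
                f"{self.position} requires a protein_change"
            )
        if not coding and self.protein_change:
            raise ModelError(
                f"protein_change {self.protein_change!r} given for "
                f"{self.consequence.value} consequence"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    variant_key: VariantKey
    zygosity: Zygosity


class GenotypeMap:
    """Sample x variant genotype lookup with absent-means-reference semantics.

    Cohort variant tables list only sites with at least one non-reference
    call; a sample without a record at a listed site is homozygous
    reference. An explicitly uncalled genotype must be stored as
    ``Zygosity.missing``.
    """

    def __init__(self, calls: Iterable[GenotypeCall] = ()) -> None:
        self._calls: dict[tuple[str, VariantKey], Zygosity] = {}
        for call in calls:
            self.add(call)

    def add(self, call: GenotypeCall) -> None:
        self._calls[(call.sample_id, call.variant_key)] = call.zygosity

    def set(self, sample_id: str, key: VariantKey, zygosity: Zygosity) -> None:
        self._calls[(sample_id, key)] = zygosity

    def get(
        self, sample_id: str, key: VariantKey, default: Zygosity = Zygosity.hom_ref
    ) -> Zygosity:
        return self._calls.get((sample_id, key), default)

    def has_call(self, sample_id: str, key: VariantKey) -> bool:
        return (sample_id, key) in self._calls

    def calls(self) -> Iterator[GenotypeCall]:
        for (sample, key), zyg in self._calls.items():
            yield GenotypeCall(sample, key, zyg)

    def __len__(self) -> int:
        return len(self._calls)

    def update(self, other: "GenotypeMap") -> None:
        self._calls.update(other._calls)


@dataclass(frozen=True)
class Trio:
    """Proband/father/mother linkage with parent-availability flags.

    An unavailable parent (pedigree id "0") is stored as ``None`` and
    carries no genotype calls.
    """

    proband_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    father_available: bool = True
    mother_available: bool = True

    def __post_init__(self) -> None:
        ids = [
            i
            for i in (self.proband_id, self.father_id, self.mother_id)
            if i is not None
        ]
        if len(ids) != len(set(ids)):
            raise ModelError(f"trio ids must be distinct: {ids}")
        if self.father_available and self.father_id is None:
            raise ModelError(f"trio {self.proband_id}: available father without id")
        if self.mother_available and self.mother_id is None:
            raise ModelError(f"trio {self.proband_id}: available mother without id")


@dataclass(frozen=True)
class KnownVariantRecord:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ModelError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


class KnownVariantDB:
    """Registered-polymorphism database indexed by chromosome + position."""

    def __init__(self, records: Iterable[KnownVariantRecord] = ()) -> None:
        self._by_position: dict[tuple[str, int], set[tuple[str, str]]] = {}
        self._records: list[KnownVariantRecord] = []
        for rec in records:
            self.add(rec)

    def add(self, record: KnownVariantRecord) -> None:
        self._records.append(record)
        self._by_position.setdefault(
            (record.chromosome, record.position), set()
        ).add((record.ref_allele, record.alt_allele))

    def contains_position(self, chromosome: str, position: int) -> bool:
        return (chromosome, position) in self._by_position

    def contains_allele(
        self, chromosome: str, position: int, ref: str, alt: str
    ) -> bool:
        return (ref, alt) in self._by_position.get((chromosome, position), ())

    @property
    def records(self) -> list[KnownVariantRecord]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def copy(self) -> "KnownVariantDB":
        return KnownVariantDB(self._records)


@dataclass(frozen=True)
class GeneSet:
    """Named, case-normalized set of gene symbols (e.g. brain-expressed)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ModelError(f"gene set {self.name!r} is empty")
        normalized = frozenset(s.upper() for s in self.symbols)
        object.__setattr__(self, "symbols", normalized)

    def __contains__(self, symbol: Optional[str]) -> bool:
        if symbol is None:
            return False
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class StageCounts:
    """Per-sample SNV counts at each cascade boundary, indels separate."""

    n_total_variants: int = 0
    n_novel_variants: int = 0
    n_novel_nsss_variants: int = 0
    n_novel_nsss_genes: int = 0
    n_brain_variants: int = 0
    n_brain_genes: int = 0
    n_total_indels: int = 0
    n_novel_indels: int = 0
    n_novel_nsss_indels: int = 0
    n_brain_indels: int = 0

    def check(self) -> None:
        snv = (
            self.n_total_variants,
            self.n_novel_variants,
            self.n_novel_nsss_variants,
            self.n_brain_variants,
        )
        indel = (
            self.n_total_indels,
            self.n_novel_indels,
            self.n_novel_nsss_indels,
            self.n_brain_indels,
        )
        for seq, what in ((snv, "SNV"), (indel, "indel")):
            if any(a < b for a, b in zip(seq, seq[1:])):
                raise ModelError(f"{what} counts not monotone non-increasing: {seq}")
        if self.n_novel_nsss_genes > self.n_novel_nsss_variants:
            raise ModelError("gene count exceeds variant count at NS/SS stage")
        if self.n_brain_genes > self.n_brain_variants:
            raise ModelError("gene count exceeds variant count at brain stage")


@dataclass
class CascadeReport:
    """Per-sample and cohort-level counts at each filter boundary.

    Cohort ``unique_*`` totals count each distinct variant key (or gene)
    once across samples; the plain per-sample sums are also derivable from
    the rows, since the two disagree whenever variants are shared.
    """

    per_sample: dict[str, StageCounts] = field(default_factory=dict)
    unique_total_variants: int = 0
    unique_novel_variants: int = 0
    unique_novel_nsss_variants: int = 0
    unique_novel_nsss_genes: int = 0
    unique_brain_variants: int = 0
    unique_brain_genes: int = 0

    def check(self) -> None:
        for counts in self.per_sample.values():
            counts.check()
        for attr in (
            "total_variants",
            "novel_variants",
            "novel_nsss_variants",
            "brain_variants",
        ):
            summed = sum(
                getattr(c, f"n_{attr}") for c in self.per_sample.values()
            )
            if getattr(self, f"unique_{attr}") > summed:
                raise ModelError(f"cohort unique {attr} exceeds per-sample sum")

    def to_rows(self) -> list[dict]:
        rows = []
        for sample, c in sorted(self.per_sample.items()):
            row = {"sample": sample}
            row.update(vars(c))
            rows.append(row)
        return rows


@dataclass
class CandidateVariant:
    """A variant plus carriers, validation status, and impact scores."""

    variant: Variant
    carrier_ids: list[str]
    de_novo_status: dict[str, "object"] = field(default_factory=dict)
    sanger_confirmed: Optional[bool] = None  # None = pending
    control_carrier_count: int = 0
    grantham: Optional[float] = None
    conservation: Optional[float] = None
    unvalidated: bool = False

    def __post_init__(self) -> None:
        if not self.carrier_ids:
            raise ModelError(
                f"candidate {self.variant.key} has no carriers"
            )
        if self.control_carrier_count < 0:
            raise ModelError("control carrier count must be >= 0")


#: Declared phenotype feature schema. "unknown" is a legal value everywhere.
PHENOTYPE_SCHEMA: Mapping[str, tuple] = {
    "respiratory_abnormality": ("yes", "no", "unknown"),
    "status_epilepticus": ("yes", "no", "unknown"),
    "epilepsy": ("yes", "no", "unknown"),
    "regression": ("yes", "no", "unknown"),
    "headache": ("yes", "no", "unknown"),
    "effective_drug": None,  # free-text categorical (drug name or "none")
}


@dataclass(frozen=True)
class PhenotypeRecord:
    patient_id: str
    mutation: str
    features: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if name not in PHENOTYPE_SCHEMA:
                raise VocabularyError(f"unknown phenotype feature {name!r}")
            allowed = PHENOTYPE_SCHEMA[name]
            if allowed is not None and value not in allowed:
                raise VocabularyError(
                    f"feature {name!r} has value {value!r}, expected {allowed}"
                )


@dataclass
class VariantTable:
    """Variants plus genotype calls for a set of samples.

    Variants are unique by key and kept in input order; per-sample carried
    lists are derived from the genotype map.
    """

    variants: list[Variant]
    genotypes: GenotypeMap
    samples: list[str]

    def pairs(self) -> list[tuple[Variant, GenotypeCall]]:
        out = []
        for v in self.variants:
            for s in self.samples:
                if self.genotypes.has_call(s, v.key):
                    out.append(
                        (v, GenotypeCall(s, v.key, self.genotypes.get(s, v.key)))
                    )
        return out

    def carried_by(self, sample_id: str) -> list[Variant]:
        return [
            v
            for v in self.variants
            if self.genotypes.get(sample_id, v.key).is_carrier
        ]

    def per_sample(self, samples: Optional[Iterable[str]] = None) -> dict[str, list[Variant]]:
        chosen = list(samples) if samples is not None else self.samples
        return {s: self.carried_by(s) for s in chosen}
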