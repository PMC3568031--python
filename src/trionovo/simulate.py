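"""Trio-cohort simulator with per-variant truth labels.

The generator emulates the data structure of a small trio-exome study of a
sporadic dominant disorder: per-proband variant tables whose composition is
controlled by a chain of fractions (registered in the known-variant
database -> novel; protein-altering/splice -> NS/SS; in a brain-expressed
gene), one or more planted de novo candidate variants shared across
probands, inherited decoys, and confirmation-failing sequencing artifacts.
Every emitted variant carries exactly one truth class in the sidecar, so a
pipeline run can be checked against intent rather than re-derivation.

Defaults are desk-scale: 8 trios at ~5,000 variants per proband with the
fraction chain (0.20 novel x 0.40 NS/SS x 0.25 brain) centring the final
brain-expressed NS/SS count per proband on ~100, inside the 77-129 band a
comparable exome cohort shows after the same three filters. Alongside the
per-proband backgrounds the simulator always plants one shared inherited
decoy gene (distinct inherited variants in ``min(4, n_trios)`` probands,
two control carriers on one of them) and, when ``artifact_rate > 0``, one
shared artifact variant that fails confirmation in every carrier — the two
failure modes a validation stage must handle.

All randomness flows from ``params.seed``; the same seed reproduces
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    ConfirmationOracle,
    ControlGenotypes,
    write_controls,
    write_known_db,
    write_oracle,
    write_pedigree,
    write_variant_table,
)
from .model import (
    Consequence,
    GenotypeMap,
    KnownVariantDB,
    KnownVariantRecord,
    Trio,
    Variant,
    VariantKey,
    VariantTable,
    Zygosity,
)

__all__ = [
    "SimParams",
    "TruthClass",
    "TruthRecord",
    "SimTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "plant_position_collision",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions; defaults are the package's study conditions."""

    n_trios: int = 8
    variants_per_proband: float = 5000.0
    fraction_known: float = 0.80
    fraction_nsss_of_novel: float = 0.40
    fraction_brain_of_nsss: float = 0.25
    n_planted: int = 1
    planted_carrier_count: int = 5
    artifact_rate: float = 0.02
    control_cohort_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if self.planted_carrier_count > self.n_trios:
            raise ValueError(
                f"planted_carrier_count ({self.planted_carrier_count}) exceeds "
                f"n_trios ({self.n_trios})"
            )
        if self.n_planted > 0 and self.planted_carrier_count < 1:
            raise ValueError("planted variants need at least one carrier")
        for name in ("fraction_known", "fraction_nsss_of_novel", "fraction_brain_of_nsss", "artifact_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.control_cohort_size < 1:
            raise ValueError("control cohort must be non-empty")


class TruthClass:
    known_background = "known_background"
    novel_benign_inherited = "novel_benign_inherited"
    planted_de_novo = "planted_de_novo"
    sequencing_artifact = "sequencing_artifact"

    ALL = (known_background, novel_benign_inherited, planted_de_novo, sequencing_artifact)


@dataclass
class TruthRecord:
    variant: Variant
    truth_class: str
    carriers: list[str]
    intended_classification: str  # de_novo / inherited / artifact_call
    is_known: bool
    is_nsss: bool
    is_brain: bool

    def __post_init__(self) -> None:
        if self.truth_class not in TruthClass.ALL:
            raise ValueError(f"unknown truth class {self.truth_class!r}")


@dataclass
class SimTruth:
    """Sidecar labelling every emitted variant's true class and carriers."""

    records: dict[VariantKey, TruthRecord] = field(default_factory=dict)

    def add(self, record: TruthRecord) -> None:
        key = record.variant.key
        if key in self.records:
            raise ValueError(f"duplicate truth record for {key}")
        self.records[key] = record

    def by_class(self, truth_class: str) -> list[TruthRecord]:
        return [r for r in self.records.values() if r.truth_class == truth_class]

    def planted_keys(self) -> set[VariantKey]:
        return {r.variant.key for r in self.by_class(TruthClass.planted_de_novo)}

    def stage_counts(self, sample: str) -> tuple[int, int, int, int]:
        """(total, novel, novel NS/SS, brain NS/SS) implied by the labels."""
        total = novel = nsss = brain = 0
        for rec in self.records.values():
            if sample not in rec.carriers:
                continue
            total += 1
            if rec.is_known:
                continue
            novel += 1
            if not rec.is_nsss:
                continue
            nsss += 1
            if rec.is_brain:
                brain += 1
        return total, novel, nsss, brain


@dataclass
class SimulatedCohort:
    params: SimParams
    probands: list[str]
    trios: list[Trio]
    cohort: dict[str, list[Variant]]  # proband -> carried variants
    genotypes: GenotypeMap
    known_db: KnownVariantDB
    controls: ControlGenotypes
    oracle: ConfirmationOracle
    truth: SimTruth

    def variant_table(self) -> VariantTable:
        samples = []
        for trio in self.trios:
            samples.append(trio.proband_id)
            if trio.father_available:
                samples.append(trio.father_id)
            if trio.mother_available:
                samples.append(trio.mother_id)
        variants: list[Variant] = []
        seen: set[VariantKey] = set()
        for rec in self.truth.records.values():
            if rec.variant.key not in seen:
                seen.add(rec.variant.key)
                variants.append(rec.variant)
        return VariantTable(variants=variants, genotypes=self.genotypes, samples=samples)

    def write_outputs(self, out_dir) -> dict[str, Path]:
        """Write VCF, PED, known-db, controls, oracle and truth tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "ped": out / "cohort.ped",
            "known_db": out / "known_db.tsv",
            "controls": out / "controls.tsv",
            "oracle": out / "oracle.tsv",
            "truth": out / "truth.tsv",
        }
        write_variant_table(paths["vcf"], self.variant_table(), dialect="vcf")
        write_pedigree(paths["ped"], self.trios)
        write_known_db(paths["known_db"], self.known_db)
        write_controls(paths["controls"], self.controls)
        write_oracle(paths["oracle"], self.oracle)
        lines = ["chrom\tpos\tref\talt\tclass\tcarriers\tintended_classification"]
        for key, rec in self.truth.records.items():
            lines.append(
                "\t".join(
                    [
                        key[0],
                        str(key[1]),
                        key[2],
                        key[3],
                        rec.truth_class,
                        ",".join(rec.carriers),
                        rec.intended_classification,
                    ]
                )
            )
        paths["truth"].write_text("\n".join(lines) + "\n")
        return paths


class _Space:
    """Unique genomic coordinates and synthetic gene pools."""

    def __init__(self, rng: np.random.Generator, n_brain: int = 150, n_other: int = 450):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.brain_genes = [f"BRG{i:04d}" for i in range(1, n_brain + 1)]
        self.other_genes = [f"GEN{i:04d}" for i in range(1, n_other + 1)]

    def position(self) -> tuple[str, int]:
        while True:
            chrom = str(int(self.rng.integers(1, 23)))
            pos = int(self.rng.integers(1, 200_000_000))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos

    def alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(4, size=2, replace=False)
        return str(_NUCS[ref]), str(_NUCS[alt])

    def gene(self, brain: bool) -> str:
        pool = self.brain_genes if brain else self.other_genes
        return pool[int(self.rng.integers(0, len(pool)))]

    def protein_change(self, synonymous: bool = False) -> str:
        aas = "ARNDCQEGHILKMFPSTWYV"
        i = int(self.rng.integers(0, 20))
        j = i if synonymous else int((i + 1 + self.rng.integers(0, 19)) % 20)
        pos = int(self.rng.integers(1, 1200))
        return f"{aas[i]}{pos}{aas[j]}"


def _make_variant(space: _Space, *, nsss: bool, brain: bool) -> Variant:
    chrom, pos = space.position()
    ref, alt = space.alleles()
    if nsss:
        consequence = Consequence.missense
        protein = space.protein_change()
    else:
        # split novel non-NS/SS background between synonymous and other
        if space.rng.random() < 0.7:
            consequence = Consequence.synonymous
            protein = space.protein_change(synonymous=True)
        else:
            consequence = Consequence.other
            protein = None
    gene = space.gene(brain)
    aa_pos = protein[1:-1] if protein else ""
    cdna = f"c.{pos % 9000 + 1}{ref}>{alt}"
    return Variant(
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        gene=gene,
        cdna_change=cdna,
        protein_change=protein,
        consequence=consequence,
    )


def simulate_cohort(params: SimParams) -> SimulatedCohort:
    """Generate a labelled trio cohort; reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    space = _Space(rng)

    probands = [f"P{i:02d}" for i in range(1, params.n_trios + 1)]
    trios = [
        Trio(
            proband_id=p,
            father_id=f"{p}_fa",
            mother_id=f"{p}_mo",
        )
        for p in probands
    ]
    genotypes = GenotypeMap()
    known_db = KnownVariantDB()
    controls = ControlGenotypes([f"C{i:03d}" for i in range(1, params.control_cohort_size + 1)])
    oracle = ConfirmationOracle()
    truth = SimTruth()
    cohort: dict[str, list[Variant]] = {p: [] for p in probands}

    def emit(
        variant: Variant,
        carriers: Sequence[str],
        truth_class: str,
        intended: str,
        *,
        is_known: bool,
        is_nsss: bool,
        is_brain: bool,
        confirmed: bool,
        inherited: bool,
    ) -> None:
        for p in carriers:
            cohort[p].append(variant)
            genotypes.set(p, variant.key, Zygosity.het)
            oracle.record(variant.key, p, confirmed)
            trio = trios[probands.index(p)]
            if inherited:
                parent = trio.father_id if rng.random() < 0.5 else trio.mother_id
                genotypes.set(parent, variant.key, Zygosity.het)
            else:
                genotypes.set(trio.father_id, variant.key, Zygosity.hom_ref)
                genotypes.set(trio.mother_id, variant.key, Zygosity.hom_ref)
        truth.add(
            TruthRecord(
                variant=variant,
                truth_class=truth_class,
                carriers=list(carriers),
                intended_classification=intended,
                is_known=is_known,
                is_nsss=is_nsss,
                is_brain=is_brain,
            )
        )

    # --- per-proband background variants (one carrier each) ---------------
    for p in probands:
        n = int(rng.poisson(params.variants_per_proband))
        known_flags = rng.random(n) < params.fraction_known
        nsss_flags = rng.random(n) < params.fraction_nsss_of_novel
        brain_flags = rng.random(n) < params.fraction_brain_of_nsss
        artifact_flags = rng.random(n) < params.artifact_rate
        for i in range(n):
            if known_flags[i]:
                v = _make_variant(space, nsss=bool(nsss_flags[i]), brain=bool(brain_flags[i]))
                known_db.add(
                    KnownVariantRecord(
                        v.chromosome, v.position, v.ref_allele, v.alt_allele,
                        source_id=f"db{len(known_db) + 1}",
                    )
                )
                # a registered polymorphism may segregate in the controls
                n_ctrl = int(rng.binomial(params.control_cohort_size, 0.02))
                if n_ctrl:
                    picks = rng.choice(params.control_cohort_size, size=n_ctrl, replace=False)
                    for idx in picks:
                        controls.set_carrier(v.key, controls.sample_ids[int(idx)])
                emit(
                    v, [p], TruthClass.known_background, "inherited",
                    is_known=True, is_nsss=bool(nsss_flags[i]),
                    is_brain=bool(brain_flags[i]), confirmed=True, inherited=True,
                )
            else:
                nsss = bool(nsss_flags[i])
                brain = bool(brain_flags[i]) if nsss else False
                artifact = nsss and brain and bool(artifact_flags[i])
                v = _make_variant(space, nsss=nsss, brain=brain)
                if artifact:
                    emit(
                        v, [p], TruthClass.sequencing_artifact, "artifact_call",
                        is_known=False, is_nsss=True, is_brain=True,
                        confirmed=False, inherited=False,
                    )
                else:
                    emit(
                        v, [p], TruthClass.novel_benign_inherited, "inherited",
                        is_known=False, is_nsss=nsss, is_brain=brain,
                        confirmed=True, inherited=True,
                    )

    # --- shared inherited decoy gene (distinct variants, all inherited) ---
    decoy_gene = "BRGDECOY"
    space.brain_genes.append(decoy_gene)
    n_decoy = min(4, params.n_trios)
    decoy_carriers = [probands[int(i)] for i in rng.choice(params.n_trios, size=n_decoy, replace=False)]
    for j, p in enumerate(decoy_carriers):
        chrom, pos = space.position()
        ref, alt = space.alleles()
        v = Variant(
            chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt,
            gene=decoy_gene, cdna_change=f"c.{100 + j}{ref}>{alt}",
            protein_change=space.protein_change(), consequence=Consequence.missense,
        )
        if j == 0:
            # one decoy variant also shows up in two controls
            picks = rng.choice(params.control_cohort_size, size=2, replace=False)
            for idx in picks:
                controls.set_carrier(v.key, controls.sample_ids[int(idx)])
        emit(
            v, [p], TruthClass.novel_benign_inherited, "inherited",
            is_known=False, is_nsss=True, is_brain=True,
            confirmed=True, inherited=True,
        )

    # --- shared confirmation-failing artifact ------------------------------
    if params.artifact_rate > 0:
        chrom, pos = space.position()
        ref, alt = space.alleles()
        n_carriers = min(max(params.planted_carrier_count, 1), params.n_trios)
        carriers = [probands[int(i)] for i in rng.choice(params.n_trios, size=n_carriers, replace=False)]
        v = Variant(
            chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt,
            gene=space.gene(brain=True), cdna_change=f"c.999{ref}>{alt}",
            protein_change=space.protein_change(), consequence=Consequence.missense,
        )
        emit(
            v, carriers, TruthClass.sequencing_artifact, "artifact_call",
            is_known=False, is_nsss=True, is_brain=True,
            confirmed=False, inherited=False,
        )

    # --- planted shared de novo variants -----------------------------------
    for k in range(params.n_planted):
        chrom, pos = space.position()
        ref, alt = space.alleles()
        gene = f"BRGPLANT{k + 1}"
        space.brain_genes.append(gene)
        carriers = [
            probands[int(i)]
            for i in rng.choice(params.n_trios, size=params.planted_carrier_count, replace=False)
        ]
        v = Variant(
            chromosome=chrom, position=pos, ref_allele=ref, alt_allele=alt,
            gene=gene, cdna_change=f"c.{2000 + k}{ref}>{alt}",
            protein_change=space.protein_change(), consequence=Consequence.missense,
        )
        emit(
            v, carriers, TruthClass.planted_de_novo, "de_novo",
            is_known=False, is_nsss=True, is_brain=True,
            confirmed=True, inherited=False,
        )

    return SimulatedCohort(
        params=params,
        probands=probands,
        trios=trios,
        cohort=cohort,
        genotypes=genotypes,
        known_db=known_db,
        controls=controls,
        oracle=oracle,
        truth=truth,
    )


def brain_gene_set(sim: SimulatedCohort):
    """The simulator's brain-expressed gene set (flagged pool + planted genes)."""
    from .model import GeneSet

    symbols = {rec.variant.gene for rec in sim.truth.records.values() if rec.is_brain}
    symbols |= {f"BRG{i:04d}" for i in range(1, 151)}
    return GeneSet(name="sim_brain", symbols=frozenset(symbols))


def plant_position_collision(
    sim: SimulatedCohort, planted_variant: Optional[Variant] = None
) -> KnownVariantDB:
    """Register a different allele at a planted variant's coordinate.

    Returns a copy of the known DB with one extra record sharing the
    planted variant's chromosome and position but a different alt allele —
    the configuration under which position-only matching wrongly treats the
    planted variant as known while allele-aware matching does not. Sample
    tables are untouched: the collision record exists only in the database.
    """
    if planted_variant is None:
        planted = sim.truth.by_class(TruthClass.planted_de_novo)
        if not planted:
            raise ValueError("simulation contains no planted variant")
        planted_variant = planted[0].variant
    key = planted_variant.key
    if key not in sim.truth.records:
        raise ValueError(f"variant {key} was not emitted by this simulation")
    other_alts = [n for n in "ACGT" if n not in (planted_variant.ref_allele, planted_variant.alt_allele)]
    db = sim.known_db.copy()
    db.add(
        KnownVariantRecord(
            chromosome=planted_variant.chromosome,
            position=planted_variant.position,
            ref_allele=planted_variant.ref_allele,
            alt_allele=other_alts[0],
            source_id="collision",
        )
    )
    return db
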