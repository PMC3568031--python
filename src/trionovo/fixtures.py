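"""The ten-patient AHC study cohort, transcribed from the published tables.

Ten sporadic alternating-hemiplegia-of-childhood (AHC) patients I-1..X-1;
the first eight were exome-sequenced as trios, IX-1 and X-1 were added
later by targeted Sanger genotyping at the candidate loci (IX-1's parents
declined testing). Four heterozygous ATP1A3 missense mutations segregate:

    G755C  chr19:42479781 G>T  carrier I-1
    E815K  chr19:42474436 G>A  carriers II-1, III-1, IV-1 (+ IX-1, X-1)
    D801N  chr19:42474557 G>A  carriers VI-1, VII-1, VIII-1
    C927Y  chr19:42472976 G>A  carrier V-1

The known-variant database registers the *different* substitution D801Y
(chr19:42474557 G>T, the rapid-onset dystonia-parkinsonism allele) at the
D801N coordinate, so position-only novelty matching wrongly discards D801N
— the configuration the gene-refocus re-analysis must rescue.

Decoys: a CNTN4 variant (V938G) shared by six probands that fails Sanger
confirmation, and four distinct novel SYNE1 missense variants in four
probands, each inherited from a healthy parent, three of them carried by
2/2/2 of the 96 controls. Fifteen further registered SYNE1 missense
variants are planted so that a SYNE1 gene refocus over the pre-filter data
yields 19 distinct non-synonymous keys with per-sample counts
10/10/8/10/9/8/10/9 — both totals the study reports.

ATP1A3 coordinates are the published chr19 positions; CNTN4 and SYNE1
genomic coordinates are not published, so those positions are synthetic
placeholders on the genes' true chromosomes. Phenotype records transcribe
the clinical table (respiratory abnormality, status epilepticus, epilepsy,
regression, headache, effective drug).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io import (
    ConfirmationOracle,
    ControlGenotypes,
    write_controls,
    write_gene_set,
    write_known_db,
    write_oracle,
    write_pedigree,
    write_phenotypes,
    write_variant_table,
)
from .model import (
    Consequence,
    GeneSet,
    GenotypeMap,
    KnownVariantDB,
    KnownVariantRecord,
    PhenotypeRecord,
    Trio,
    Variant,
    VariantTable,
    Zygosity,
)

__all__ = ["PaperCohort", "fixture_paper_cohort"]

EXOME_PROBANDS = ["I-1", "II-1", "III-1", "IV-1", "V-1", "VI-1", "VII-1", "VIII-1"]
EXTENSION_PATIENTS = ["IX-1", "X-1"]
ALL_PATIENTS = EXOME_PROBANDS + EXTENSION_PATIENTS

ATP1A3_VARIANTS = {
    "G755C": Variant("19", 42479781, "G", "T", "ATP1A3", "c.2263G>T", "G755C", Consequence.missense),
    "E815K": Variant("19", 42474436, "G", "A", "ATP1A3", "c.2443G>A", "E815K", Consequence.missense),
    "D801N": Variant("19", 42474557, "G", "A", "ATP1A3", "c.2401G>A", "D801N", Consequence.missense),
    "C927Y": Variant("19", 42472976, "G", "A", "ATP1A3", "c.2780G>A", "C927Y", Consequence.missense),
}

ATP1A3_CARRIERS = {
    "G755C": ["I-1"],
    "E815K": ["II-1", "III-1", "IV-1", "IX-1", "X-1"],
    "D801N": ["VI-1", "VII-1", "VIII-1"],
    "C927Y": ["V-1"],
}

# CNTN4 position is a synthetic placeholder within the gene's chr3 locus.
CNTN4_V938G = Variant("3", 2617000, "T", "G", "CNTN4", "c.2813T>G", "V938G", Consequence.missense)
CNTN4_CARRIERS = ["II-1", "III-1", "IV-1", "VI-1", "VII-1", "VIII-1"]

# SYNE1 positions are synthetic placeholders within the gene's chr6 locus.
SYNE1_NOVEL = {
    "E1319K": (Variant("6", 152770000, "G", "A", "SYNE1", "c.3955G>A", "E1319K", Consequence.missense), "VII-1"),
    "V2399A": (Variant("6", 152720000, "T", "G", "SYNE1", "c.7196T>G", "V2399A", Consequence.missense), "III-1"),
    "M3376V": (Variant("6", 152680000, "A", "G", "SYNE1", "c.10126A>G", "M3376V", Consequence.missense), "V-1"),
    "R8222Q": (Variant("6", 152480000, "G", "A", "SYNE1", "c.24665G>A", "R8222Q", Consequence.missense), "I-1"),
}
SYNE1_CONTROL_CARRIERS = {"E1319K": 2, "V2399A": 2, "M3376V": 2, "R8222Q": 0}

# Registered SYNE1 missense background reproducing the refocus totals:
# 19 distinct NS keys, per-sample counts 10/10/8/10/9/8/10/9 over I-1..VIII-1.
_ALL8 = EXOME_PROBANDS
_SYNE1_KNOWN_CARRIERS = [
    _ALL8, _ALL8, _ALL8, _ALL8, _ALL8,                       # u1-u5: all eight
    ["I-1", "II-1", "III-1", "IV-1"],                        # u6a
    ["V-1", "VI-1", "VII-1", "VIII-1"],                      # u6b
    ["II-1", "IV-1", "VII-1"],                               # k7
    ["II-1", "IV-1", "VIII-1"],                              # k8
    ["I-1", "II-1", "IV-1"],                                 # k9
    ["II-1", "IV-1", "VI-1"],                                # k10
    ["I-1", "V-1", "VIII-1"],                                # k11
    ["I-1", "VII-1", "VIII-1"],                              # k12
    ["III-1", "V-1"],                                        # k13
    ["VI-1", "VII-1"],                                       # k14
]

BRAIN_GENES = ["ATP1A3", "SYNE1", "CNTN4", "ATP1A2", "CACNA1A", "SCN1A", "GRIN2A", "KCNQ2"]

_PHENOTYPES = {
    # patient: (mutation, respiratory, status_epilepticus, epilepsy, regression, headache, drug)
    "I-1": ("G755C", "yes", "no", "yes", "no", "yes", "flunarizine"),
    "II-1": ("E815K", "no", "yes", "yes", "yes", "yes", "clonazepam"),
    "III-1": ("E815K", "yes", "yes", "yes", "yes", "no", "clonazepam+flunarizine"),
    "IV-1": ("E815K", "yes", "no", "no", "no", "no", "flunarizine"),
    "V-1": ("C927Y", "no", "no", "no", "yes", "no", "clonazepam"),
    "VI-1": ("D801N", "no", "no", "no", "no", "no", "flunarizine"),
    "VII-1": ("D801N", "no", "no", "yes", "no", "no", "flunarizine"),
    "VIII-1": ("D801N", "yes", "yes", "yes", "yes", "no", "flunarizine"),
    "IX-1": ("E815K", "yes", "yes", "yes", "yes", "unknown", "none"),
    "X-1": ("E815K", "yes", "yes", "yes", "no", "unknown", "midazolam"),
}


@dataclass
class PaperCohort:
    trios: list[Trio]
    variants: list[Variant]
    genotypes: GenotypeMap
    known_db: KnownVariantDB
    gene_set: GeneSet
    controls: ControlGenotypes
    oracle: ConfirmationOracle
    phenotypes: list[PhenotypeRecord]
    exome_probands: list[str]
    extension_patients: list[str]
    atp1a3: dict[str, Variant]
    syne1_novel: dict[str, Variant]
    cntn4: Variant

    def exome_cohort(self) -> dict[str, list[Variant]]:
        """Per-proband carried variants for the eight exome trios."""
        gm = self.genotypes
        return {
            p: [v for v in self.variants if gm.get(p, v.key).is_carrier]
            for p in self.exome_probands
        }

    def extension_genotypes(self) -> GenotypeMap:
        return self.genotypes

    def variant_table(self, samples=None) -> VariantTable:
        if samples is None:
            samples = list(self.exome_probands)
            for t in self.trios:
                if t.proband_id in self.exome_probands:
                    if t.father_available:
                        samples.append(t.father_id)
                    if t.mother_available:
                        samples.append(t.mother_id)
        return VariantTable(variants=list(self.variants), genotypes=self.genotypes, samples=samples)

    def write_outputs(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "ped": out / "cohort.ped",
            "known_db": out / "known_db.tsv",
            "gene_set": out / "brain_genes.txt",
            "controls": out / "controls.tsv",
            "oracle": out / "oracle.tsv",
            "phenotypes": out / "phenotypes.tsv",
        }
        write_variant_table(paths["vcf"], self.variant_table(), dialect="vcf")
        write_pedigree(paths["ped"], self.trios)
        write_known_db(paths["known_db"], self.known_db)
        write_gene_set(paths["gene_set"], self.gene_set)
        write_controls(paths["controls"], self.controls)
        write_oracle(paths["oracle"], self.oracle)
        write_phenotypes(paths["phenotypes"], self.phenotypes)
        return paths


def _check_consistency(cohort: PaperCohort) -> None:
    expected = {"E815K": 5, "D801N": 3, "G755C": 1, "C927Y": 1}
    for pchange, n in expected.items():
        v = cohort.atp1a3[pchange]
        carriers = [
            p for p in ALL_PATIENTS if cohort.genotypes.get(p, v.key).is_carrier
        ]
        if len(carriers) != n:
            raise AssertionError(
                f"fixture inconsistency: {pchange} has {len(carriers)} carriers, expected {n}"
            )
    distinct = {v.protein_change for v in cohort.atp1a3.values()}
    if len(distinct) != 4:
        raise AssertionError("fixture must contain exactly 4 distinct ATP1A3 protein changes")


def fixture_paper_cohort() -> PaperCohort:
    """Build the in-paper ten-patient cohort with all sidecar tables."""
    genotypes = GenotypeMap()
    variants: list[Variant] = []
    oracle = ConfirmationOracle()

    trios = []
    for p in ALL_PATIENTS:
        if p == "IX-1":
            trios.append(Trio(p, None, None, father_available=False, mother_available=False))
        else:
            trios.append(Trio(p, f"{p}-f", f"{p}-m"))

    def add_variant(v: Variant, carriers, *, inherited_from=None, confirmed=True):
        variants.append(v)
        for p in carriers:
            genotypes.set(p, v.key, Zygosity.het)
            oracle.record(v.key, p, confirmed)
            if inherited_from == "father":
                genotypes.set(f"{p}-f", v.key, Zygosity.het)
            elif inherited_from == "mother":
                genotypes.set(f"{p}-m", v.key, Zygosity.het)

    # ATP1A3 mutations: heterozygous in carriers, absent from all tested parents
    for pchange, v in ATP1A3_VARIANTS.items():
        add_variant(v, ATP1A3_CARRIERS[pchange], confirmed=True)
        # extension patients were genotyped at every candidate locus
        for p in EXTENSION_PATIENTS:
            if p not in ATP1A3_CARRIERS[pchange]:
                genotypes.set(p, v.key, Zygosity.hom_ref)

    # CNTN4 shared call, not confirmed by Sanger (exome sequencing error)
    add_variant(CNTN4_V938G, CNTN4_CARRIERS, confirmed=False)

    # Novel SYNE1 variants: one carrier each, inherited from a healthy parent
    for i, (pchange, (v, carrier)) in enumerate(SYNE1_NOVEL.items()):
        add_variant(v, [carrier], inherited_from="father" if i % 2 == 0 else "mother")

    # Registered SYNE1 missense background (synthetic positions/changes)
    known_db = KnownVariantDB()
    known_db.add(KnownVariantRecord("19", 42474557, "G", "T", source_id="db_D801Y_RDP"))
    aas = "ARNDCQEGHILKMFPSTWYV"
    for i, carriers in enumerate(_SYNE1_KNOWN_CARRIERS):
        v = Variant(
            "6", 152500000 + 1000 * i, "C", "T", "SYNE1",
            f"c.{300 + 3 * i}C>T", f"{aas[i]}{100 + i}{aas[(i + 3) % 20]}",
            Consequence.missense,
        )
        known_db.add(KnownVariantRecord(v.chromosome, v.position, v.ref_allele, v.alt_allele, source_id=f"db_SYNE1_{i + 1}"))
        add_variant(v, carriers, inherited_from="mother")

    # A little non-candidate background so every cascade stage is exercised:
    # one registered synonymous, one novel synonymous (brain gene), and one
    # novel missense in a non-brain gene, per exome proband.
    for j, p in enumerate(EXOME_PROBANDS):
        known_syn = Variant("1", 1_000_000 + j, "G", "A", "OR4F5", f"c.{60 + j}G>A", f"L{20 + j}L", Consequence.synonymous)
        known_db.add(KnownVariantRecord("1", 1_000_000 + j, "G", "A", source_id=f"db_bg_{j}"))
        add_variant(known_syn, [p], inherited_from="father")
        novel_syn = Variant("2", 2_000_000 + j, "C", "T", "ATP1A2", f"c.{90 + j}C>T", f"V{40 + j}V", Consequence.synonymous)
        add_variant(novel_syn, [p], inherited_from="mother")
        novel_nonbrain = Variant("2", 3_000_000 + j, "A", "G", "TTN", f"c.{120 + j}A>G", f"I{70 + j}V", Consequence.missense)
        add_variant(novel_nonbrain, [p], inherited_from="father")

    controls = ControlGenotypes([f"CTRL{i:02d}" for i in range(1, 97)])
    next_ctrl = 0
    for pchange, (v, _carrier) in SYNE1_NOVEL.items():
        for _ in range(SYNE1_CONTROL_CARRIERS[pchange]):
            next_ctrl += 1
            controls.set_carrier(v.key, f"CTRL{next_ctrl:02d}")

    phenotypes = []
    for patient, row in _PHENOTYPES.items():
        mutation, resp, stat, epi, regr, head, drug = row
        phenotypes.append(
            PhenotypeRecord(
                patient_id=patient,
                mutation=mutation,
                features={
                    "respiratory_abnormality": resp,
                    "status_epilepticus": stat,
                    "epilepsy": epi,
                    "regression": regr,
                    "headache": head,
                    "effective_drug": drug,
                },
            )
        )

    cohort = PaperCohort(
        trios=trios,
        variants=variants,
        genotypes=genotypes,
        known_db=known_db,
        gene_set=GeneSet(name="brain_expressed", symbols=frozenset(BRAIN_GENES)),
        controls=controls,
        oracle=oracle,
        phenotypes=phenotypes,
        exome_probands=list(EXOME_PROBANDS),
        extension_patients=list(EXTENSION_PATIENTS),
        atp1a3=dict(ATP1A3_VARIANTS),
        syne1_novel={k: v for k, (v, _c) in SYNE1_NOVEL.items()},
        cntn4=CNTN4_V938G,
    )
    _check_consistency(cohort)
    return cohort
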