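"""Readers and writers for every file the pipeline touches.

Formats: VCF 4.x (via pysam) and a package-defined ``annotated_tsv`` dialect
for variants+genotypes; 6-column PED for pedigrees; newline-delimited symbol
lists for gene sets; TSV tables for the known-variant database, control
genotypes, the confirmation oracle, and phenotype records.

The annotated_tsv dialect has columns
``chrom pos ref alt gene cdna protein consequence`` followed by one zygosity
column per sample. Annotation in VCF input is carried in the ``ANN`` INFO
field, one ``gene|cdna|protein|consequence`` entry per annotation; when a
variant has several, the most severe consequence by the closed-vocabulary
order is kept. Multi-allelic VCF rows are split into one variant per alt
allele before anything else sees them. Duplicate rows describing the same
variant (e.g. a concatenation of per-patient exports) merge: a
non-reference call is never overwritten by a later homozygous-reference
one.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    CONSEQUENCE_SEVERITY,
    Consequence,
    GeneSet,
    GenotypeCall,
    GenotypeMap,
    KnownVariantDB,
    KnownVariantRecord,
    ModelError,
    PhenotypeRecord,
    Trio,
    Variant,
    VariantTable,
    Zygosity,
)

__all__ = [
    "ParseError",
    "read_variant_table",
    "write_variant_table",
    "read_pedigree",
    "write_pedigree",
    "read_gene_set",
    "write_gene_set",
    "read_known_db",
    "write_known_db",
    "ControlGenotypes",
    "read_controls",
    "write_controls",
    "ConfirmationOracle",
    "read_oracle",
    "write_oracle",
    "read_phenotypes",
    "write_phenotypes",
]

ANNOTATED_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "cdna", "protein", "consequence"]


class ParseError(ValueError):
    """Malformed input row, reported with its file and line number."""

    def __init__(self, path, line_number: Optional[int], message: str) -> None:
        where = f"{path}" + (f", line {line_number}" if line_number else "")
        super().__init__(f"{where}: {message}")
        self.path = path
        self.line_number = line_number


def _severest(annotations: Sequence[tuple]) -> tuple:
    """Keep one (gene, cdna, protein, consequence) annotation per variant."""
    return min(annotations, key=lambda a: CONSEQUENCE_SEVERITY[a[3]])


def _merge_call(genotypes: GenotypeMap, sample: str, key, zygosity: Zygosity) -> None:
    if genotypes.has_call(sample, key) and zygosity is Zygosity.hom_ref:
        return
    genotypes.set(sample, key, zygosity)


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path, dialect: str = "auto") -> VariantTable:
    """Read a cohort variant+genotype table.

    ``dialect`` is ``"vcf"``, ``"annotated_tsv"`` or ``"auto"`` (by file
    suffix). Sample ids come from the file header.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "annotated_tsv"
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "annotated_tsv":
        return _read_annotated_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _zygosity_from_gt(allele_indices, alt_index: int) -> Zygosity:
    if allele_indices is None or any(a is None for a in allele_indices):
        return Zygosity.missing
    n_alt = sum(1 for a in allele_indices if a == alt_index)
    if n_alt == 0:
        return Zygosity.hom_ref
    if n_alt == len(allele_indices):
        return Zygosity.hom_alt
    return Zygosity.het


def _read_vcf(path: Path) -> VariantTable:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    seen: set = set()
    genotypes = GenotypeMap()
    for rec in vf:
        alts = rec.alts or ()
        ann_raw = rec.info.get("ANN") if "ANN" in rec.info else None
        if isinstance(ann_raw, str):
            ann_raw = (ann_raw,)
        for alt_index, alt in enumerate(alts, start=1):
            annotations = []
            for entry in ann_raw or ():
                parts = entry.split("|")
                if len(parts) != 4:
                    raise ParseError(path, None, f"malformed ANN entry {entry!r}")
                gene, cdna, protein, cons_term = parts
                annotations.append(
                    (
                        gene or None,
                        cdna or None,
                        protein or None,
                        Consequence.from_term(cons_term),
                    )
                )
            if annotations:
                gene, cdna, protein, consequence = _severest(annotations)
            else:
                gene = cdna = protein = None
                consequence = Consequence.other
            try:
                variant = Variant(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    gene=gene,
                    cdna_change=cdna,
                    protein_change=protein,
                    consequence=consequence,
                )
            except ModelError as exc:
                raise ParseError(path, None, str(exc)) from exc
            if variant.key not in seen:
                seen.add(variant.key)
                variants.append(variant)
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                _merge_call(genotypes, sample, variant.key, _zygosity_from_gt(gt, alt_index))
    vf.close()
    return VariantTable(variants=variants, genotypes=genotypes, samples=samples)


def _read_annotated_tsv(path: Path) -> VariantTable:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(path, 1, "empty header")
        header = header_line.rstrip("\n").split("\t")
        if header[: len(ANNOTATED_TSV_COLUMNS)] != ANNOTATED_TSV_COLUMNS:
            raise ParseError(
                path, 1, f"header must start with {ANNOTATED_TSV_COLUMNS}, got {header}"
            )
        samples = header[len(ANNOTATED_TSV_COLUMNS):]
        variants: list[Variant] = []
        seen: set = set()
        genotypes = GenotypeMap()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    path, lineno,
                    f"expected {len(header)} columns, got {len(fields)}",
                )
            chrom, pos, ref, alt, gene, cdna, protein, cons_term = fields[:8]
            try:
                variant = Variant(
                    chromosome=chrom,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    gene=gene or None,
                    cdna_change=cdna or None,
                    protein_change=protein or None,
                    consequence=Consequence.from_term(cons_term),
                )
            except (ModelError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if variant.key not in seen:
                seen.add(variant.key)
                variants.append(variant)
            for sample, zyg_term in zip(samples, fields[8:]):
                try:
                    zyg = Zygosity.from_term(zyg_term)
                except ModelError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
                _merge_call(genotypes, sample, variant.key, zyg)
    return VariantTable(variants=variants, genotypes=genotypes, samples=samples)


_ZYG_TO_GT = {
    Zygosity.hom_ref: "0/0",
    Zygosity.het: "0/1",
    Zygosity.hom_alt: "1/1",
    Zygosity.missing: "./.",
}


def write_variant_table(path, table: VariantTable, dialect: str = "auto") -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix == ".vcf" else "annotated_tsv"
    if dialect == "vcf":
        _write_vcf(path, table)
    elif dialect == "annotated_tsv":
        _write_annotated_tsv(path, table)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_vcf(path: Path, table: VariantTable) -> None:
    contigs = []
    for v in table.variants:
        if v.chromosome not in contigs:
            contigs.append(v.chromosome)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        '##INFO=<ID=ANN,Number=.,Type=String,'
        'Description="Annotation: gene|cdna|protein|consequence">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += table.samples
    lines.append("\t".join(header))
    for v in table.variants:
        ann = "|".join(
            [v.gene or "", v.cdna_change or "", v.protein_change or "", v.consequence.value]
        )
        row = [
            v.chromosome,
            str(v.position),
            ".",
            v.ref_allele,
            v.alt_allele,
            ".",
            "PASS",
            f"ANN={ann}",
            "GT",
        ]
        for sample in table.samples:
            row.append(_ZYG_TO_GT[table.genotypes.get(sample, v.key)])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_annotated_tsv(path: Path, table: VariantTable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATED_TSV_COLUMNS + table.samples)
        for v in table.variants:
            row = [
                v.chromosome,
                v.position,
                v.ref_allele,
                v.alt_allele,
                v.gene or "",
                v.cdna_change or "",
                v.protein_change or "",
                v.consequence.value,
            ]
            row += [table.genotypes.get(s, v.key).value for s in table.samples]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# pedigrees


def read_pedigree(path) -> list[Trio]:
    """Read a 6-column PED file into one Trio per proband.

    Proband rows are those with phenotype "2" (affected); if no row is
    marked affected, rows naming at least one parent are taken as probands.
    A parent id of "0" clears the corresponding availability flag.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected 6 PED columns, got {len(fields)}")
            rows.append((lineno, fields[:6]))
    affected = [(n, f) for n, f in rows if f[5] == "2"]
    chosen = affected if affected else [(n, f) for n, f in rows if f[2] != "0" or f[3] != "0"]
    trios: list[Trio] = []
    seen: set[str] = set()
    for lineno, (_fam, iid, father, mother, _sex, _pheno) in chosen:
        if iid in seen:
            raise ParseError(path, lineno, f"duplicate proband id {iid!r}")
        seen.add(iid)
        trios.append(
            Trio(
                proband_id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                father_available=father != "0",
                mother_available=mother != "0",
            )
        )
    return trios


def write_pedigree(path, trios: Iterable[Trio], family_prefix: str = "FAM") -> None:
    lines = []
    for i, trio in enumerate(trios, start=1):
        fam = f"{family_prefix}{i}"
        father = trio.father_id if trio.father_available else "0"
        mother = trio.mother_id if trio.mother_available else "0"
        lines.append(f"{fam}\t{trio.proband_id}\t{father}\t{mother}\t0\t2")
        if trio.father_available:
            lines.append(f"{fam}\t{father}\t0\t0\t1\t1")
        if trio.mother_available:
            lines.append(f"{fam}\t{mother}\t0\t0\t2\t1")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a newline-delimited symbol list; blank lines are skipped."""
    path = Path(path)
    symbols = {
        line.strip().upper()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not symbols:
        raise ParseError(path, None, "gene set file contains no symbols")
    return GeneSet(name=name or path.stem, symbols=frozenset(symbols))


def write_gene_set(path, gene_set: GeneSet) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.symbols)) + "\n")


# ---------------------------------------------------------------------------
# known-variant database


def read_known_db(path) -> KnownVariantDB:
    """Read a dbSNP-role TSV with columns chrom, pos, ref, alt, source_id."""
    path = Path(path)
    db = KnownVariantDB()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(path, 1, f"bad known-db header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                db.add(
                    KnownVariantRecord(
                        chromosome=fields[0],
                        position=int(fields[1]),
                        ref_allele=fields[2],
                        alt_allele=fields[3],
                        source_id=fields[4] if len(fields) > 4 else "",
                    )
                )
            except (ModelError, ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return db


def write_known_db(path, db: KnownVariantDB) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "source_id"])
        for rec in db.records:
            writer.writerow(
                [rec.chromosome, rec.position, rec.ref_allele, rec.alt_allele, rec.source_id]
            )


# ---------------------------------------------------------------------------
# control cohort


class ControlGenotypes:
    """Sparse genotypes of an unaffected control cohort."""

    def __init__(self, sample_ids: Sequence[str]) -> None:
        if not sample_ids:
            raise ModelError("control cohort is empty")
        self.sample_ids = list(sample_ids)
        self._carriers: dict[tuple, set[str]] = {}

    @property
    def size(self) -> int:
        return len(self.sample_ids)

    def set_carrier(self, key, sample_id: str, zygosity: Zygosity = Zygosity.het) -> None:
        if sample_id not in self.sample_ids:
            raise ModelError(f"unknown control sample {sample_id!r}")
        if zygosity.is_carrier:
            self._carriers.setdefault(key, set()).add(sample_id)

    def carriers(self, key) -> set[str]:
        return set(self._carriers.get(key, ()))

    def carried_keys(self) -> list:
        return list(self._carriers)


def read_controls(path) -> ControlGenotypes:
    """Read control genotypes.

    TSV: columns chrom, pos, ref, alt followed by one zygosity column per
    control; VCF: any file whose suffix says so, genotypes taken as-is.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        table = _read_vcf(path)
        controls = ControlGenotypes(table.samples)
        for v in table.variants:
            for s in table.samples:
                zyg = table.genotypes.get(s, v.key)
                if zyg.is_carrier:
                    controls.set_carrier(v.key, s, zyg)
        return controls
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(path, 1, f"bad controls header {header}")
        samples = header[4:]
        controls = ControlGenotypes(samples)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(path, lineno, "column count mismatch")
            key = (fields[0], int(fields[1]), fields[2], fields[3])
            for sample, term in zip(samples, fields[4:]):
                zyg = Zygosity.from_term(term)
                if zyg.is_carrier:
                    controls.set_carrier(key, sample, zyg)
    return controls


def write_controls(path, controls: ControlGenotypes) -> None:
    keys = sorted(controls.carried_keys())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt"] + controls.sample_ids)
        for key in keys:
            carriers = controls.carriers(key)
            row = list(key) + [
                Zygosity.het.value if s in carriers else Zygosity.hom_ref.value
                for s in controls.sample_ids
            ]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# confirmation oracle


class ConfirmationOracle:
    """Stand-in for Sanger validation: (variant key, sample) -> confirmed.

    A missing entry raises rather than silently passing, so every candidate
    call must have an explicit wet-lab outcome (or simulator truth label).
    """

    def __init__(self) -> None:
        self._outcomes: dict[tuple, bool] = {}

    def record(self, key, sample_id: str, confirmed: bool) -> None:
        self._outcomes[(tuple(key), sample_id)] = confirmed

    def confirmed(self, key, sample_id: str) -> bool:
        try:
            return self._outcomes[(tuple(key), sample_id)]
        except KeyError:
            raise KeyError(
                f"confirmation oracle has no entry for variant {key} in sample "
                f"{sample_id!r}; refusing to silently pass"
            ) from None

    def has_entry(self, key, sample_id: str) -> bool:
        return (tuple(key), sample_id) in self._outcomes

    def entries(self):
        return dict(self._outcomes)


def read_oracle(path) -> ConfirmationOracle:
    """TSV columns: chrom, pos, ref, alt, sample, confirmed (true/false)."""
    path = Path(path)
    oracle = ConfirmationOracle()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "ref", "alt", "sample", "confirmed"]:
            raise ParseError(path, 1, f"bad oracle header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(path, lineno, "expected 6 columns")
            flag = fields[5].strip().lower()
            if flag not in ("true", "false"):
                raise ParseError(path, lineno, f"confirmed must be true/false, got {flag!r}")
            oracle.record(
                (fields[0], int(fields[1]), fields[2], fields[3]),
                fields[4],
                flag == "true",
            )
    return oracle


def write_oracle(path, oracle: ConfirmationOracle) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "sample", "confirmed"])
        for (key, sample), confirmed in sorted(
            oracle.entries().items(), key=lambda kv: (kv[0][0], kv[0][1])
        ):
            writer.writerow(list(key) + [sample, "true" if confirmed else "false"])


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> list[PhenotypeRecord]:
    """TSV with columns patient_id, mutation, then one column per feature."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    if "patient_id" not in df.columns or "mutation" not in df.columns:
        raise ParseError(path, 1, "phenotype table needs patient_id and mutation columns")
    feature_cols = [c for c in df.columns if c not in ("patient_id", "mutation")]
    records = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                patient_id=row["patient_id"],
                mutation=row["mutation"],
                features={c: row[c] for c in feature_cols},
            )
        )
    return records


def write_phenotypes(path, records: Sequence[PhenotypeRecord]) -> None:
    features = sorted({f for r in records for f in r.features})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "mutation": r.mutation}
        for f in features:
            row[f] = r.features.get(f, "unknown")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
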