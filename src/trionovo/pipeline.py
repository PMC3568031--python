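"""End-to-end orchestration: cascade -> recurrence -> validation -> scoring.

A run keeps the pre-novelty-filter data so that gene refocus remains
possible, logs a removal reason for every variant that does not survive
(conservation of records: every input variant is either a final candidate
or removed with a reason), and can be extended with additional patients
genotyped at the candidate loci, recomputing carrier lists, prevalences
and validation statuses over the larger cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .cascade import MatchMode, filter_consequence, filter_expressed, is_known, run_cascade
from .io import (
    ConfirmationOracle,
    ControlGenotypes,
    read_controls,
    read_gene_set,
    read_known_db,
    read_oracle,
    read_pedigree,
    read_phenotypes,
    read_variant_table,
)
from .model import (
    CandidateVariant,
    CascadeReport,
    Consequence,
    GeneSet,
    GenotypeMap,
    KnownVariantDB,
    Trio,
    Variant,
    VariantKey,
    Zygosity,
)
from .recurrence import RecurrenceResult, gene_refocus, prevalence, shared_variants
from .scoring import (
    HomologAlignment,
    conservation_fraction,
    grantham_distance,
    parse_protein_change,
    rank_candidates,
)
from .validation import ExclusionLog, exclude_non_causal

__all__ = ["PipelineConfig", "PipelineReport", "run_analysis", "run_pipeline", "extend_cohort"]


@dataclass
class PipelineConfig:
    """File-path configuration; serializable to and from YAML."""

    variant_table: str
    pedigree: str
    known_db: str
    gene_set: str
    controls: str
    oracle: str
    phenotypes: Optional[str] = None
    match_mode: str = "allele_aware"
    min_carriers: int = 4
    keep_classes: Optional[list[str]] = None
    refocus_genes: list[str] = field(default_factory=list)
    alignments: dict[str, str] = field(default_factory=dict)
    output_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in vars(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def check_paths(self) -> None:
        paths = [self.variant_table, self.pedigree, self.known_db, self.gene_set,
                 self.controls, self.oracle, self.phenotypes]
        paths += list(self.alignments.values())
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


@dataclass
class PipelineReport:
    """Result of one pipeline run, with every removal reason logged."""

    match_mode: str
    min_carriers: int
    cohort_samples: list[str]
    cascade_report: CascadeReport
    recurrence: RecurrenceResult
    candidates: list[CandidateVariant]            # ranked survivors
    removed: dict[VariantKey, str]                # variant key -> reason
    refocus_recovered: dict[str, list[VariantKey]]
    prevalences: dict[str, tuple[int, int, float, int]]  # label -> (carriers, cohort, frac, pct)
    # context retained for cohort extension
    trios: list[Trio] = field(default_factory=list)
    genotypes: GenotypeMap = field(default_factory=GenotypeMap)
    controls: Optional[ControlGenotypes] = None
    oracle: Optional[ConfirmationOracle] = None
    alignments: dict[str, HomologAlignment] = field(default_factory=dict)

    @property
    def cohort_size(self) -> int:
        return len(self.cohort_samples)

    def candidate_by_protein_change(self, protein_change: str) -> CandidateVariant:
        for c in self.candidates:
            if c.variant.protein_change == protein_change:
                return c
        raise KeyError(protein_change)

    def summary_rows(self) -> list[dict]:
        rows = []
        for c in self.candidates:
            label = c.variant.protein_change or f"{c.variant.chromosome}:{c.variant.position}"
            prev = self.prevalences.get(label)
            rows.append(
                {
                    "gene": c.variant.gene,
                    "variant": label,
                    "chrom": c.variant.chromosome,
                    "pos": c.variant.position,
                    "ref": c.variant.ref_allele,
                    "alt": c.variant.alt_allele,
                    "carriers": ",".join(c.carrier_ids),
                    "n_carriers": len(c.carrier_ids),
                    "statuses": ";".join(
                        f"{p}:{s.value}" for p, s in c.de_novo_status.items()
                    ),
                    "confirmed": c.sanger_confirmed,
                    "control_carriers": c.control_carrier_count,
                    "grantham": c.grantham,
                    "conservation": c.conservation,
                    "unvalidated": c.unvalidated,
                    "prevalence_percent": prev[3] if prev else None,
                }
            )
        return rows

    def write(self, out_dir) -> dict[str, Path]:
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cascade": out / "cascade_report.tsv",
            "candidates": out / "candidates.tsv",
            "removed": out / "removed.tsv",
        }
        pd.DataFrame(self.cascade_report.to_rows()).to_csv(paths["cascade"], sep="\t", index=False)
        pd.DataFrame(self.summary_rows()).to_csv(paths["candidates"], sep="\t", index=False)
        removed_rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "reason": r}
            for k, r in sorted(self.removed.items())
        ]
        pd.DataFrame(removed_rows).to_csv(paths["removed"], sep="\t", index=False)
        return paths


def _score_candidate(cand: CandidateVariant, alignments: Mapping[str, HomologAlignment]) -> None:
    v = cand.variant
    if v.protein_change:
        try:
            aa_from, residue, aa_to = parse_protein_change(v.protein_change)
        except ValueError:
            return
        if aa_from != aa_to:
            try:
                cand.grantham = float(grantham_distance(aa_from, aa_to))
            except Exception:
                cand.grantham = None
        gene = (v.gene or "").upper()
        if gene in alignments:
            try:
                cand.conservation = conservation_fraction(alignments[gene], residue)
            except (KeyError, ValueError):
                cand.conservation = None


def run_analysis(
    cohort: Mapping[str, Sequence[Variant]],
    trios: Sequence[Trio],
    genotypes: GenotypeMap,
    known_db: KnownVariantDB,
    gene_set: GeneSet,
    controls: ControlGenotypes,
    oracle: ConfirmationOracle,
    match_mode: MatchMode = MatchMode.allele_aware,
    min_carriers: int = 4,
    keep_classes=None,
    refocus_genes: Sequence[str] = (),
    alignments: Optional[Mapping[str, HomologAlignment]] = None,
) -> PipelineReport:
    """Run the full prioritization on in-memory cohort objects."""
    match_mode = MatchMode.from_term(match_mode)
    alignments = {k.upper(): v for k, v in (alignments or {}).items()}
    survivors, cascade_report = run_cascade(
        cohort, known_db, gene_set, match_mode, keep_classes
    )
    recurrence = shared_variants(survivors, min_carriers)

    # candidates: every cascade survivor in a recurrence-flagged gene
    carrier_lists: dict[VariantKey, list[str]] = {}
    variant_of: dict[VariantKey, Variant] = {}
    flagged_genes = set(recurrence.gene_carriers)
    for sample in cohort:
        for v in survivors.get(sample, []):
            if v.gene in flagged_genes:
                variant_of.setdefault(v.key, v)
                lst = carrier_lists.setdefault(v.key, [])
                if sample not in lst:
                    lst.append(sample)

    # gene refocus: pull back consequence-passing variants of named genes
    # from the pre-novelty-filter data (rescues position-collision losses)
    refocus_recovered: dict[str, list[VariantKey]] = {}
    for gene in refocus_genes:
        per_sample = gene_refocus(cohort, gene, keep_classes)
        recovered: list[VariantKey] = []
        for sample, vs in per_sample.items():
            for v in vs:
                variant_of.setdefault(v.key, v)
                lst = carrier_lists.setdefault(v.key, [])
                if sample not in lst:
                    lst.append(sample)
                if v.key not in recovered:
                    recovered.append(v.key)
        refocus_recovered[gene.upper()] = recovered

    candidates = [
        CandidateVariant(variant=variant_of[key], carrier_ids=carriers)
        for key, carriers in carrier_lists.items()
    ]
    for cand in candidates:
        _score_candidate(cand, alignments)

    log = ExclusionLog()
    surviving = exclude_non_causal(candidates, trios, genotypes, controls, oracle, log)
    ranked = rank_candidates(surviving)

    # removal log over every distinct input variant
    removed: dict[VariantKey, str] = {}
    survivor_keys = {c.variant.key for c in ranked}
    candidate_keys = set(carrier_lists)
    seen: set[VariantKey] = set()
    for sample, vs in cohort.items():
        for v in vs:
            if v.key in seen:
                continue
            seen.add(v.key)
            if v.key in survivor_keys:
                continue
            if v.key in log.removed:
                removed[v.key] = log.removed[v.key].value
            elif v.key in candidate_keys:
                removed[v.key] = "excluded"
            elif is_known(v, known_db, match_mode):
                removed[v.key] = "registered_known"
            elif not filter_consequence([v], keep_classes):
                removed[v.key] = "consequence_class"
            elif not filter_expressed([v], gene_set):
                removed[v.key] = "not_brain_expressed"
            else:
                removed[v.key] = "not_recurrent"

    cohort_samples = list(cohort)
    prevalences: dict[str, tuple[int, int, float, int]] = {}
    for c in ranked:
        label = c.variant.protein_change or f"{c.variant.chromosome}:{c.variant.position}"
        frac, pct = prevalence(len(c.carrier_ids), len(cohort_samples))
        prevalences[label] = (len(c.carrier_ids), len(cohort_samples), frac, pct)

    return PipelineReport(
        match_mode=match_mode.value,
        min_carriers=min_carriers,
        cohort_samples=cohort_samples,
        cascade_report=cascade_report,
        recurrence=recurrence,
        candidates=ranked,
        removed=removed,
        refocus_recovered=refocus_recovered,
        prevalences=prevalences,
        trios=list(trios),
        genotypes=genotypes,
        controls=controls,
        oracle=oracle,
        alignments=dict(alignments),
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Load the configured inputs, run the analysis, optionally write reports."""
    config.check_paths()
    table = read_variant_table(config.variant_table)
    trios = read_pedigree(config.pedigree)
    known_db = read_known_db(config.known_db)
    gene_set = read_gene_set(config.gene_set)
    controls = read_controls(config.controls)
    oracle = read_oracle(config.oracle)
    alignments = {
        gene.upper(): HomologAlignment.from_fasta(path)
        for gene, path in config.alignments.items()
    }
    probands = [t.proband_id for t in trios]
    cohort = table.per_sample(samples=[p for p in probands if p in table.samples])
    report = run_analysis(
        cohort,
        trios,
        table.genotypes,
        known_db,
        gene_set,
        controls,
        oracle,
        match_mode=MatchMode.from_term(config.match_mode),
        min_carriers=config.min_carriers,
        keep_classes=None if config.keep_classes is None else [
            Consequence.from_term(t) for t in config.keep_classes
        ],
        refocus_genes=config.refocus_genes,
        alignments=alignments,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def extend_cohort(
    report: PipelineReport,
    additional_samples: Mapping[str, Mapping[VariantKey, Zygosity]],
    additional_trios: Sequence[Trio] = (),
) -> PipelineReport:
    """Fold additional patients, genotyped at the candidate loci, into a report.

    Carrier lists, prevalences and validation statuses are recomputed over
    the extended cohort; adding zero samples returns an equivalent report.
    """
    collisions = set(additional_samples) & set(report.cohort_samples)
    if collisions:
        raise ValueError(f"sample id collision: {sorted(collisions)}")
    genotypes = GenotypeMap()
    genotypes.update(report.genotypes)
    for sample, calls in additional_samples.items():
        for key, zyg in calls.items():
            genotypes.set(sample, key, zyg)
    trios = list(report.trios) + list(additional_trios)
    trio_probands = {t.proband_id for t in trios}

    new_samples = report.cohort_samples + [
        s for s in additional_samples if s not in report.cohort_samples
    ]
    candidates = []
    for cand in report.candidates:
        carriers = list(cand.carrier_ids)
        for sample in additional_samples:
            if genotypes.get(sample, cand.variant.key).is_carrier and sample not in carriers:
                carriers.append(sample)
        candidates.append(
            CandidateVariant(
                variant=cand.variant,
                carrier_ids=carriers,
                grantham=cand.grantham,
                conservation=cand.conservation,
            )
        )
    log = ExclusionLog()
    surviving = exclude_non_causal(
        candidates, trios, genotypes, report.controls, report.oracle, log
    )
    ranked = rank_candidates(surviving)
    removed = dict(report.removed)
    for key, reason in log.removed.items():
        removed[key] = reason.value
    prevalences = {}
    for c in ranked:
        label = c.variant.protein_change or f"{c.variant.chromosome}:{c.variant.position}"
        frac, pct = prevalence(len(c.carrier_ids), len(new_samples))
        prevalences[label] = (len(c.carrier_ids), len(new_samples), frac, pct)
    return PipelineReport(
        match_mode=report.match_mode,
        min_carriers=report.min_carriers,
        cohort_samples=new_samples,
        cascade_report=report.cascade_report,
        recurrence=report.recurrence,
        candidates=ranked,
        removed=removed,
        refocus_recovered=dict(report.refocus_recovered),
        prevalences=prevalences,
        trios=trios,
        genotypes=genotypes,
        controls=report.controls,
        oracle=report.oracle,
        alignments=dict(report.alignments),
    )
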