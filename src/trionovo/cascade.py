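"""Sequential novelty -> consequence -> expression filters with per-stage counts.

The novelty filter removes variants registered in a known-polymorphism
database. Its matching semantics are explicit: ``allele_aware`` (the
default) calls a query known only when a database record shares chromosome,
position, ref *and* alt; ``position_only`` calls it known when any record
shares the coordinate. The latter reproduces a real failure mode — a novel
substitution is discarded because a *different* substitution at the same
site is registered (the ATP1A3 D801N/D801Y configuration) — and is kept as
an explicit flag so the pitfall can be demonstrated and audited.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    CascadeReport,
    GeneSet,
    KnownVariantDB,
    NSSS_CLASSES,
    StageCounts,
    Variant,
)

__all__ = [
    "MatchMode",
    "is_known",
    "filter_novel",
    "filter_consequence",
    "filter_expressed",
    "run_cascade",
]


class MatchMode(enum.Enum):
    position_only = "position_only"
    allele_aware = "allele_aware"

    @classmethod
    def from_term(cls, term) -> "MatchMode":
        if isinstance(term, cls):
            return term
        aliases = {"position": cls.position_only, "allele": cls.allele_aware}
        term = str(term).strip().lower()
        if term in aliases:
            return aliases[term]
        return cls(term)


def is_known(variant: Variant, known_db: KnownVariantDB, match_mode: MatchMode) -> bool:
    """Is the variant registered in the database under the given semantics?"""
    mode = MatchMode.from_term(match_mode)
    if mode is MatchMode.position_only:
        return known_db.contains_position(variant.chromosome, variant.position)
    return known_db.contains_allele(
        variant.chromosome, variant.position, variant.ref_allele, variant.alt_allele
    )


def filter_novel(
    variants: Sequence[Variant],
    known_db: KnownVariantDB,
    match_mode: MatchMode = MatchMode.allele_aware,
) -> list[Variant]:
    """Keep only non-registered variants, preserving input order."""
    return [v for v in variants if not is_known(v, known_db, match_mode)]


def filter_consequence(
    variants: Sequence[Variant],
    keep_classes: Optional[Iterable] = None,
) -> list[Variant]:
    """Keep protein-altering and splice-site consequence classes."""
    keep = frozenset(keep_classes) if keep_classes is not None else NSSS_CLASSES
    return [v for v in variants if v.consequence in keep]


def filter_expressed(variants: Sequence[Variant], gene_set: GeneSet) -> list[Variant]:
    """Keep variants in genes from the expression set.

    A variant with no gene symbol cannot be shown expressed and is removed.
    """
    return [v for v in variants if v.gene in gene_set]


def _stage_counts(
    total: Sequence[Variant],
    novel: Sequence[Variant],
    nsss: Sequence[Variant],
    brain: Sequence[Variant],
) -> StageCounts:
    def split(vs):
        snv = [v for v in vs if not v.is_indel]
        indel = [v for v in vs if v.is_indel]
        return snv, indel

    t_snv, t_ind = split(total)
    n_snv, n_ind = split(novel)
    s_snv, s_ind = split(nsss)
    b_snv, b_ind = split(brain)
    counts = StageCounts(
        n_total_variants=len(t_snv),
        n_novel_variants=len(n_snv),
        n_novel_nsss_variants=len(s_snv),
        n_novel_nsss_genes=len({v.gene for v in s_snv if v.gene}),
        n_brain_variants=len(b_snv),
        n_brain_genes=len({v.gene for v in b_snv if v.gene}),
        n_total_indels=len(t_ind),
        n_novel_indels=len(n_ind),
        n_novel_nsss_indels=len(s_ind),
        n_brain_indels=len(b_ind),
    )
    counts.check()
    return counts


def run_cascade(
    cohort_tables: Mapping[str, Sequence[Variant]],
    known_db: KnownVariantDB,
    gene_set: GeneSet,
    match_mode: MatchMode = MatchMode.allele_aware,
    keep_classes: Optional[Iterable] = None,
) -> tuple[dict[str, list[Variant]], CascadeReport]:
    """Run novelty -> consequence -> expression on each sample's variants.

    ``cohort_tables`` maps sample id to the variants that sample carries.
    Returns surviving variants per sample plus a per-stage count report;
    cohort unique totals count each distinct variant key (and gene) once
    across samples.
    """
    if not cohort_tables:
        raise ValueError("cascade needs at least one sample")
    survivors: dict[str, list[Variant]] = {}
    report = CascadeReport()
    uniq: dict[str, set] = {s: set() for s in ("total", "novel", "nsss", "brain")}
    uniq_genes: dict[str, set] = {"nsss": set(), "brain": set()}
    for sample, variants in cohort_tables.items():
        novel = filter_novel(variants, known_db, match_mode)
        nsss = filter_consequence(novel, keep_classes)
        brain = filter_expressed(nsss, gene_set)
        survivors[sample] = brain
        report.per_sample[sample] = _stage_counts(variants, novel, nsss, brain)
        snv_only = lambda vs: (v for v in vs if not v.is_indel)
        uniq["total"].update(v.key for v in snv_only(variants))
        uniq["novel"].update(v.key for v in snv_only(novel))
        uniq["nsss"].update(v.key for v in snv_only(nsss))
        uniq["brain"].update(v.key for v in snv_only(brain))
        uniq_genes["nsss"].update(v.gene for v in snv_only(nsss) if v.gene)
        uniq_genes["brain"].update(v.gene for v in snv_only(brain) if v.gene)
    report.unique_total_variants = len(uniq["total"])
    report.unique_novel_variants = len(uniq["novel"])
    report.unique_novel_nsss_variants = len(uniq["nsss"])
    report.unique_novel_nsss_genes = len(uniq_genes["nsss"])
    report.unique_brain_variants = len(uniq["brain"])
    report.unique_brain_genes = len(uniq_genes["brain"])
    report.check()
    return survivors, report
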