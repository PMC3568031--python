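"""Cross-proband sharing, prevalence arithmetic, and gene refocus.

Sharing is assessed at two levels. Variant-level recurrence asks how many
probands carry the *same* substitution; gene-level recurrence asks how many
probands carry *any* qualifying variant of a gene, so a gene hit by four
different substitutions in four probands is flagged just like one variant
shared by four. The default carrier threshold is 4 — half of an
eight-proband cohort, the smallest sharing worth pursuing in a dominant
sporadic-disease design — and is exposed as a parameter.

``gene_refocus`` is the rescue step for the position-only matching pitfall:
given the *pre-novelty-filter* data, it returns every consequence-passing
variant of one gene per sample, including variants discarded upstream as
"known". A causal variant wrongly removed because a different allele shares
its coordinate is recoverable only this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .model import NSSS_CLASSES, Variant, VariantKey
from .cascade import filter_consequence

__all__ = ["RecurrenceResult", "shared_variants", "prevalence", "gene_refocus"]


@dataclass
class RecurrenceResult:
    """Variant-level and gene-level sharing maps, carriers deduplicated."""

    variant_carriers: dict[VariantKey, list[str]] = field(default_factory=dict)
    gene_carriers: dict[str, set[tuple[str, VariantKey]]] = field(default_factory=dict)
    variants: dict[VariantKey, Variant] = field(default_factory=dict)

    def gene_carrier_count(self, gene: str) -> int:
        return len({carrier for carrier, _ in self.gene_carriers.get(gene, ())})

    def flagged_genes(self) -> list[str]:
        return sorted(self.gene_carriers)


def shared_variants(
    per_sample_variants: Mapping[str, Sequence[Variant]],
    min_carriers: int = 4,
) -> RecurrenceResult:
    """Restrict to variants/genes carried by at least ``min_carriers`` probands."""
    if min_carriers < 1:
        raise ValueError(f"min_carriers must be >= 1, got {min_carriers}")
    by_variant: dict[VariantKey, list[str]] = {}
    by_gene: dict[str, set[tuple[str, VariantKey]]] = {}
    variants: dict[VariantKey, Variant] = {}
    for sample, vs in per_sample_variants.items():
        seen_keys = set()
        for v in vs:
            if v.key in seen_keys:
                continue
            seen_keys.add(v.key)
            variants.setdefault(v.key, v)
            carriers = by_variant.setdefault(v.key, [])
            if sample not in carriers:
                carriers.append(sample)
            if v.gene:
                by_gene.setdefault(v.gene, set()).add((sample, v.key))
    result = RecurrenceResult()
    result.variant_carriers = {
        k: c for k, c in by_variant.items() if len(c) >= min_carriers
    }
    result.gene_carriers = {
        g: pairs
        for g, pairs in by_gene.items()
        if len({carrier for carrier, _ in pairs}) >= min_carriers
    }
    result.variants = {
        k: variants[k]
        for k in set(result.variant_carriers)
        | {key for pairs in result.gene_carriers.values() for _, key in pairs}
    }
    return result


def prevalence(carrier_count: int, cohort_size: int) -> tuple[float, int]:
    """Carriers as a share of the cohort: (raw fraction, integer percent).

    The percent is rounded half-up, so 19 of 82 reports 23%.
    """
    if cohort_size == 0:
        raise ValueError("cohort_size must be positive")
    if not 0 < carrier_count <= cohort_size:
        raise ValueError(
            f"carrier count must be in (0, cohort_size]; got "
            f"{carrier_count} of {cohort_size}"
        )
    fraction = carrier_count / cohort_size
    percent = int(
        (Decimal(100 * carrier_count) / Decimal(cohort_size)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    return fraction, percent


def gene_refocus(
    all_variants_per_sample: Mapping[str, Sequence[Variant]],
    gene: str,
    keep_classes: Optional[Iterable] = None,
) -> dict[str, list[Variant]]:
    """All consequence-passing variants of one gene, novelty filter bypassed.

    ``all_variants_per_sample`` must be the pre-novelty-filter data;
    applying this to post-cascade survivors cannot recover anything.
    """
    if not gene or not gene.strip():
        raise ValueError("gene symbol must be non-empty")
    target = gene.strip().upper()
    keep = frozenset(keep_classes) if keep_classes is not None else NSSS_CLASSES
    out: dict[str, list[Variant]] = {}
    for sample, vs in all_variants_per_sample.items():
        in_gene = [v for v in vs if v.gene and v.gene.upper() == target]
        out[sample] = filter_consequence(in_gene, keep)
    return out
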