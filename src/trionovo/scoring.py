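"""Substitution impact scoring, conservation, ranking, phenotype counts.

The physicochemical distance between two amino acids combines three
residue properties — composition *c* (atomic weight ratio of hetero
elements in the side chain), polarity *p*, and molecular volume *v* — as

    d(i, j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho chosen so the
mean over all 190 unordered residue pairs is 100. Larger distances mark
chemically more radical substitutions (range ~5 for Ile/Leu to 215 for
Cys/Trp).

Two surfaces are provided. :data:`GRANTHAM_MATRIX` is the canonical
published integer table, which downstream consumers use as the shared
reference; :class:`GranthamModel` recomputes distances from the property
values. The two agree exactly on 149 of 190 pairs and within one unit on
the rest except Trp/Asp, where the printed 181 cannot be regenerated from
the printed properties (recomputation gives 191) — an internal rounding
anomaly of the historical table, surfaced here rather than hidden.
:func:`grantham_distance` defaults to the published table.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import CandidateVariant, PhenotypeRecord, PHENOTYPE_SCHEMA, VocabularyError

__all__ = [
    "AMINO_ACIDS",
    "RESIDUE_PROPERTIES",
    "GranthamModel",
    "GRANTHAM_MATRIX",
    "grantham_distance",
    "grantham_matrix",
    "HomologAlignment",
    "conservation_fraction",
    "parse_protein_change",
    "rank_candidates",
    "aggregate_phenotypes",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: (composition, polarity, molecular volume) per residue.
RESIDUE_PROPERTIES: Mapping[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}


def _check_residue(aa: str) -> str:
    aa = aa.upper()
    if aa not in RESIDUE_PROPERTIES:
        raise VocabularyError(f"{aa!r} is not a standard amino acid letter")
    return aa


@dataclass(frozen=True)
class GranthamModel:
    """From-scratch physicochemical distance model.

    ``rho`` defaults to the value normalizing the mean distance over the
    190 unordered residue pairs to 100.
    """

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(RESIDUE_PROPERTIES)
    )
    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        if set(self.properties) != set(RESIDUE_PROPERTIES):
            missing = set(RESIDUE_PROPERTIES) - set(self.properties)
            raise ValueError(f"properties must cover all 20 residues; missing {missing}")
        if self.rho is None:
            pairs = itertools.combinations(sorted(self.properties), 2)
            raws = [self._raw(a, b) for a, b in pairs]
            object.__setattr__(self, "rho", 100.0 / (sum(raws) / len(raws)))

    def _raw(self, a: str, b: str) -> float:
        c1, p1, v1 = self.properties[a]
        c2, p2, v2 = self.properties[b]
        return math.sqrt(
            self.alpha * (c1 - c2) ** 2
            + self.beta * (p1 - p2) ** 2
            + self.gamma * (v1 - v2) ** 2
        )

    def distance(self, aa_from: str, aa_to: str) -> float:
        """Full-precision distance; symmetric, zero iff identical."""
        a, b = _check_residue(aa_from), _check_residue(aa_to)
        if a == b:
            return 0.0
        return self.rho * self._raw(a, b)

    def matrix(self) -> dict[tuple[str, str], int]:
        """All 190 unordered pairs, rounded to integers."""
        return {
            (a, b): round(self.distance(a, b))
            for a, b in itertools.combinations(sorted(RESIDUE_PROPERTIES), 2)
        }


def _build_published() -> dict[tuple[str, str], int]:
    # Canonical published integer table (lower triangle, historical layout:
    # columns S R L P T A V G I F Y C H Q N K D E M, rows R..W).
    cols = "SRLPTAVGIFYCHQNKDEM"
    rows = {
        "R": [110],
        "L": [145, 102],
        "P": [74, 103, 98],
        "T": [58, 71, 92, 38],
        "A": [99, 112, 96, 27, 58],
        "V": [124, 96, 32, 68, 69, 64],
        "G": [56, 125, 138, 42, 59, 60, 109],
        "I": [142, 97, 5, 95, 89, 94, 29, 135],
        "F": [155, 97, 22, 114, 103, 113, 50, 153, 21],
        "Y": [144, 77, 36, 110, 92, 112, 55, 147, 33, 22],
        "C": [112, 180, 198, 169, 149, 195, 192, 159, 198, 205, 194],
        "H": [89, 29, 99, 77, 47, 86, 84, 98, 94, 100, 83, 174],
        "Q": [68, 43, 113, 76, 42, 91, 96, 87, 109, 116, 99, 154, 24],
        "N": [46, 86, 153, 91, 65, 111, 133, 80, 149, 158, 143, 139, 68, 46],
        "K": [121, 26, 107, 103, 78, 106, 97, 127, 102, 102, 85, 202, 32, 53, 94],
        "D": [65, 96, 172, 108, 85, 126, 152, 94, 168, 177, 160, 154, 81, 61, 23, 101],
        "E": [80, 54, 138, 93, 65, 107, 121, 98, 134, 140, 122, 170, 40, 29, 42, 56, 45],
        "M": [135, 91, 15, 87, 81, 84, 21, 127, 10, 28, 36, 196, 87, 101, 142, 95, 160, 126],
        "W": [177, 101, 61, 147, 128, 148, 88, 184, 61, 40, 37, 215, 115, 130, 174, 110, 181, 152, 67],
    }
    table: dict[tuple[str, str], int] = {}
    for row_aa, values in rows.items():
        for col_aa, value in zip(cols, values):
            table[tuple(sorted((row_aa, col_aa)))] = value
    return table


#: Published 20x20 integer distance matrix (unordered pairs; diagonal is 0).
GRANTHAM_MATRIX: Mapping[tuple[str, str], int] = _build_published()


def grantham_distance(
    aa_from: str, aa_to: str, model: Optional[GranthamModel] = None
) -> float:
    """Distance between two residues.

    With no model, the canonical published integer is returned; with a
    :class:`GranthamModel`, the full-precision recomputed value.
    """
    a, b = _check_residue(aa_from), _check_residue(aa_to)
    if model is not None:
        return model.distance(a, b)
    if a == b:
        return 0
    return GRANTHAM_MATRIX[tuple(sorted((a, b)))]


def grantham_matrix(model: Optional[GranthamModel] = None) -> dict[tuple[str, str], int]:
    """The 190-pair integer matrix (published, or recomputed from a model)."""
    if model is None:
        return dict(GRANTHAM_MATRIX)
    return model.matrix()


_PCHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


def parse_protein_change(protein_change: str) -> tuple[str, int, str]:
    """Split a short-form protein change like "D801N" into (from, pos, to)."""
    m = _PCHANGE_RE.match(protein_change.strip())
    if not m:
        raise ValueError(f"cannot parse protein change {protein_change!r}")
    return m.group(1), int(m.group(2)), m.group(3)


# ---------------------------------------------------------------------------
# conservation


class HomologAlignment:
    """Aligned orthologue/isoform block anchored on a human reference row.

    ``rows`` are (label, aligned residue string) in display order; the human
    row supplies the residue numbering (gaps excluded) and the consensus
    anchor for conservation.
    """

    GAP_CHARS = "-."

    def __init__(self, rows: Sequence[tuple[str, str]], human_label: Optional[str] = None):
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        self.rows = [(label, seq.upper()) for label, seq in rows]
        if human_label is None:
            human_candidates = [lbl for lbl, _ in self.rows if "human" in lbl.lower()]
            human_label = human_candidates[0] if human_candidates else self.rows[0][0]
        labels = [lbl for lbl, _ in self.rows]
        if human_label not in labels:
            raise ValueError(f"human row {human_label!r} not in alignment")
        self.human_label = human_label
        self._human_seq = dict(self.rows)[human_label]
        self.column_map: dict[int, int] = {}
        residue = 0
        for col, ch in enumerate(self._human_seq):
            if ch not in self.GAP_CHARS:
                residue += 1
                self.column_map[residue] = col
        # offset support: residue numbering may not start at 1
        self._offset = 0

    def with_start(self, first_residue_number: int) -> "HomologAlignment":
        """Renumber so the first human residue is ``first_residue_number``."""
        self._offset = first_residue_number - 1
        return self

    def column_for(self, human_residue_number: int) -> int:
        try:
            return self.column_map[human_residue_number - self._offset]
        except KeyError:
            raise KeyError(
                f"human residue {human_residue_number} not covered by alignment"
            ) from None

    def human_residue(self, human_residue_number: int) -> str:
        return self._human_seq[self.column_for(human_residue_number)]

    @classmethod
    def from_fasta(cls, path, human_label: Optional[str] = None) -> "HomologAlignment":
        from Bio import AlignIO

        alignment = AlignIO.read(str(path), "fasta")
        rows = [(rec.id, str(rec.seq)) for rec in alignment]
        return cls(rows, human_label=human_label)


def conservation_fraction(
    alignment: HomologAlignment, human_residue_number: int
) -> float:
    """Fraction of informative homolog rows matching the human residue.

    Rows gapped at the queried column are excluded from the denominator, as
    is the human reference row itself; a column with no informative homolog
    rows is degenerate and raises.
    """
    col = alignment.column_for(human_residue_number)
    ref = alignment.human_residue(human_residue_number)
    informative = [
        seq[col]
        for label, seq in alignment.rows
        if label != alignment.human_label and seq[col] not in HomologAlignment.GAP_CHARS
    ]
    if not informative:
        raise ValueError(
            f"no informative rows at human residue {human_residue_number} "
            "(all homolog rows gapped)"
        )
    return sum(1 for ch in informative if ch == ref) / len(informative)


# ---------------------------------------------------------------------------
# ranking and phenotypes

_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def _chrom_rank(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, _CHROM_ORDER[c]) if c in _CHROM_ORDER else (1, c)


def rank_candidates(candidates: Sequence[CandidateVariant]) -> list[CandidateVariant]:
    """Order candidates by decreasing priority.

    Sort key: confirmed de novo carrier count, total carriers, conservation,
    then physicochemical distance, all descending; ties break by genomic
    coordinate (stable).
    """
    from .validation import TrioClassification

    def de_novo_carriers(c: CandidateVariant) -> int:
        if not c.sanger_confirmed:
            return 0
        return sum(
            1
            for s in c.de_novo_status.values()
            if s is TrioClassification.de_novo
        )

    def sort_key(c: CandidateVariant):
        return (
            -de_novo_carriers(c),
            -len(c.carrier_ids),
            -(c.conservation if c.conservation is not None else -1.0),
            -(c.grantham if c.grantham is not None else -1.0),
            _chrom_rank(c.variant.chromosome),
            c.variant.position,
            c.variant.ref_allele,
            c.variant.alt_allele,
        )

    return sorted(candidates, key=sort_key)


def aggregate_phenotypes(
    records: Sequence[PhenotypeRecord], mutation: str, feature: str
) -> tuple[int, int]:
    """(carriers of ``mutation`` with feature == "yes", total carriers)."""
    if feature not in PHENOTYPE_SCHEMA:
        raise VocabularyError(
            f"unknown phenotype feature {feature!r}; schema has "
            f"{sorted(PHENOTYPE_SCHEMA)}"
        )
    carriers = [r for r in records if r.mutation == mutation]
    with_feature = sum(
        1 for r in carriers if r.features.get(feature, "unknown") == "yes"
    )
    return with_feature, len(carriers)
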