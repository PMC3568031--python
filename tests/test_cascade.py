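"""Novelty/consequence/expression filters and their matching semantics."""

import pytest
from hypothesis import given, settings, strategies as st

from trionovo.cascade import (
    MatchMode,
    filter_consequence,
    filter_expressed,
    filter_novel,
    is_known,
    run_cascade,
)
from trionovo.model import (
    Consequence,
    GeneSet,
    KnownVariantDB,
    KnownVariantRecord,
    Variant,
)

D801Y_DB = KnownVariantDB([KnownVariantRecord("19", 42474557, "G", "T", "rdp")])


def table2_variants(paper):
    return [paper.atp1a3[p] for p in ("G755C", "E815K", "D801N", "C927Y")]


class TestIsKnown:
    def test_position_only_conflates_different_alleles(self, paper):
        d801n = paper.atp1a3["D801N"]
        assert is_known(d801n, D801Y_DB, MatchMode.position_only) is True

    def test_allele_aware_distinguishes_substitutions(self, paper):
        d801n = paper.atp1a3["D801N"]
        assert is_known(d801n, D801Y_DB, MatchMode.allele_aware) is False

    @pytest.mark.parametrize("mode", list(MatchMode))
    def test_empty_db_knows_nothing(self, paper, mode):
        assert is_known(paper.atp1a3["D801N"], KnownVariantDB(), mode) is False


class TestFilterNovel:
    def test_position_only_loses_the_collided_variant(self, paper):
        out = filter_novel(table2_variants(paper), D801Y_DB, MatchMode.position_only)
        assert [v.protein_change for v in out] == ["G755C", "E815K", "C927Y"]

    def test_allele_aware_keeps_all_four(self, paper):
        out = filter_novel(table2_variants(paper), D801Y_DB, MatchMode.allele_aware)
        assert len(out) == 4

    def test_empty_input(self):
        assert filter_novel([], D801Y_DB, MatchMode.allele_aware) == []


class TestFilterConsequence:
    def test_missense_retained(self, paper):
        assert filter_consequence([paper.atp1a3["E815K"]]) == [paper.atp1a3["E815K"]]

    def test_synonymous_removed(self):
        syn = Variant("1", 100, "G", "A", "X", None, "L10L", Consequence.synonymous)
        assert filter_consequence([syn]) == []

    def test_splice_acceptor_retained(self):
        ss = Variant("1", 100, "G", "A", "X", None, None, Consequence.splice_acceptor)
        assert filter_consequence([ss]) == [ss]


class TestFilterExpressed:
    def test_brain_gene_retained(self, paper):
        v = paper.atp1a3["E815K"]
        assert filter_expressed([v], paper.gene_set) == [v]

    def test_non_brain_gene_removed(self, paper):
        v = Variant("2", 100, "G", "A", "TTN", None, "I1V", Consequence.missense)
        assert filter_expressed([v], paper.gene_set) == []

    def test_missing_gene_symbol_fails_closed(self, paper):
        v = Variant("2", 100, "G", "A", None, None, None, Consequence.other)
        assert filter_expressed([v], paper.gene_set) == []

    def test_empty_input(self, paper):
        assert filter_expressed([], paper.gene_set) == []


class TestRunCascade:
    def test_all_registered_sample_has_zero_downstream(self, paper):
        db = KnownVariantDB(
            [KnownVariantRecord(*v.key) for v in table2_variants(paper)]
        )
        survivors, report = run_cascade(
            {"S1": table2_variants(paper)}, db, paper.gene_set
        )
        counts = report.per_sample["S1"]
        assert survivors["S1"] == []
        assert counts.n_novel_variants == 0 == counts.n_brain_variants

    def test_position_only_cascade_leaves_five_atp1a3_probands(self, paper):
        survivors, _ = run_cascade(
            paper.exome_cohort(), paper.known_db, paper.gene_set,
            MatchMode.position_only,
        )
        with_atp1a3 = [
            s for s, vs in survivors.items() if any(v.gene == "ATP1A3" for v in vs)
        ]
        assert len(with_atp1a3) == 5

    def test_simulated_counts_equal_truth_labels(self, small_sim, small_sim_genes):
        _, report = run_cascade(
            small_sim.cohort, small_sim.known_db, small_sim_genes
        )
        for sample in small_sim.probands:
            c = report.per_sample[sample]
            assert (
                c.n_total_variants,
                c.n_novel_variants,
                c.n_novel_nsss_variants,
                c.n_brain_variants,
            ) == small_sim.truth.stage_counts(sample)

    def test_cohort_unique_totals_count_shared_variants_once(self, paper):
        _, report = run_cascade(paper.exome_cohort(), paper.known_db, paper.gene_set)
        summed = sum(c.n_brain_variants for c in report.per_sample.values())
        assert report.unique_brain_variants < summed  # E815K etc. are shared


# --- property tests ---------------------------------------------------------

_consequences = st.sampled_from(list(Consequence))


@st.composite
def variants(draw):
    cons = draw(_consequences)
    coding = cons in (Consequence.missense, Consequence.synonymous)
    ref, alt = draw(
        st.sampled_from([("G", "A"), ("G", "T"), ("C", "T"), ("A", "G")])
    )
    return Variant(
        chromosome=draw(st.sampled_from(["1", "2", "19"])),
        position=draw(st.integers(1, 30)),
        ref_allele=ref,
        alt_allele=alt,
        gene=draw(st.sampled_from(["ATP1A3", "SYNE1", "TTN", None])),
        cdna_change=None,
        protein_change="A1V" if coding else None,
        consequence=cons,
    )


@st.composite
def dbs(draw):
    records = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2", "19"]),
                st.integers(1, 30),
                st.sampled_from([("G", "A"), ("G", "T"), ("C", "T")]),
            ),
            max_size=20,
        )
    )
    return KnownVariantDB(
        [KnownVariantRecord(c, p, ra[0], ra[1]) for c, p, ra in records]
    )


GENES = GeneSet("brain", frozenset({"ATP1A3", "SYNE1"}))


@settings(max_examples=200, deadline=None)
@given(vs=st.lists(variants(), max_size=30), db=dbs())
def test_filters_commute_and_are_idempotent(vs, db):
    """The three filters are independent predicates: any order, once or twice."""
    mode = MatchMode.allele_aware

    def novel(x):
        return filter_novel(x, db, mode)

    def cons(x):
        return filter_consequence(x)

    def expr(x):
        return filter_expressed(x, GENES)

    baseline = expr(cons(novel(vs)))
    import itertools

    for order in itertools.permutations([novel, cons, expr]):
        out = vs
        for f in order:
            out = f(out)
        assert set(v.key for v in out) == set(v.key for v in baseline)
    assert novel(novel(vs)) == novel(vs)
    assert cons(cons(vs)) == cons(vs)
    assert expr(expr(vs)) == expr(vs)


@settings(max_examples=200, deadline=None)
@given(vs=st.lists(variants(), max_size=30), db=dbs())
def test_allele_aware_survivors_superset_of_position_only(vs, db):
    """Position-only matching can only remove more, and exactly the
    variants sharing a registered coordinate without a registered allele."""
    aware = filter_novel(vs, db, MatchMode.allele_aware)
    position = filter_novel(vs, db, MatchMode.position_only)
    assert {v.key for v in position} <= {v.key for v in aware}
    difference = {v.key for v in aware} - {v.key for v in position}
    expected = {
        v.key
        for v in vs
        if db.contains_position(v.chromosome, v.position)
        and not db.contains_allele(*v.key)
    }
    assert difference == expected
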