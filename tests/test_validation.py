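"""Trio classification, control screening, confirmation, and exclusion."""

import itertools

import pytest

from trionovo.io import ControlGenotypes
from trionovo.model import (
    CandidateVariant,
    Consequence,
    GenotypeMap,
    Trio,
    Variant,
    Zygosity,
)
from trionovo.validation import (
    RemovalReason,
    ExclusionLog,
    TrioClassification,
    classify_trio,
    confirm_variant,
    control_screen,
    exclude_non_causal,
)

V = Variant("19", 42474436, "G", "A", "ATP1A3", "c.2443G>A", "E815K", Consequence.missense)


def build(proband, father=Zygosity.hom_ref, mother=Zygosity.hom_ref,
          father_available=True, mother_available=True):
    trio = Trio("P", "F" if father_available else None, "M" if mother_available else None,
                father_available=father_available, mother_available=mother_available)
    gm = GenotypeMap()
    gm.set("P", V.key, proband)
    if father_available:
        gm.set("F", V.key, father)
    if mother_available:
        gm.set("M", V.key, mother)
    return trio, gm


class TestClassifyTrio:
    def test_het_proband_with_reference_parents_is_de_novo(self):
        trio, gm = build(Zygosity.het)
        assert classify_trio(V, trio, gm) is TrioClassification.de_novo

    def test_carrier_parent_gives_inherited(self):
        trio, gm = build(Zygosity.het, father=Zygosity.het)
        assert classify_trio(V, trio, gm) is TrioClassification.inherited_paternal

    def test_unavailable_parent_gives_unknown(self):
        trio, gm = build(Zygosity.het, father_available=False)
        assert classify_trio(V, trio, gm) is TrioClassification.unknown_parent

    def test_reference_proband_is_absent(self):
        trio, gm = build(Zygosity.hom_ref)
        assert classify_trio(V, trio, gm) is TrioClassification.absent_in_proband

    def test_missing_proband_genotype_is_an_error(self):
        trio, gm = build(Zygosity.missing)
        with pytest.raises(ValueError, match="no genotype"):
            classify_trio(V, trio, gm)

    def test_exhaustive_against_brute_force_table(self):
        """Enumerate every proband x father x mother zygosity and availability
        combination and compare with an independent case analysis."""
        zygs = list(Zygosity)
        availabilities = [True, False]
        carrier = {Zygosity.het, Zygosity.hom_alt}
        checked = 0
        for pz, fz, mz, fa, ma in itertools.product(zygs, zygs, zygs, availabilities, availabilities):
            trio, gm = build(pz, father=fz, mother=mz, father_available=fa, mother_available=ma)
            if pz is Zygosity.missing:
                with pytest.raises(ValueError):
                    classify_trio(V, trio, gm)
                continue
            got = classify_trio(V, trio, gm)
            # independent decision table
            if pz not in carrier:
                expected = TrioClassification.absent_in_proband
            else:
                f_observed = fa and fz is not Zygosity.missing
                m_observed = ma and mz is not Zygosity.missing
                f_carrier = f_observed and fz in carrier
                m_carrier = m_observed and mz in carrier
                if f_carrier and m_carrier:
                    expected = TrioClassification.inherited_either
                elif f_carrier:
                    expected = TrioClassification.inherited_paternal
                elif m_carrier:
                    expected = TrioClassification.inherited_maternal
                elif f_observed and m_observed:
                    expected = TrioClassification.de_novo
                else:
                    expected = TrioClassification.unknown_parent
            assert got is expected, (pz, fz, mz, fa, ma)
            checked += 1
        assert checked == 4 * 4 * 4 * 3  # all combinations with a usable proband call


class TestControlScreen:
    def test_syne1_variant_found_in_two_controls(self, paper):
        assert control_screen(paper.syne1_novel["E1319K"], paper.controls) == 2

    @pytest.mark.parametrize("pchange", ["G755C", "E815K", "D801N", "C927Y"])
    def test_atp1a3_mutations_absent_from_controls(self, paper, pchange):
        assert control_screen(paper.atp1a3[pchange], paper.controls) == 0

    def test_additive_over_disjoint_control_sets(self, paper):
        v = paper.syne1_novel["V2399A"]
        half1 = ControlGenotypes(paper.controls.sample_ids[:48])
        half2 = ControlGenotypes(paper.controls.sample_ids[48:])
        for carrier in paper.controls.carriers(v.key):
            target = half1 if carrier in half1.sample_ids else half2
            target.set_carrier(v.key, carrier)
        assert control_screen(v, half1) + control_screen(v, half2) == control_screen(
            v, paper.controls
        )


class TestConfirmVariant:
    def test_shared_artifact_fails_confirmation(self, paper):
        cand = CandidateVariant(
            paper.cntn4,
            carrier_ids=["II-1", "III-1", "IV-1", "VI-1", "VII-1", "VIII-1"],
        )
        assert confirm_variant(cand, paper.oracle) is False

    def test_real_mutation_confirms(self, paper):
        cand = CandidateVariant(paper.atp1a3["E815K"], carrier_ids=["II-1", "III-1"])
        assert confirm_variant(cand, paper.oracle) is True

    def test_simulator_artifact_fails_by_construction(self, small_sim):
        artifact = small_sim.truth.by_class("sequencing_artifact")[0]
        cand = CandidateVariant(artifact.variant, carrier_ids=list(artifact.carriers))
        assert confirm_variant(cand, small_sim.oracle) is False

    def test_missing_oracle_entry_raises(self, paper):
        cand = CandidateVariant(paper.atp1a3["E815K"], carrier_ids=["STRANGER"])
        with pytest.raises(KeyError):
            confirm_variant(cand, paper.oracle)


class TestExcludeNonCausal:
    def _paper_candidates(self, paper):
        cands = [
            CandidateVariant(paper.cntn4, carrier_ids=["II-1", "III-1", "IV-1", "VI-1", "VII-1", "VIII-1"]),
        ]
        for pchange, v in paper.syne1_novel.items():
            carrier = {"E1319K": "VII-1", "V2399A": "III-1", "M3376V": "V-1", "R8222Q": "I-1"}[pchange]
            cands.append(CandidateVariant(v, carrier_ids=[carrier]))
        carriers_of = {
            "G755C": ["I-1"], "E815K": ["II-1", "III-1", "IV-1"],
            "C927Y": ["V-1"], "D801N": ["VI-1", "VII-1", "VIII-1"],
        }
        for pchange, v in paper.atp1a3.items():
            cands.append(CandidateVariant(v, carrier_ids=carriers_of[pchange]))
        return cands

    def test_only_the_four_real_mutations_survive(self, paper):
        log = ExclusionLog()
        survivors = exclude_non_causal(
            self._paper_candidates(paper), paper.trios, paper.genotypes,
            paper.controls, paper.oracle, log,
        )
        assert {c.variant.protein_change for c in survivors} == {
            "G755C", "E815K", "D801N", "C927Y"
        }
        assert log.removed[paper.cntn4.key] is RemovalReason.confirmation_failed
        assert log.removed[paper.syne1_novel["E1319K"].key] is RemovalReason.control_carriers
        # R8222Q is absent from controls but inherited from a healthy parent
        assert log.removed[paper.syne1_novel["R8222Q"].key] is RemovalReason.inherited_in_all_carriers

    def test_all_inherited_candidate_set_is_emptied(self, paper):
        cands = [
            CandidateVariant(v, carrier_ids=[c])
            for v, c in [
                (paper.syne1_novel["R8222Q"], "I-1"),
                (paper.syne1_novel["M3376V"], "V-1"),
            ]
        ]
        controls = ControlGenotypes(["C1"])  # no carriers recorded
        assert exclude_non_causal(cands, paper.trios, paper.genotypes, controls, paper.oracle) == []

    def test_unknown_parent_only_candidate_retained_but_unvalidated(self, paper):
        v = paper.atp1a3["E815K"]
        cand = CandidateVariant(v, carrier_ids=["IX-1"])  # parents refused testing
        (survivor,) = exclude_non_causal(
            [cand], paper.trios, paper.genotypes, paper.controls, paper.oracle
        )
        assert survivor.unvalidated
        assert survivor.de_novo_status["IX-1"] is TrioClassification.unknown_parent

    def test_never_removes_confirmed_de_novo_control_free_candidate(self, small_sim):
        planted = small_sim.truth.by_class("planted_de_novo")
        cands = [
            CandidateVariant(rec.variant, carrier_ids=list(rec.carriers))
            for rec in planted
        ]
        survivors = exclude_non_causal(
            cands, small_sim.trios, small_sim.genotypes,
            small_sim.controls, small_sim.oracle,
        )
        assert {c.variant.key for c in survivors} == small_sim.truth.planted_keys()
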