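"""Codon expansion, mutation calling, classification, screening, selection."""

import pytest

from breeddiff import mutscan
from breeddiff.mutscan import (
    AaMutation,
    FrameError,
    MultiAmbiguityError,
    ReferenceAmbiguityError,
    TopologyAnnotation,
    annotate_region,
    call_aa_mutations,
    classify_mutation,
    expand_codon,
    screen_ancestral,
    select_candidates,
)
from breeddiff.seqio import PopulationPartition

from conftest import make_alignment

TWO_BREEDS = PopulationPartition(
    {"n1": "Shaver", "n2": "Shaver", "n3": "Shaver",
     "s1": "Shamo", "s2": "Shamo", "s3": "Shamo"}
)


def mut(carriers, **kw):
    defaults = dict(gene="G", aa_pos=5, ref_aa="S", alt_aa="G")
    defaults.update(kw)
    return AaMutation(carriers=dict(carriers), **defaults)


class TestExpandCodon:
    def test_unambiguous(self):
        assert expand_codon("AGC") == frozenset("S")

    def test_single_heterozygous_position(self):
        assert expand_codon("RGC") == frozenset({"S", "G"})

    def test_stop_included_as_star(self):
        assert expand_codon("TRA") == frozenset({"*"})  # TGA and TAA both stop

    def test_two_ambiguous_positions_rejected(self):
        with pytest.raises(MultiAmbiguityError):
            expand_codon("RRC")

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            expand_codon("A-C")


class TestCallAaMutations:
    def base_alignment(self, sample_codon, ref_codon="AGC"):
        # codon 2 is the variable one; codon 1 = ATG in all samples
        seqs = {
            "ref": "ATG" + ref_codon,
            "n1": "ATG" + sample_codon,
            "n2": "ATG" + ref_codon,
        }
        return make_alignment(seqs, roles={"ref": "reference"})

    def test_heterozygous_codon_called_het(self):
        aln = self.base_alignment("RGC")
        [m] = call_aa_mutations(aln, "ref")
        assert (m.aa_pos, m.ref_aa, m.alt_aa) == (2, "S", "G")
        assert m.label == "S2G"
        assert m.carriers == {"n1": "het"}

    def test_homozygous_alt_called_hom(self):
        aln = self.base_alignment("GGC")
        [m] = call_aa_mutations(aln, "ref")
        assert m.carriers == {"n1": "hom"}

    def test_no_variation_no_calls(self):
        aln = self.base_alignment("AGC")
        assert call_aa_mutations(aln, "ref") == []

    def test_synonymous_change_not_called(self):
        aln = self.base_alignment("AGT")  # AGC and AGT are both serine
        assert call_aa_mutations(aln, "ref") == []

    def test_carriers_aggregate_per_alt_residue(self):
        seqs = {"ref": "ATGAGC", "n1": "ATGRGC", "n2": "ATGGGC"}
        aln = make_alignment(seqs, roles={"ref": "reference"})
        [m] = call_aa_mutations(aln, "ref")
        assert m.carriers == {"n1": "het", "n2": "hom"}

    def test_ambiguous_reference_rejected(self):
        aln = self.base_alignment("AGC", ref_codon="RGC")
        with pytest.raises(ReferenceAmbiguityError, match="codon 2"):
            call_aa_mutations(aln, "ref")

    def test_frame_violation(self):
        aln = make_alignment({"ref": "ATGA", "n1": "ATGA"},
                             roles={"ref": "reference"})
        with pytest.raises(FrameError):
            call_aa_mutations(aln, "ref")

    def test_multi_ambiguous_sample_codon_skipped(self):
        aln = self.base_alignment("RRC")
        assert call_aa_mutations(aln, "ref") == []

    def test_every_carrier_expansion_contains_alt(self):
        seqs = {"ref": "ATGAGCAAA", "n1": "ATGRGCAAR", "n2": "ATGGGCAAA"}
        aln = make_alignment(seqs, roles={"ref": "reference"})
        for m in call_aa_mutations(aln, "ref"):
            for sample, zyg in m.carriers.items():
                codon = aln.member(sample).bases[3 * (m.aa_pos - 1):3 * m.aa_pos]
                residues = expand_codon(codon)
                assert m.alt_aa in residues
                if zyg == "hom":
                    assert residues == frozenset({m.alt_aa})


class TestClassifyMutation:
    def test_all_of_one_breed(self):
        m = mut({"n1": "het", "n2": "het", "n3": "het"})
        assert classify_mutation(m, TWO_BREEDS) == "breedA_specific"
        assert m.complete_in_breed and not m.individual_level

    def test_single_carrier_marked_individual(self):
        m = mut({"s1": "het"})
        assert classify_mutation(m, TWO_BREEDS) == "breedB_specific"
        assert m.individual_level and not m.complete_in_breed

    def test_partial_breed_keeps_specific_class(self):
        m = mut({"n1": "het", "n2": "het"})
        assert classify_mutation(m, TWO_BREEDS) == "breedA_specific"
        assert not m.individual_level and not m.complete_in_breed

    def test_both_breeds_common(self):
        m = mut({"n1": "het", "n2": "het", "s1": "het", "s2": "het", "s3": "het"})
        assert classify_mutation(m, TWO_BREEDS) == "common"

    def test_unknown_carrier_rejected(self):
        m = mut({"zz": "het"})
        with pytest.raises(ValueError, match="zz"):
            classify_mutation(m, TWO_BREEDS)

    def test_classification_exhaustive_and_exclusive(self):
        import itertools

        samples = list(TWO_BREEDS.assignment)
        for r in range(1, 4):
            for combo in itertools.combinations(samples, r):
                m = mut({s: "het" for s in combo})
                assert classify_mutation(m, TWO_BREEDS) in (
                    "breedA_specific", "breedB_specific", "common"
                )


class TestScreenAncestral:
    def outgroups(self, codon2):
        return make_alignment(
            {"og1": "ATG" + codon2}, roles={"og1": "outgroup"}
        )

    def test_alt_in_outgroup_is_ancestral(self):
        m = mut({"n1": "het"}, aa_pos=2, ref_aa="G", alt_aa="S")
        assert screen_ancestral(m, self.outgroups("AGC")) == "ancestral_present"

    def test_heterozygous_outgroup_counts(self):
        m = mut({"n1": "het"}, aa_pos=2, ref_aa="S", alt_aa="G")
        assert screen_ancestral(m, self.outgroups("RGC")) == "ancestral_present"

    def test_absent_alt_is_derived(self):
        m = mut({"n1": "het"}, aa_pos=2, ref_aa="T", alt_aa="N")
        assert screen_ancestral(m, self.outgroups("ACC")) == "derived"

    def test_uncovered_position_unscreened(self):
        m = mut({"n1": "het"}, aa_pos=2, ref_aa="S", alt_aa="G")
        assert screen_ancestral(m, self.outgroups("NNN")) == "unscreened"

    def test_dropping_outgroups_never_creates_derived(self):
        m = mut({"n1": "het"}, aa_pos=2, ref_aa="G", alt_aa="S")
        screen_ancestral(m, self.outgroups("AGC"))
        assert m.ancestry == "ancestral_present"
        screen_ancestral(m, self.outgroups("NNN"))
        assert m.ancestry == "unscreened"


class TestTopology:
    TOPO = TopologyAnnotation(
        gene="G",
        segments=((1, 30, "outside"), (31, 53, "TMhelix"), (54, 100, "inside")),
    )

    @pytest.mark.parametrize("pos,region", [(15, "outside"), (40, "TMhelix"),
                                            (60, "inside"), (150, "unannotated")])
    def test_region_lookup(self, pos, region):
        m = mut({"n1": "het"}, aa_pos=pos)
        assert annotate_region(m, self.TOPO) == region

    def test_no_annotation_is_unannotated(self):
        m = mut({"n1": "het"})
        assert annotate_region(m, None) == "unannotated"

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            TopologyAnnotation("G", ((1, 10, "inside"), (5, 20, "TMhelix")))

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            TopologyAnnotation("G", ((1, 10, "transmembrane"),))


class TestSelectCandidates:
    def classified(self, carriers, **kw):
        m = mut(carriers, **kw)
        classify_mutation(m, TWO_BREEDS)
        return m

    def test_breed_fixed_derived_tm_retained(self):
        m = self.classified({"n1": "het", "n2": "het", "n3": "het"})
        m.ancestry, m.region = "derived", "TMhelix"
        assert select_candidates([m]) == [m] and m.selected

    def test_ancestral_dropped(self):
        m = self.classified({"n1": "het", "n2": "het", "n3": "het"})
        m.ancestry, m.region = "ancestral_present", "TMhelix"
        assert select_candidates([m]) == []

    def test_extracellular_dropped(self):
        m = self.classified({"s1": "het", "s2": "het", "s3": "het"})
        m.ancestry, m.region = "derived", "outside"
        assert select_candidates([m]) == []

    def test_partial_breed_dropped_but_common_partial_kept(self):
        partial = self.classified({"n1": "het", "n2": "het"})
        partial.ancestry = "derived"
        common = self.classified({"n1": "het", "s1": "het"})
        common.ancestry = "derived"
        assert select_candidates([partial, common]) == [common]

    def test_unscreened_not_selected(self):
        m = self.classified({"n1": "het", "n2": "het", "n3": "het"})
        m.ancestry = "unscreened"
        assert select_candidates([m]) == []

    def test_stop_gain_never_selected(self):
        m = self.classified({"n1": "het", "n2": "het", "n3": "het"},
                            alt_aa="*")
        m.ancestry, m.region = "derived", "TMhelix"
        assert select_candidates([m]) == []

    def test_output_subset_of_input(self):
        muts = [
            self.classified({"n1": "het"}),
            self.classified({"n1": "het", "n2": "het", "n3": "het"}),
        ]
        for m in muts:
            m.ancestry = "derived"
        kept = select_candidates(muts)
        assert set(id(m) for m in kept) <= set(id(m) for m in muts)
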