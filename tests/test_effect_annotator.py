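"""Gene-model mapping, codon-effect computation and consistency checks."""

from itertools import product

import pytest

from orgredit.edit_caller import CandidateSite
from orgredit.effect_annotator import (
    aa_transition_counts,
    achievable_codons,
    achievable_with_coedits,
    annotate_sites,
    apply_edit,
    check_against_table,
    codon_position,
    codon_position_partition,
    locate,
    per_gene_counts,
)
from orgredit.orgdata import (
    EditSite,
    GeneModel,
    GenomeRecord,
    SiteTable,
    ValidationError,
    transcript_sequence,
)

# independent genetic-code oracle: codon -> 1-letter aa, stop as X,
# written out by hand in TCAG order (never derived from the implementation)
_ORACLE_AA = "FFLLSSSSYYXXCCXWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {
    a + b + c: _ORACLE_AA[i]
    for i, (a, b, c) in enumerate(product("TCAG", repeat=3))
}


def candidate(pos):
    return CandidateSite(
        genome_pos=pos,
        ref_base="C",
        alt_base="T",
        editing_freq=1.0,
        dna_cov=30,
        rna_cov=30,
        is_c_to_u=True,
    )


class TestLocate:
    PLUS = GeneModel(gene_id="p", strand="+", segments=((100, 199),), complete=False)
    MINUS = GeneModel(gene_id="m", strand="-", segments=((100, 199),), complete=False)
    SPLIT = GeneModel(
        gene_id="s", strand="+", segments=((100, 129), (200, 229)), complete=False
    )

    def test_plus_strand_first_base(self):
        (loc,) = locate(100, [self.PLUS])
        assert loc.position == 1

    def test_minus_strand_origin_is_rightmost_base(self):
        (loc,) = locate(199, [self.MINUS])
        assert loc.position == 1

    def test_spliced_position_counts_across_the_junction(self):
        (loc,) = locate(200, [self.SPLIT])
        assert loc.position == 31

    def test_intergenic_returns_nothing(self):
        assert locate(50, [self.PLUS, self.SPLIT]) == []

    def test_overlapping_genes_both_reported(self):
        hits = locate(150, [self.PLUS, self.MINUS])
        assert sorted(h.gene.gene_id for h in hits) == ["m", "p"]


class TestCodonPosition:
    @pytest.mark.parametrize("cds_pos, expected", [(1234, 1), (701, 2), (1722, 3)])
    def test_catalog_examples(self, cds_pos, expected):
        assert codon_position(cds_pos) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            codon_position(0)


class TestApplyEdit:
    def test_stop_gain(self):
        out = apply_edit("CGA", 1)
        assert (out.alt_codon, out.ref_aa, out.alt_aa) == ("TGA", "R", "X")
        assert out.effect == "stop_gain"

    def test_start_gain_at_codon_one(self):
        out = apply_edit("ACG", 2, codon_index=1)
        assert (out.alt_codon, out.ref_aa, out.alt_aa) == ("ATG", "T", "M")
        assert out.effect == "start_gain"

    def test_same_codon_not_first_is_plain_missense(self):
        assert apply_edit("ACG", 2, codon_index=5).effect == "missense"

    def test_synonymous_third_position(self):
        out = apply_edit("ATC", 3)
        assert (out.ref_aa, out.alt_aa) == ("I", "I")
        assert out.effect == "synonymous"

    def test_codon_without_c_is_not_editable(self):
        with pytest.raises(ValidationError, match="not editable"):
            apply_edit("ATG", 1)

    def test_agrees_with_independent_oracle_on_all_codons(self):
        """Brute force over 64 codons x 3 positions against a hand-written
        genetic code."""
        for codon, pos in product(ORACLE_CODE, (1, 2, 3)):
            if codon[pos - 1] != "C":
                continue
            out = apply_edit(codon, pos)
            alt = codon[: pos - 1] + "T" + codon[pos:]
            assert out.alt_codon == alt
            assert out.ref_aa == ORACLE_CODE[codon]
            assert out.alt_aa == ORACLE_CODE[alt]

    def test_stop_loss_is_unreachable(self):
        # no stop codon contains a C, so editing can never destroy a stop
        for codon in ORACLE_CODE:
            if ORACLE_CODE[codon] == "X":
                assert "C" not in codon


class TestAnnotateSites:
    def test_planted_stop_gain_annotates_as_stop_gain(self):
        #            start  R(CGA)  stop
        cds = "ATG" + "CGA" + "TAA"
        genome = GenomeRecord(id="g", sequence="TT" + cds + "TT")
        gene = GeneModel(gene_id="x", strand="+", segments=((3, 11),))
        result = annotate_sites([candidate(6)], genome, gene and [gene])
        (site,) = result.sites
        assert site.effect == "stop_gain"
        assert (site.ref_codon, site.alt_codon) == ("CGA", "TGA")

    def test_intergenic_candidate_reported_noncoding(self):
        genome = GenomeRecord(id="g", sequence="TTATGCGATAATT")
        gene = GeneModel(gene_id="x", strand="+", segments=((3, 11),))
        result = annotate_sites([candidate(1)], genome, [gene])
        assert len(result.sites) == 0
        assert result.noncoding[0].feature_class == "intergenic"

    def test_reference_mismatch_is_an_error(self):
        genome = GenomeRecord(id="g", sequence="TTATGCGATAATT")
        gene = GeneModel(gene_id="x", strand="+", segments=((3, 11),))
        with pytest.raises(ValidationError, match="not C"):
            annotate_sites([candidate(3)], genome, [gene])  # A, not C

    def test_full_truth_set_round_trips(self, clean_truth):
        cands = [candidate(s.genome_pos) for s in clean_truth.sites]
        result = annotate_sites(cands, clean_truth.genome, clean_truth.genes)
        report = check_against_table(result.sites, clean_truth.sites)
        assert report.ok, report.summary()

    def test_locate_agrees_with_transcript_sequence(self, clean_truth):
        """The base the transcript shows at a mapped position equals the
        strand-folded genome base, for simulated gene models."""
        comp = str.maketrans("ACGT", "TGCA")
        for gene in clean_truth.genes:
            tx = transcript_sequence(clean_truth.genome, gene)
            for tpos in range(1, len(gene) + 1, 37):
                gpos = gene.genome_position(tpos)
                base = clean_truth.genome.base(gpos)
                if gene.strand == "-":
                    base = base.translate(comp)
                assert tx[tpos - 1] == base


class TestCheckAgainstTable:
    def test_table_matches_itself(self, table1):
        report = check_against_table(table1, table1)
        assert report.n_match == 38 and report.ok

    def test_single_corrupted_row_is_flagged(self, table1):
        rows = list(table1.rows)
        bad = rows[0]
        rows[0] = EditSite(
            gene_id=bad.gene_id,
            genome_pos=bad.genome_pos,
            cds_pos=bad.cds_pos + 3,  # same codon position, wrong cds_pos
            codon_index=bad.codon_index,
            codon_position=bad.codon_position,
            ref_aa=bad.ref_aa,
            alt_aa=bad.alt_aa,
            effect=bad.effect,
            organelle=bad.organelle,
        )
        corrupted = SiteTable(rows=rows, provenance="called")
        report = check_against_table(corrupted, table1)
        assert report.n_mismatch == 1
        assert report.n_match == 37


class TestCatalogTallies:
    def test_codon_position_partition(self, table1, table2):
        assert codon_position_partition(table1, table2) == {1: 57, 2: 116, 3: 4}

    def test_mitochondrial_per_gene_counts(self, table2):
        counts = per_gene_counts(table2)
        assert counts.idxmax() == "ccmB"
        assert counts["ccmB"] == 34
        assert counts["nad5"] == 17
        assert counts["cob"] == 15
        assert counts["cox2"] == 15
        assert counts["atp4"] == 11

    def test_chloroplast_gene_structure(self, table1):
        counts = per_gene_counts(table1)
        assert counts["ndhB"] == 8
        assert counts["ndhD"] == 5
        assert counts["matK"] == 3
        assert (counts == 1).sum() == 16

    def test_transition_spectra_both_flavours(self, table2):
        with_syn = aa_transition_counts(table2, include_synonymous=True)
        without = aa_transition_counts(table2, include_synonymous=False)
        assert with_syn.sum() == 139
        assert with_syn["S→L"] > 0
        assert set(without.index) <= set(with_syn.index)
        assert "I→I" in with_syn.index and "I→I" not in without.index


class TestAchievability:
    def test_single_edit_search_agrees_with_oracle(self):
        for (ra, aa), pos in product(
            [("S", "L"), ("P", "L"), ("R", "X"), ("H", "Y"), ("P", "H")],
            (1, 2, 3),
        ):
            expected = sorted(
                codon
                for codon in ORACLE_CODE
                if codon[pos - 1] == "C"
                and ORACLE_CODE[codon] == ra
                and ORACLE_CODE[codon[: pos - 1] + "T" + codon[pos:]] == aa
            )
            assert achievable_codons(ra, aa, pos) == expected

    def test_coediting_explains_joint_codon_changes(self):
        # P->F printed for each of two edited Cs in one codon: only the
        # joint CCx -> TTx edit yields F
        assert achievable_codons("P", "F", 1) == []
        assert achievable_with_coedits("P", "F", 1, coedited_positions=[2]) == [
            "CCC",
            "CCT",
        ]
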