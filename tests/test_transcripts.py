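"""Coordinate arithmetic: genomic ↔ spliced-mRNA mapping, CDS extraction,
final-junction geometry and splice-dinucleotide indexing."""

import pytest

from pvburden.transcripts import (
    GenomeSequence,
    StructuralValidationError,
    TranscriptModel,
    reverse_complement,
)

from conftest import random_transcript_and_genome


def exon_walk(tx):
    """Brute-force enumeration of exonic genomic positions in
    transcription order — the independent oracle for coordinate mapping."""
    walk = [p for s, e in tx.exons for p in range(s, e + 1)]
    return walk if tx.strand == "+" else walk[::-1]


class TestGenomicToMrna:
    def test_first_exonic_base_plus_strand_maps_to_one(self, three_exon_plus):
        tx, _ = three_exon_plus
        assert tx.genomic_to_mrna(11) == 1

    def test_intronic_position_maps_to_none(self, three_exon_plus):
        tx, _ = three_exon_plus
        assert tx.genomic_to_mrna(25) is None
        assert tx.genomic_to_mrna(5) is None  # outside the span

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exon_walk_enumeration(self, seed):
        tx, _ = random_transcript_and_genome(seed)
        walk = exon_walk(tx)
        for i, pos in enumerate(walk, start=1):
            assert tx.genomic_to_mrna(pos) == i
        lo, hi = tx.span
        for pos in range(lo, hi + 1):
            if pos not in set(walk):
                assert tx.genomic_to_mrna(pos) is None

    @pytest.mark.parametrize("seed", range(40))
    def test_bijection_round_trip(self, seed):
        tx, _ = random_transcript_and_genome(seed)
        for m in range(1, tx.mrna_length + 1):
            assert tx.genomic_to_mrna(tx.mrna_to_genomic(m)) == m


class TestSplicedCds:
    def test_single_exon_no_splicing(self):
        genome = GenomeSequence("c", "TTATGAAATGATT")
        tx = TranscriptModel("t", "g", "c", "+", ((3, 11),), 3, 11)
        assert tx.spliced_cds(genome) == "ATGAAATGA"

    def test_minus_strand_is_reverse_complement_of_plus_extraction(self):
        genome = GenomeSequence("c", "TTATGAAATGATT")
        plus = TranscriptModel("t", "g", "c", "+", ((3, 11),), 3, 11)
        minus = TranscriptModel("t", "g", "c", "-", ((3, 11),), 3, 11)
        assert minus.spliced_cds(genome) == reverse_complement(
            plus.spliced_cds(genome)
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_per_base_extraction_oracle(self, seed):
        tx, genome = random_transcript_and_genome(seed)
        lo, hi = tx.cds_mrna_interval()
        expected = "".join(
            genome.base(tx.mrna_to_genomic(m))
            if tx.strand == "+"
            else reverse_complement(genome.base(tx.mrna_to_genomic(m)))
            for m in range(lo, hi + 1)
        )
        assert tx.spliced_cds(genome) == expected
        assert len(tx.spliced_cds(genome)) == hi - lo + 1


class TestFinalJunction:
    def test_cumulative_sum_of_exon_lengths(self):
        # exon mRNA lengths 300/200/150 -> junction at 500
        tx = TranscriptModel(
            "t", "g", "c", "+",
            ((1, 300), (401, 600), (701, 850)), 1, 850,
        )
        assert tx.final_junction_mrna() == 500

    def test_single_exon_has_no_junction(self):
        tx = TranscriptModel("t", "g", "c", "+", ((1, 300),), 1, 300)
        assert tx.final_junction_mrna() is None

    @pytest.mark.parametrize("seed", range(40))
    def test_arithmetic_oracle(self, seed):
        tx, _ = random_transcript_and_genome(seed, min_exons=2)
        last = tx.exons_tx_order()[-1]
        expected = tx.mrna_length - (last[1] - last[0] + 1)
        assert tx.final_junction_mrna() == expected
        assert tx.final_junction_mrna() < tx.mrna_length


class TestSpliceSiteIndex:
    def test_donor_and_acceptor_plus_strand(self, three_exon_plus):
        tx, _ = three_exon_plus
        assert tx.intron_index_of_splice_site(21) == (1, "donor")
        assert tx.intron_index_of_splice_site(22) == (1, "donor")
        assert tx.intron_index_of_splice_site(29) == (1, "acceptor")
        assert tx.intron_index_of_splice_site(30) == (1, "acceptor")
        assert tx.intron_index_of_splice_site(46) == (2, "donor")
        assert tx.intron_index_of_splice_site(23) is None  # 3rd intronic base

    @pytest.mark.parametrize("seed", range(30))
    def test_minus_strand_mirrors_plus_under_reverse_complement(self, seed):
        tx, _ = random_transcript_and_genome(seed, min_exons=2)
        flipped = TranscriptModel(
            tx.transcript_id, tx.gene, tx.chrom,
            "-" if tx.strand == "+" else "+",
            tx.exons, tx.cds_start, tx.cds_end,
        )
        n_introns = tx.n_exons - 1
        lo, hi = tx.span
        for pos in range(lo, hi + 1):
            got = tx.intron_index_of_splice_site(pos)
            mirrored = flipped.intron_index_of_splice_site(pos)
            if got is None:
                assert mirrored is None
            else:
                idx, kind = got
                other = "acceptor" if kind == "donor" else "donor"
                assert mirrored == (n_introns - idx + 1, other)


class TestValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(StructuralValidationError):
            TranscriptModel("t", "g", "c", "+", ((1, 10), (10, 20)), 1, 20)

    def test_abutting_exons_rejected(self):
        with pytest.raises(StructuralValidationError):
            TranscriptModel("t", "g", "c", "+", ((1, 10), (11, 20)), 1, 20)

    def test_intronic_cds_endpoint_rejected(self):
        with pytest.raises(StructuralValidationError):
            TranscriptModel("t", "g", "c", "+", ((1, 10), (20, 30)), 1, 15)

    def test_non_acgt_genome_rejected(self):
        with pytest.raises(StructuralValidationError):
            GenomeSequence("c", "ACGTN")
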