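"""Consequence calling, PTC localization and the NMD decision cascade."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pvburden.cohort import CohortVariant
from pvburden.nmd import (
    ConsequenceCall,
    EscapeOverrideList,
    InputConsistencyError,
    NMDStatus,
    call_consequence,
    classify_nmd,
    locate_ptc,
    trim_variant,
)
from pvburden.synthetic import GeneratorParams, generate_reference
from pvburden.transcripts import GenomeSequence, TranscriptModel, reverse_complement


def build_tx(mrna, exon_lens, cds_lo, cds_hi, strand="+", chrom="t"):
    """Transcript with the given spliced sequence and exon split.

    Introns are canonical 12-bp GT..AG; 5-bp flanks. ``cds_lo``/``cds_hi``
    are mRNA coordinates of the CDS endpoints.
    """
    assert sum(exon_lens) == len(mrna)
    flank, intron = 5, 12
    pieces, exons = [], []
    cursor, off = flank + 1, 0
    for i, el in enumerate(exon_lens):
        pieces.append(mrna[off : off + el])
        exons.append((cursor, cursor + el - 1))
        cursor += el
        off += el
        if i < len(exon_lens) - 1:
            pieces.append("GT" + "C" * (intron - 4) + "AG")
            cursor += intron
    seq = "A" * flank + "".join(pieces) + "A" * flank
    N = len(seq)

    def to_genomic(m):
        off = 0
        for (s, _), el in zip(exons, exon_lens):
            if m <= off + el:
                return s + (m - off - 1)
            off += el
        raise AssertionError

    gs, ge = to_genomic(cds_lo), to_genomic(cds_hi)
    if strand == "-":
        seq = reverse_complement(seq)
        exons = sorted((N - e + 1, N - s + 1) for s, e in exons)
        gs, ge = sorted((N - gs + 1, N - ge + 1))
    tx = TranscriptModel("T", "G", chrom, strand, tuple(exons), gs, ge)
    return tx, GenomeSequence(chrom, seq)


def snv(tx, genome, m, alt_tx_base):
    """SNV at mRNA position ``m`` installing a transcript-sense base."""
    gpos = tx.mrna_to_genomic(m)
    ref = genome.base(gpos)
    alt = alt_tx_base if tx.strand == "+" else reverse_complement(alt_tx_base)
    assert ref != alt
    return CohortVariant(tx.chrom, gpos, ref, alt, an_adj=1)


def deletion(tx, genome, m, length):
    """Deletion of mRNA positions m..m+length-1 (plus strand only)."""
    assert tx.strand == "+"
    a = tx.mrna_to_genomic(m) - 1
    return CohortVariant(
        tx.chrom, a, genome.slice(a, a + length), genome.base(a), an_adj=1
    )


class TestTrimVariant:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (10, "A", "G", (10, "A", "G")),
            (10, "AT", "A", (11, "T", "")),
            (10, "A", "AT", (11, "", "T")),
            (10, "ATG", "ACG", (11, "T", "C")),
            (10, "CAG", "CG", (11, "A", "")),
        ],
    )
    def test_minimal_representation(self, pos, ref, alt, expected):
        assert trim_variant(pos, ref, alt) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            trim_variant(1, "A", "A")


class TestCallConsequence:
    # spliced CDS: ATG CAA TGG ... TGA over two exons
    MRNA = "ATGCAATGGCCTGAAGGATGA"

    @pytest.fixture
    def tx_genome(self):
        return build_tx(self.MRNA, [9, 12], 1, 21)

    def test_stop_gain_is_nonsense_with_ptc_at_codon_start(self, tx_genome):
        tx, genome = tx_genome
        call = call_consequence(snv(tx, genome, 4, "T"), tx, genome)  # CAA->TAA
        assert call.category == "nonsense"
        assert call.ptc_mrna_pos == 4

    def test_synonymous_and_missense(self, tx_genome):
        tx, genome = tx_genome
        syn = call_consequence(snv(tx, genome, 6, "G"), tx, genome)  # CAA->CAG
        mis = call_consequence(snv(tx, genome, 4, "G"), tx, genome)  # CAA->GAA
        assert syn.category == "synonymous"
        assert mis.category == "missense"

    def test_single_base_deletion_is_frameshift(self, tx_genome):
        tx, genome = tx_genome
        call = call_consequence(deletion(tx, genome, 5, 1), tx, genome)
        assert call.category == "frameshift"

    def test_three_base_deletion_is_inframe(self, tx_genome):
        tx, genome = tx_genome
        call = call_consequence(deletion(tx, genome, 4, 3), tx, genome)
        assert call.category == "inframe_indel"

    def test_splice_donor_dinucleotide(self, tx_genome):
        tx, genome = tx_genome
        gpos = tx.exons[0][1] + 1  # first intronic base
        ref = genome.base(gpos)
        alt = "C" if ref != "C" else "T"
        call = call_consequence(
            CohortVariant(tx.chrom, gpos, ref, alt, an_adj=1), tx, genome
        )
        assert call.category == "splice_donor"
        assert call.intron_index == 1

    def test_deep_intronic_and_ref_mismatch(self, tx_genome):
        tx, genome = tx_genome
        gpos = tx.exons[0][1] + 4
        ref = genome.base(gpos)
        alt = "C" if ref != "C" else "T"
        call = call_consequence(
            CohortVariant(tx.chrom, gpos, ref, alt, an_adj=1), tx, genome
        )
        assert call.category == "intronic_other"
        with pytest.raises(InputConsistencyError):
            bad_ref = "G" if ref != "G" else "A"
            call_consequence(
                CohortVariant(tx.chrom, gpos, bad_ref, "T", an_adj=1), tx, genome
            )

    def test_random_snvs_agree_with_whole_cds_translation_oracle(self):
        """Category of random coding SNVs must match full mutant-CDS
        translation (independent oracle via Biopython)."""
        params = GeneratorParams(seed=5, n_genes=6)
        genomes, transcripts = generate_reference(params)
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 300:
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            genome = genomes[tx.chrom]
            cds_lo, cds_hi = tx.cds_mrna_interval()
            m = int(rng.integers(cds_lo, cds_hi + 1))
            cds = tx.spliced_cds(genome)
            i = m - cds_lo
            alt_base = "ACGT"[int(rng.integers(0, 4))]
            if alt_base == cds[i]:
                continue
            mutant_cds = cds[:i] + alt_base + cds[i + 1 :]
            ref_aa = str(Seq(cds).translate())
            mut_aa = str(Seq(mutant_cds).translate())
            if mut_aa == ref_aa:
                expected = "synonymous"
            elif "*" in mut_aa[:-1]:
                expected = "nonsense"
            else:
                expected = "missense"
            call = call_consequence(snv(tx, genome, m, alt_base), tx, genome)
            assert call.category == expected, (tx.transcript_id, m)
            if expected == "nonsense":
                assert call.ptc_mrna_pos == cds_lo + 3 * (mut_aa.index("*"))
            checked += 1


class TestLocatePtc:
    def test_frameshift_deletion_worked_example(self):
        # reference CDS ATG AAA ATA AGG TGA; deleting CDS base 4 gives
        # ATG AAA TAA ... -> PTC at codon 3 = CDS offset + 6
        mrna = "AA" + "ATGAAAATAAGGTGA" + "AAA"
        tx, genome = build_tx(mrna, [10, 10], 3, 17)
        v = deletion(tx, genome, 6, 1)  # CDS base 4 = mRNA 6
        call = call_consequence(v, tx, genome)
        assert call.category == "frameshift"
        assert locate_ptc(call, tx, genome) == 3 + 6

    def test_nonsense_ptc_is_codon_first_base(self):
        mrna = "ATGCAATGGCCTGAAGGATGA"
        tx, genome = build_tx(mrna, [9, 12], 1, 21)
        call = call_consequence(snv(tx, genome, 4, "T"), tx, genome)
        # codon k=2 -> CDS offset + 3*(k-1) + 1 = 4
        assert locate_ptc(call, tx, genome) == 4

    def test_frameshift_with_no_downstream_stop_returns_none(self):
        # after deleting base 4, shifted frame AAA AAT GAA AAA has no stop
        mrna = "ATGAAAAATGAAAAA"
        tx, genome = build_tx(mrna, [8, 7], 1, 12)
        v = deletion(tx, genome, 4, 1)
        call = call_consequence(v, tx, genome)
        assert call.category == "frameshift"
        assert locate_ptc(call, tx, genome) is None

    def test_usage_error_on_non_truncating(self):
        mrna = "ATGCAATGGCCTGAAGGATGA"
        tx, genome = build_tx(mrna, [9, 12], 1, 21)
        call = call_consequence(snv(tx, genome, 6, "G"), tx, genome)
        with pytest.raises(ValueError):
            locate_ptc(call, tx, genome)


def make_call(category, ptc=None, intron_index=None):
    return ConsequenceCall(
        chrom="c", pos=1, ref="A", alt="T", transcript_id="T",
        category=category, ptc_mrna_pos=ptc, intron_index=intron_index,
    )


class TestClassifyNmd:
    # exon mRNA lengths 300/200/150 -> final junction at 500
    TX = TranscriptModel(
        "T", "G", "c", "+", ((1, 300), (401, 600), (701, 850)), 1, 850
    )

    def test_fifty_bp_rule_boundary(self):
        far = classify_nmd(make_call("nonsense", ptc=430), self.TX)
        near = classify_nmd(make_call("nonsense", ptc=455), self.TX)
        assert (far.status, far.reason) == ("NMD_positive", "qualifying_ptc")
        assert (near.status, near.reason) == (
            "NMD_negative", "within_50bp_of_final_junction",
        )
        # distance exactly 50 escapes (inclusive window)
        edge = classify_nmd(make_call("nonsense", ptc=450), self.TX)
        assert edge.reason == "within_50bp_of_final_junction"

    def test_last_exon_ptc_escapes(self):
        res = classify_nmd(make_call("nonsense", ptc=501), self.TX)
        assert (res.status, res.reason) == ("NMD_negative", "last_exon")

    def test_final_intron_splice_escapes_others_trigger(self):
        final = classify_nmd(
            make_call("splice_acceptor", intron_index=2), self.TX
        )
        first = classify_nmd(make_call("splice_donor", intron_index=1), self.TX)
        assert (final.status, final.reason) == (
            "NMD_negative", "final_intron_splice",
        )
        assert (first.status, first.reason) == (
            "NMD_positive", "non_final_intron_splice",
        )

    def test_single_exon_transcript_escapes(self):
        tx1 = TranscriptModel("T", "G", "c", "+", ((1, 300),), 1, 300)
        res = classify_nmd(make_call("nonsense", ptc=30), tx1)
        assert (res.status, res.reason) == ("NMD_negative", "single_exon")

    def test_override_wins(self):
        overrides = EscapeOverrideList({("c", 1, "A", "T"): "PMID:1"})
        res = classify_nmd(make_call("nonsense", ptc=100), self.TX, overrides)
        assert res.reason == "experimental_escape_override"

    def test_non_truncating_and_no_ptc(self):
        assert classify_nmd(make_call("missense"), self.TX).reason == "non_truncating"
        assert classify_nmd(make_call("frameshift"), self.TX).reason == "no_ptc_found"

    def test_status_reason_consistency_enforced(self):
        with pytest.raises(ValueError):
            NMDStatus("NMD_positive", "last_exon")

    @pytest.mark.parametrize("seed", range(15))
    def test_nonsense_ptc_monotonicity(self, seed):
        """If a PTC at p triggers NMD, every PTC at p' < p does too."""
        rng = np.random.default_rng(seed)
        n_exons = int(rng.integers(2, 9))
        lens = rng.integers(30, 200, size=n_exons)
        exons, cursor = [], 1
        for ln in lens:
            exons.append((cursor, cursor + int(ln) - 1))
            cursor += int(ln) + 10
        tx = TranscriptModel(
            "T", "G", "c", "+", tuple(exons), exons[0][0], exons[-1][1]
        )
        statuses = [
            classify_nmd(make_call("nonsense", ptc=p), tx).status
            for p in range(1, tx.mrna_length + 1)
        ]
        first_negative = statuses.index("NMD_negative") if "NMD_negative" in statuses else len(statuses)
        assert all(s == "NMD_positive" for s in statuses[:first_negative])
        assert all(s == "NMD_negative" for s in statuses[first_negative:])
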