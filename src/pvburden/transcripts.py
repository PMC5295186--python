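"""Transcript models and genomic ↔ spliced-mRNA coordinate arithmetic.

Conventions used throughout the package:

* genomic positions are 1-based and inclusive (VCF convention);
* mRNA positions are 1-based in transcription direction (5'→3' of the
  transcript), so that the distance of a premature termination codon from
  the final exon–exon junction is a plain subtraction;
* minus-strand transcripts are handled by reverse complement at sequence
  extraction time only — all transcript-level logic works in transcription
  direction;
* introns are numbered 1..(n_exons − 1) in transcription direction, so the
  "final intron" is the biologically last one regardless of genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ALPHABET = frozenset("ACGT")


class StructuralValidationError(ValueError):
    """A transcript or genome violates its structural invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A,C,G,T}."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise StructuralValidationError(f"{self.chrom}: empty sequence")
        if not _ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - _ALPHABET)
            raise StructuralValidationError(
                f"{self.chrom}: non-ACGT characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """1-based base access."""
        return self.seq[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure, CDS endpoints, strand.

    ``exons`` are genomic (start, end) pairs, 1-based inclusive, sorted by
    genomic start regardless of strand. ``cds_start``/``cds_end`` are genomic
    positions with cds_start ≤ cds_end; both must be exonic.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    clinically_relevant: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise StructuralValidationError(
                f"{self.transcript_id}: strand must be '+' or '-'"
            )
        if not self.exons:
            raise StructuralValidationError(
                f"{self.transcript_id}: at least one exon required"
            )
        object.__setattr__(
            self, "exons", tuple((int(s), int(e)) for s, e in self.exons)
        )
        prev_end = None
        for s, e in self.exons:
            if s > e or s < 1:
                raise StructuralValidationError(
                    f"{self.transcript_id}: bad exon interval ({s},{e})"
                )
            if prev_end is not None and s <= prev_end + 1:
                raise StructuralValidationError(
                    f"{self.transcript_id}: exons overlap or abut "
                    f"(intron would be empty) near position {s}"
                )
            prev_end = e
        if self.cds_start > self.cds_end:
            raise StructuralValidationError(
                f"{self.transcript_id}: cds_start > cds_end"
            )
        for p in (self.cds_start, self.cds_end):
            if not self.is_exonic(p):
                raise StructuralValidationError(
                    f"{self.transcript_id}: CDS endpoint {p} is not exonic"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (reversed for the minus strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def is_intronic(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi and not self.is_exonic(pos)

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_mrna(self, pos: int) -> Optional[int]:
        """Spliced-transcript position of a genomic position, or None.

        Returns the 1-based position of ``pos`` in the spliced mRNA counted
        in transcription direction; None for intronic positions or positions
        outside the transcript span.
        """
        offset = 0
        forward_index = None
        for s, e in self.exons:
            if s <= pos <= e:
                forward_index = offset + (pos - s) + 1
                break
            offset += e - s + 1
        if forward_index is None:
            return None
        if self.strand == "+":
            return forward_index
        return self.mrna_length - forward_index + 1

    def mrna_to_genomic(self, mpos: int) -> int:
        """Inverse of :meth:`genomic_to_mrna` (raises on out-of-range)."""
        if not 1 <= mpos <= self.mrna_length:
            raise ValueError(
                f"mRNA position {mpos} outside 1..{self.mrna_length}"
            )
        forward_index = (
            mpos if self.strand == "+" else self.mrna_length - mpos + 1
        )
        offset = 0
        for s, e in self.exons:
            length = e - s + 1
            if forward_index <= offset + length:
                return s + (forward_index - offset - 1)
            offset += length
        raise AssertionError("unreachable")  # pragma: no cover

    def final_junction_mrna(self) -> Optional[int]:
        """mRNA position of the last base of the penultimate exon.

        This is the final exon–exon junction used by the 50-bp rule; None
        for single-exon transcripts, which have no junction.
        """
        if self.n_exons < 2:
            return None
        last = self.exons_tx_order()[-1]
        return self.mrna_length - (last[1] - last[0] + 1)

    # -- splice-site geometry --------------------------------------------

    def introns_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Intron (start, end) genomic intervals in transcription order."""
        gaps = [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(self.n_exons - 1)
        ]
        return tuple(gaps if self.strand == "+" else gaps[::-1])

    def intron_index_of_splice_site(
        self, pos: int
    ) -> Optional[tuple[int, str]]:
        """(intron index, 'donor'|'acceptor') for a consensus-dinucleotide
        position, else None.

        The donor dinucleotide is the first two intronic bases in
        transcription direction; the acceptor dinucleotide is the last two.
        Introns are numbered 1..(n_exons − 1) in transcription direction.
        """
        for i, (s, e) in enumerate(self.introns_tx_order(), start=1):
            if self.strand == "+":
                donor, acceptor = (s, s + 1), (e - 1, e)
            else:
                donor, acceptor = (e - 1, e), (s, s + 1)
            if pos in donor:
                return i, "donor"
            if pos in acceptor:
                return i, "acceptor"
        return None

    # -- sequence extraction ----------------------------------------------

    def spliced_mrna(self, genome: GenomeSequence) -> str:
        """Full spliced transcript sequence in transcription direction."""
        seq = "".join(genome.slice(s, e) for s, e in self.exons)
        return seq if self.strand == "+" else reverse_complement(seq)

    def cds_mrna_interval(self) -> tuple[int, int]:
        """(start, end) of the CDS in mRNA coordinates, start < end."""
        a = self.genomic_to_mrna(self.cds_start)
        b = self.genomic_to_mrna(self.cds_end)
        if a is None or b is None:  # guarded by __post_init__
            raise StructuralValidationError(
                f"{self.transcript_id}: CDS endpoint is intronic"
            )
        return (a, b) if a <= b else (b, a)

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """Coding sequence: exonic bases from cds_start to cds_end in
        transcription direction (reverse-complemented on the minus strand).
        """
        lo, hi = self.cds_mrna_interval()
        cds = self.spliced_mrna(genome)[lo - 1 : hi]
        if len(cds) < 3:
            raise StructuralValidationError(
                f"{self.transcript_id}: CDS shorter than one codon"
            )
        return cds
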