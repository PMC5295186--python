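"""Predicted nonsense-mediated decay (NMD) fate of truncating variants.

A truncating variant (nonsense, frameshift, or consensus splice-site) is
predicted to trigger NMD ("NMD_positive") unless it falls under one of the
classical escape rules: the premature termination codon (PTC) lies in the
final exon, within 50 bp upstream of the final exon–exon junction, or the
splice variant hits the consensus dinucleotide of the final intron.
Variants with published experimental evidence of NMD escape can be
overridden via an explicit list. Everything else is "NMD_negative".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.Seq import Seq

from .transcripts import GenomeSequence, TranscriptModel, reverse_complement

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

TRUNCATING = frozenset({"nonsense", "frameshift", "splice_donor", "splice_acceptor"})
SPLICE = frozenset({"splice_donor", "splice_acceptor"})

NMD_POSITIVE = "NMD_positive"
NMD_NEGATIVE = "NMD_negative"

POSITIVE_REASONS = frozenset({"qualifying_ptc", "non_final_intron_splice"})


class InputConsistencyError(ValueError):
    """Variant REF does not match the genome sequence."""


VariantKey = tuple[str, int, str, str]


def variant_key(v) -> VariantKey:
    return (v.chrom, int(v.pos), v.ref, v.alt)


@dataclass(frozen=True)
class ConsequenceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    category: str
    ptc_mrna_pos: Optional[int] = None
    intron_index: Optional[int] = None

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class NMDStatus:
    status: str
    reason: str

    def __post_init__(self) -> None:
        if (self.status == NMD_POSITIVE) != (self.reason in POSITIVE_REASONS):
            raise ValueError(
                f"inconsistent status/reason pair: {self.status}/{self.reason}"
            )


@dataclass
class EscapeOverrideList:
    """Variants with published experimental evidence of NMD escape."""

    entries: dict[VariantKey, str]

    @classmethod
    def empty(cls) -> "EscapeOverrideList":
        return cls(entries={})

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries


def trim_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation of a VCF allele pair.

    Strips the shared suffix, then the shared prefix (advancing ``pos``).
    Either returned allele may be empty: empty ref = pure insertion before
    ``pos``; empty alt = pure deletion of pos..pos+len(ref)-1.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical")
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _check_ref(v, genome: GenomeSequence) -> None:
    observed = genome.slice(v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise InputConsistencyError(
            f"{v.chrom}:{v.pos} REF={v.ref} but genome has {observed}"
        )


def _splice_hit(
    tx: TranscriptModel, tpos: int, tref: str, talt: str
) -> Optional[tuple[int, str]]:
    """Splice dinucleotide hit for a trimmed variant, or None."""
    if tref:  # SNV / deletion / delins: genomic footprint tpos..tpos+len-1
        for p in range(tpos, tpos + len(tref)):
            hit = tx.intron_index_of_splice_site(p)
            if hit is not None:
                return hit
        return None
    # pure insertion between tpos-1 and tpos: disruptive only if it falls
    # strictly between the two bases of one dinucleotide
    h1 = tx.intron_index_of_splice_site(tpos - 1)
    h2 = tx.intron_index_of_splice_site(tpos)
    if h1 is not None and h1 == h2:
        return h1
    return None


def _insertion_junction(tx: TranscriptModel, tpos: int) -> Optional[int]:
    """mRNA coordinate after which an insertion at genomic ``tpos`` lands.

    Returns j such that the inserted block sits between mRNA positions j and
    j+1; None when the insertion point is not flanked by exonic sequence on
    the transcription-upstream side.
    """
    flank = tpos - 1 if tx.strand == "+" else tpos
    return tx.genomic_to_mrna(flank)


def call_consequence(v, tx: TranscriptModel, genome: GenomeSequence) -> ConsequenceCall:
    """Assign a molecular consequence of a variant on one transcript.

    SNVs inside the CDS are classified by translating the affected codon of
    the mutant CDS; indels by net length modulo 3; positions hitting a
    consensus splice dinucleotide take the splice category (which dominates
    exonic categories for indels spanning a boundary).
    """
    _check_ref(v, genome)
    tpos, tref, talt = trim_variant(v.pos, v.ref, v.alt)
    base = dict(
        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
        transcript_id=tx.transcript_id,
    )

    hit = _splice_hit(tx, tpos, tref, talt)
    if hit is not None:
        idx, kind = hit
        return ConsequenceCall(
            **base, category=f"splice_{kind}", intron_index=idx
        )

    cds_lo, cds_hi = tx.cds_mrna_interval()

    if len(tref) == 1 and len(talt) == 1:  # SNV
        m = tx.genomic_to_mrna(tpos)
        if m is None:
            cat = "intronic_other" if tx.is_intronic(tpos) else "other"
            return ConsequenceCall(**base, category=cat)
        if not cds_lo <= m <= cds_hi:
            return ConsequenceCall(**base, category="other")
        cds = tx.spliced_cds(genome)
        ci = (m - cds_lo) // 3
        within = (m - cds_lo) % 3
        codon = cds[3 * ci : 3 * ci + 3]
        if len(codon) < 3:  # truncated terminal codon; malformed CDS
            return ConsequenceCall(**base, category="other")
        alt_base = talt if tx.strand == "+" else reverse_complement(talt)
        mutant = codon[:within] + alt_base + codon[within + 1 :]
        if mutant in STOP_CODONS:
            return ConsequenceCall(
                **base, category="nonsense", ptc_mrna_pos=cds_lo + 3 * ci
            )
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutant).translate())
        cat = "synonymous" if ref_aa == alt_aa else "missense"
        return ConsequenceCall(**base, category=cat)

    # indel / delins
    if tref:
        coords = [tx.genomic_to_mrna(p) for p in range(tpos, tpos + len(tref))]
        exonic = [c for c in coords if c is not None]
        in_cds = any(cds_lo <= c <= cds_hi for c in exonic)
        if not exonic:
            cat = "intronic_other" if tx.is_intronic(tpos) else "other"
            return ConsequenceCall(**base, category=cat)
    else:
        j = _insertion_junction(tx, tpos)
        if j is None:
            cat = "intronic_other" if tx.is_intronic(tpos) else "other"
            return ConsequenceCall(**base, category=cat)
        in_cds = cds_lo <= j < cds_hi
    if not in_cds:
        return ConsequenceCall(**base, category="other")
    net = len(talt) - len(tref)
    cat = "frameshift" if net % 3 != 0 else "inframe_indel"
    return ConsequenceCall(**base, category=cat)


def _mutant_mrna_edit(
    v, tx: TranscriptModel, genome: GenomeSequence
) -> tuple[str, int, int, int]:
    """Apply a trimmed exonic edit to the spliced mRNA.

    Returns (mutant mRNA, edit_start, n_del, n_ins) with edit_start the
    first affected mutant coordinate (see :func:`map_back_mrna`). Intronic
    bases of a deletion footprint are ignored (splice disruption is handled
    by the splice category upstream).
    """
    R = tx.spliced_mrna(genome)
    tpos, tref, talt = trim_variant(v.pos, v.ref, v.alt)
    if tref:
        coords = sorted(
            c
            for p in range(tpos, tpos + len(tref))
            if (c := tx.genomic_to_mrna(p)) is not None
        )
        d, k = coords[0], len(coords)
    else:
        j = _insertion_junction(tx, tpos)
        if j is None:
            raise ValueError("insertion point not exonic")
        d, k = j + 1, 0
    ins = talt if tx.strand == "+" else reverse_complement(talt)
    mutant = R[: d - 1] + ins + R[d - 1 + k :]
    return mutant, d, k, len(ins)


def locate_ptc(
    call: ConsequenceCall, tx: TranscriptModel, genome: GenomeSequence
) -> Optional[int]:
    """Spliced-mRNA position of the first base of the PTC.

    Nonsense: the variant-created stop codon. Frameshift: the mutant spliced
    transcript is rebuilt, translation proceeds from the first altered codon
    in the shifted frame through the transcript end, and the first stop's
    position is reported in mutant-transcript coordinates — these coincide
    with reference coordinates upstream of the edit, and for the 1–2 bp
    indels seen in practice differ by at most the indel length downstream of
    it. None when no stop occurs before the transcript end.
    """
    if call.category == "nonsense":
        return call.ptc_mrna_pos
    if call.category != "frameshift":
        raise ValueError(f"locate_ptc on non-truncating category {call.category}")
    mutant, d, n_del, n_ins = _mutant_mrna_edit(call, tx, genome)
    cds_lo, _ = tx.cds_mrna_interval()
    scan = cds_lo + 3 * max(0, (d - cds_lo) // 3)
    for i in range(scan - 1, len(mutant) - 2, 3):
        if mutant[i : i + 3] in STOP_CODONS:
            return i + 1
    return None


def classify_nmd(
    call: ConsequenceCall,
    tx: TranscriptModel,
    overrides: Optional[EscapeOverrideList] = None,
    escape_window: int = 50,
) -> NMDStatus:
    """Decision cascade for predicted NMD fate.

    Order: experimental-escape override; splice variants (final intron
    escapes, all others trigger); non-truncating categories; single-exon
    transcripts; no PTC; PTC in the final exon; PTC within ``escape_window``
    bp (inclusive, default 50) of the final junction; else NMD_positive.
    """
    if overrides is not None and call.key in overrides:
        return NMDStatus(NMD_NEGATIVE, "experimental_escape_override")
    if call.category in SPLICE:
        if call.intron_index == tx.n_exons - 1:
            return NMDStatus(NMD_NEGATIVE, "final_intron_splice")
        return NMDStatus(NMD_POSITIVE, "non_final_intron_splice")
    if call.category not in TRUNCATING:
        return NMDStatus(NMD_NEGATIVE, "non_truncating")
    if tx.n_exons == 1:
        return NMDStatus(NMD_NEGATIVE, "single_exon")
    ptc = call.ptc_mrna_pos
    if ptc is None:
        return NMDStatus(NMD_NEGATIVE, "no_ptc_found")
    junction = tx.final_junction_mrna()
    assert junction is not None
    if ptc > junction:
        return NMDStatus(NMD_NEGATIVE, "last_exon")
    if junction - ptc <= escape_window:
        return NMDStatus(NMD_NEGATIVE, "within_50bp_of_final_junction")
    return NMDStatus(NMD_POSITIVE, "qualifying_ptc")


def annotate_variants(
    variants: Iterable,
    transcripts: Iterable[TranscriptModel],
    genomes: Mapping[str, GenomeSequence],
    overrides: Optional[EscapeOverrideList] = None,
    escape_window: int = 50,
) -> pd.DataFrame:
    """Annotate variants against the clinically relevant transcripts.

    Each variant is assigned to the clinically relevant transcript whose
    span contains it; variants mapping to none are dropped with a logged
    warning. Returns one row per variant with consequence category, PTC
    position, NMD status and reason.
    """
    index = [t for t in transcripts if t.clinically_relevant]
    rows = []
    n_dropped = 0
    for v in variants:
        tx = next(
            (
                t
                for t in index
                if t.chrom == v.chrom and t.span[0] <= v.pos <= t.span[1]
            ),
            None,
        )
        if tx is None:
            n_dropped += 1
            logger.warning(
                "variant %s:%d %s>%s maps to no clinically relevant "
                "transcript; dropped",
                v.chrom, v.pos, v.ref, v.alt,
            )
            continue
        call = call_consequence(v, tx, genomes[v.chrom])
        if call.category == "frameshift":
            call = ConsequenceCall(
                **{**call.__dict__, "ptc_mrna_pos": locate_ptc(call, tx, genomes[v.chrom])}
            )
        status = classify_nmd(call, tx, overrides, escape_window=escape_window)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": tx.gene,
                "transcript_id": tx.transcript_id,
                "category": call.category,
                "ptc_mrna_pos": call.ptc_mrna_pos,
                "intron_index": call.intron_index,
                "nmd_status": status.status,
                "nmd_reason": status.reason,
            }
        )
    if n_dropped:
        logger.warning("%d variant(s) dropped: no clinically relevant transcript", n_dropped)
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "transcript_id",
            "category", "ptc_mrna_pos", "intron_index", "nmd_status", "nmd_reason",
        ],
    )
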