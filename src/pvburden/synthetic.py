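"""Synthetic genomes, cohorts, submissions and publication counts.

The generator emits a miniature population-cohort world with known ground
truth: random multi-exon genes with valid ORFs and canonical GT..AG introns,
a cohort VCF whose pathogenic truncating variants follow the empirical
frequency profile of well-studied disease genes (≈85% absent from the
cohort, ≈75% of the observed ones singletons, a handful of planted founder
alleles at AC > 3), benign variants spanning a broad frequency range,
per-site total allele numbers centred near 121,000 with a minority of
shallow (<80,000) and non-PASS records, ClinVar-style submission tables and
per-variant publication counts with a planted MAF–publication correlation
for pathogenic variants.

Ground-truth NMD fate is computed by :func:`oracle_nmd_status`, a
full-reconstruction oracle (mutate the chromosome, shift the exon
coordinates, splice, translate with Biopython, apply the escape rules
literally) that is independent of the production classifier in
:mod:`pvburden.nmd`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .cohort import CohortVariant
from .consensus import SubmissionRecord
from .nmd import (
    NMD_NEGATIVE,
    NMD_POSITIVE,
    NMDStatus,
    trim_variant,
)
from .stats import PublicationRecord
from .transcripts import GenomeSequence, TranscriptModel, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class ParameterError(ValueError):
    """Generator parameters are infeasible or inconsistent."""


@dataclass
class GeneratorParams:
    """Stated world for the synthetic cohort.

    Frequency-profile defaults follow the empirical profile of pathogenic
    variants in intensively tested loss-of-function genes: 85.3% absent from
    the cohort, 74.8% of observed variants seen in a single individual, 14
    founder/recurrent alleles at allele counts between 4 and 40, per-site
    total allele number near 121,000 with a small fraction of shallow loci.
    """

    seed: int = 0
    # reference
    n_genes: int = 12
    exon_count_range: tuple[int, int] = (1, 12)
    exon_length_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (60, 400)
    utr5_range: tuple[int, int] = (3, 40)
    utr3_range: tuple[int, int] = (3, 40)
    flank: int = 100
    # cohort composition
    n_pathogenic: int = 500
    n_escapers: int = 60
    n_background: int = 240
    founder_count: int = 14
    founder_ac_range: tuple[int, int] = (4, 40)
    absent_fraction: float = 0.853
    singleton_fraction: float = 0.748
    an_mean: float = 121_000.0
    an_sd: float = 6_000.0
    an_floor_fraction: float = 0.05
    non_pass_fraction: float = 0.05
    # submissions
    trusted_submitters: tuple[str, ...] = (
        "Alpha Diagnostics",
        "Beta Genetics",
        "Gamma Labs",
        "Delta Clinical",
        "Epsilon Genomics",
    )
    untrusted_submitters: tuple[str, ...] = ("CrowdLab",)
    max_submitters_per_variant: int = 4
    conflict_rate: float = 0.05
    # publications
    pathogenic_pub_base: float = 20.0
    pathogenic_pub_maf_exponent: float = 0.35
    pathogenic_pub_dispersion: float = 1.5
    benign_zero_fraction: float = 0.47
    benign_pub_mean: float = 3.0

    def __post_init__(self) -> None:
        for name in ("absent_fraction", "singleton_fraction",
                     "an_floor_fraction", "non_pass_fraction",
                     "conflict_rate", "benign_zero_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name}={val} outside [0, 1]")
        for name in ("exon_count_range", "exon_length_range",
                     "intron_length_range", "founder_ac_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ParameterError(f"{name}=({lo},{hi}) is degenerate")
        if self.founder_count > self.n_pathogenic:
            raise ParameterError(
                "more founders requested than pathogenic variants"
            )
        if self.founder_ac_range[0] <= 3:
            raise ParameterError("founder alleles must have AC > 3")
        if self.exon_length_range[0] < 20:
            raise ParameterError("exons shorter than 20 bp unsupported")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_gene(
    rng: np.random.Generator, params: GeneratorParams, idx: int
) -> tuple[GenomeSequence, TranscriptModel]:
    """One gene on its own chromosome.

    Built in transcription direction (valid ORF, GT..AG introns, stop codon
    and entire 3' UTR inside the final exon) then mirrored onto the minus
    strand for half the genes.
    """
    n_exons = int(rng.integers(*params.exon_count_range, endpoint=True))
    exon_lens = rng.integers(
        *params.exon_length_range, size=n_exons, endpoint=True
    ).tolist()
    intron_lens = rng.integers(
        *params.intron_length_range, size=max(n_exons - 1, 0), endpoint=True
    ).tolist()
    L = sum(exon_lens)
    utr3 = int(
        rng.integers(
            params.utr3_range[0],
            min(params.utr3_range[1], exon_lens[-1] - 6),
            endpoint=True,
        )
    )
    utr5 = int(rng.integers(*params.utr5_range, endpoint=True))
    utr5 += (L - utr5 - utr3) % 3  # keep the CDS length a codon multiple
    cds_len = L - utr5 - utr3
    if cds_len < 9:
        raise ParameterError("length constraints leave no room for a CDS")
    n_internal = cds_len // 3 - 2
    cds = (
        "ATG"
        + "".join(
            np.asarray(_NON_STOP_CODONS)[
                rng.integers(0, len(_NON_STOP_CODONS), size=n_internal)
            ]
        )
        + _STOPS[rng.integers(0, 3)]
    )
    mrna = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)

    # lay out exons/introns in transcription direction
    pieces, exon_coords = [], []
    cursor = params.flank + 1
    offset = 0
    for i, elen in enumerate(exon_lens):
        pieces.append(mrna[offset : offset + elen])
        exon_coords.append((cursor, cursor + elen - 1))
        cursor += elen
        offset += elen
        if i < n_exons - 1:
            ilen = intron_lens[i]
            pieces.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            cursor += ilen
    gene_seq = (
        _random_seq(rng, params.flank)
        + "".join(pieces)
        + _random_seq(rng, params.flank)
    )
    N = len(gene_seq)

    def tx_to_genomic(mpos: int) -> int:
        off = 0
        for (s, e), elen in zip(exon_coords, exon_lens):
            if mpos <= off + elen:
                return s + (mpos - off - 1)
            off += elen
        raise AssertionError  # pragma: no cover

    g_cds_start = tx_to_genomic(utr5 + 1)
    g_cds_end = tx_to_genomic(utr5 + cds_len)

    strand = "+" if idx % 2 == 0 else "-"
    chrom = f"chr{idx + 1}"
    if strand == "-":
        gene_seq = reverse_complement(gene_seq)
        exon_coords = sorted(
            (N - e + 1, N - s + 1) for s, e in exon_coords
        )
        g_cds_start, g_cds_end = sorted(
            (N - g_cds_start + 1, N - g_cds_end + 1)
        )
    genome = GenomeSequence(chrom, gene_seq)
    tx = TranscriptModel(
        transcript_id=f"TX{idx + 1:03d}.1",
        gene=f"GENE{idx + 1:02d}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exon_coords),
        cds_start=g_cds_start,
        cds_end=g_cds_end,
    )
    # by-construction sanity: exactly one stop, at the end
    aa = str(Seq(tx.spliced_cds(genome)).translate())
    assert aa.count("*") == 1 and aa.endswith("*"), "invalid generated ORF"
    return genome, tx


def generate_reference(
    params: GeneratorParams,
) -> tuple[dict[str, GenomeSequence], list[TranscriptModel]]:
    """Random genes with valid ORFs, one per chromosome, both strands."""
    rng = np.random.default_rng(params.seed)
    genomes: dict[str, GenomeSequence] = {}
    transcripts: list[TranscriptModel] = []
    for i in range(params.n_genes):
        genome, tx = _random_gene(rng, params, i)
        genomes[genome.chrom] = genome
        transcripts.append(tx)
    return genomes, transcripts


# ---------------------------------------------------------------------------
# independent NMD oracle
# ---------------------------------------------------------------------------

def _splice_dinucleotides(tx: TranscriptModel) -> dict[int, tuple[int, ...]]:
    """intron index (transcription order) → its four dinucleotide positions."""
    out = {}
    for i, (s, e) in enumerate(tx.introns_tx_order(), start=1):
        out[i] = (s, s + 1, e - 1, e)
    return out


def oracle_nmd_status(
    variant, tx: TranscriptModel, genome: GenomeSequence, overrides=None
) -> NMDStatus:
    """Brute-force NMD fate by full mutant-transcript reconstruction.

    The chromosome is mutated, exon and CDS coordinates are shifted across
    the edit, the mutant transcript is spliced and translated from the start
    codon with Biopython, and the escape rules are applied literally to the
    first premature stop found. Splice-dinucleotide membership is recomputed
    directly from the intron intervals.
    """
    if overrides is not None and (
        (variant.chrom, int(variant.pos), variant.ref, variant.alt) in overrides
    ):
        return NMDStatus(NMD_NEGATIVE, "experimental_escape_override")

    tpos, tref, talt = trim_variant(variant.pos, variant.ref, variant.alt)
    footprint = set(range(tpos, tpos + len(tref)))

    # literal splice-dinucleotide rule
    n_introns = tx.n_exons - 1
    for idx, dinucs in _splice_dinucleotides(tx).items():
        hit = bool(footprint & set(dinucs))
        if not hit and not tref:
            # pure insertion strictly between the two bases of a pair
            hit = (tpos - 1, tpos) in ((dinucs[0], dinucs[1]), (dinucs[2], dinucs[3]))
        if hit:
            if idx == n_introns:
                return NMDStatus(NMD_NEGATIVE, "final_intron_splice")
            return NMDStatus(NMD_POSITIVE, "non_final_intron_splice")

    # full reconstruction
    seq = genome.seq
    mutant_seq = seq[: tpos - 1] + talt + seq[tpos - 1 + len(tref) :]
    net = len(talt) - len(tref)
    edit_lo, edit_hi = tpos, tpos + len(tref) - 1  # replaced genomic interval

    def shift(c: int) -> int:
        if c < edit_lo:
            return c
        if c > edit_hi:
            return c + net
        return edit_lo  # boundary inside the replaced block (exonic edits only)

    new_exons = tuple((shift(s), shift(e)) for s, e in tx.exons)
    mutant_tx = TranscriptModel(
        transcript_id=tx.transcript_id,
        gene=tx.gene,
        chrom=tx.chrom,
        strand=tx.strand,
        exons=new_exons,
        cds_start=shift(tx.cds_start),
        cds_end=shift(tx.cds_end),
        clinically_relevant=tx.clinically_relevant,
    )
    mutant_genome = GenomeSequence(genome.chrom, mutant_seq)
    M = mutant_tx.spliced_mrna(mutant_genome)
    cds_lo_mut = min(
        mutant_tx.genomic_to_mrna(mutant_tx.cds_start),
        mutant_tx.genomic_to_mrna(mutant_tx.cds_end),
    )
    tail = M[cds_lo_mut - 1 :]
    tail = tail[: len(tail) - len(tail) % 3]
    aa = str(Seq(tail).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        return NMDStatus(NMD_NEGATIVE, "no_ptc_found")
    p = cds_lo_mut + 3 * stop_idx  # stop first base, mutant mRNA coords

    # where the *normal* stop sits in mutant coordinates: shifted by the
    # mRNA net length change when the (exonic) edit starts upstream of it
    ref_coords = sorted(
        c for p_ in footprint if (c := tx.genomic_to_mrna(p_)) is not None
    )
    if ref_coords:
        d = ref_coords[0]
    elif not tref:
        flank = tpos - 1 if tx.strand == "+" else tpos
        j = tx.genomic_to_mrna(flank)
        d = None if j is None else j + 1
    else:
        d = None
    cds_lo_ref, cds_hi_ref = tx.cds_mrna_interval()
    normal_stop = cds_hi_ref - 2
    if d is not None and d <= normal_stop:
        normal_stop += len(talt) - len(ref_coords)
    if p >= normal_stop:
        return NMDStatus(NMD_NEGATIVE, "no_ptc_found")  # normal stop reached

    if tx.n_exons == 1:
        return NMDStatus(NMD_NEGATIVE, "single_exon")
    junction = tx.final_junction_mrna()
    if p > junction:
        return NMDStatus(NMD_NEGATIVE, "last_exon")
    if junction - p <= 50:
        return NMDStatus(NMD_NEGATIVE, "within_50bp_of_final_junction")
    return NMDStatus(NMD_POSITIVE, "qualifying_ptc")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class _Candidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    category: str
    status: NMDStatus


def _make_nonsense(rng, tx, genome, near_end: bool) -> Optional[_Candidate]:
    cds_lo, cds_hi = tx.cds_mrna_interval()
    n_codons = (cds_hi - cds_lo + 1) // 3
    if n_codons < 4:
        return None
    if near_end:
        ci = int(rng.integers(max(1, n_codons - 40), n_codons - 1))
    else:
        ci = int(rng.integers(1, n_codons - 1))
    within = int(rng.integers(0, 3))
    m = cds_lo + 3 * ci + within
    cds = tx.spliced_cds(genome)
    codon = cds[3 * ci : 3 * ci + 3]
    choices = []
    for b in "ACGT":
        if b == codon[within]:
            continue
        if codon[:within] + b + codon[within + 1 :] in _STOPS:
            choices.append(b)
    if not choices:
        return None
    alt_tx = choices[int(rng.integers(0, len(choices)))]
    gpos = tx.mrna_to_genomic(m)
    ref = genome.base(gpos)
    alt = alt_tx if tx.strand == "+" else reverse_complement(alt_tx)
    return _Candidate(tx.chrom, gpos, ref, alt, tx.gene, "nonsense", None)


def _exonic_run(tx, m: int, length: int) -> Optional[list[int]]:
    """Genomic coords of mRNA positions m..m+length-1 if one exon, else None."""
    try:
        g = [tx.mrna_to_genomic(m + i) for i in range(length)]
    except ValueError:
        return None
    g_sorted = sorted(g)
    if g_sorted[-1] - g_sorted[0] != length - 1:
        return None
    return g_sorted


def _make_frameshift(rng, tx, genome, near_end: bool) -> Optional[_Candidate]:
    cds_lo, cds_hi = tx.cds_mrna_interval()
    if near_end:
        lo = max(cds_lo + 3, cds_hi - 120)
    else:
        lo = cds_lo + 3
    hi = cds_hi - 6
    if hi <= lo:
        return None
    m = int(rng.integers(lo, hi))
    if rng.random() < 0.6:  # deletion of 1-2 bases
        dlen = int(rng.integers(1, 3))
        run = _exonic_run(tx, m, dlen)
        if run is None:
            return None
        a = run[0] - 1
        if a < 1 or tx.genomic_to_mrna(a) is None:
            return None
        ref = genome.slice(a, a + dlen)
        alt = ref[0]
        return _Candidate(tx.chrom, a, ref, alt, tx.gene, "frameshift", None)
    ilen = int(rng.integers(1, 3))
    run = _exonic_run(tx, m, 2)  # anchor and next base in the same exon
    if run is None:
        return None
    a = run[0]
    ref = genome.base(a)
    alt = ref + _random_seq(rng, ilen)
    return _Candidate(tx.chrom, a, ref, alt, tx.gene, "frameshift", None)


def _make_splice(rng, tx, genome, final_intron: bool) -> Optional[_Candidate]:
    n_introns = tx.n_exons - 1
    if n_introns == 0:
        return None
    idx = n_introns if final_intron else int(rng.integers(1, n_introns + 1))
    s, e = tx.introns_tx_order()[idx - 1]
    positions = (s, s + 1, e - 1, e)
    gpos = int(positions[rng.integers(0, 4)])
    ref = genome.base(gpos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    kind = "splice"
    return _Candidate(tx.chrom, gpos, ref, alt, tx.gene, kind, None)


def _make_background(rng, tx, genome) -> Optional[_Candidate]:
    cds_lo, cds_hi = tx.cds_mrna_interval()
    n_codons = (cds_hi - cds_lo + 1) // 3
    ci = int(rng.integers(1, n_codons - 1))
    within = int(rng.integers(0, 3))
    m = cds_lo + 3 * ci + within
    cds = tx.spliced_cds(genome)
    codon = cds[3 * ci : 3 * ci + 3]
    choices = [
        b
        for b in "ACGT"
        if b != codon[within]
        and codon[:within] + b + codon[within + 1 :] not in _STOPS
    ]
    if not choices:
        return None
    alt_tx = choices[int(rng.integers(0, len(choices)))]
    mutant = codon[:within] + alt_tx + codon[within + 1 :]
    cat = (
        "synonymous"
        if str(Seq(codon).translate()) == str(Seq(mutant).translate())
        else "missense"
    )
    gpos = tx.mrna_to_genomic(m)
    ref = genome.base(gpos)
    alt = alt_tx if tx.strand == "+" else reverse_complement(alt_tx)
    return _Candidate(tx.chrom, gpos, ref, alt, tx.gene, cat, None)


def _draw_an(rng, params: GeneratorParams, allow_shallow: bool = True) -> int:
    if allow_shallow and rng.random() < params.an_floor_fraction:
        return int(rng.integers(40_000, 80_000))
    an = int(round(rng.normal(params.an_mean, params.an_sd)))
    return max(80_000, min(an, 135_000))


def generate_cohort(
    transcripts: list[TranscriptModel],
    genomes: dict[str, GenomeSequence],
    params: GeneratorParams,
) -> tuple[list[CohortVariant], pd.DataFrame]:
    """Plant variants with ground-truth classes and cohort frequencies.

    Pathogenic variants are truncating variants the oracle calls
    NMD_positive; "escapers" are truncating variants the oracle calls
    NMD_negative (benign-like, since loss of function is not expected);
    background variants are missense/synonymous SNVs. Exactly
    ``founder_count`` pathogenic variants are planted with AC > 3 at
    well-genotyped PASS loci; remaining pathogenic ACs follow the
    absent/singleton profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    multi = [t for t in transcripts if t.n_exons >= 2]
    if not multi:
        raise ParameterError("need at least one multi-exon transcript")

    seen: set[tuple] = set()
    pos_pool: list[_Candidate] = []
    neg_pool: list[_Candidate] = []
    attempts = 0
    max_attempts = 400 * (params.n_pathogenic + params.n_escapers + 10)
    while (
        len(pos_pool) < params.n_pathogenic
        or len(neg_pool) < params.n_escapers
    ):
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "could not plant the requested truncating variants; "
                "relax the length/count parameters"
            )
        need_escaper = len(neg_pool) < params.n_escapers and (
            len(pos_pool) >= params.n_pathogenic or rng.random() < 0.3
        )
        pool = multi if not need_escaper else transcripts
        tx = pool[int(rng.integers(0, len(pool)))]
        genome = genomes[tx.chrom]
        u = rng.random()
        if u < 0.45:
            cand = _make_nonsense(rng, tx, genome, near_end=need_escaper)
        elif u < 0.80:
            cand = _make_frameshift(rng, tx, genome, near_end=need_escaper)
        else:
            cand = _make_splice(rng, tx, genome, final_intron=need_escaper)
        if cand is None:
            continue
        key = (cand.chrom, cand.pos, cand.ref, cand.alt)
        if key in seen:
            continue
        status = oracle_nmd_status(cand, tx, genome)
        cand.status = status
        if status.status == NMD_POSITIVE:
            if len(pos_pool) < params.n_pathogenic:
                seen.add(key)
                pos_pool.append(cand)
        else:
            if len(neg_pool) < params.n_escapers:
                seen.add(key)
                neg_pool.append(cand)

    bg_pool: list[_Candidate] = []
    while len(bg_pool) < params.n_background:
        tx = transcripts[int(rng.integers(0, len(transcripts)))]
        cand = _make_background(rng, tx, genomes[tx.chrom])
        if cand is None:
            continue
        key = (cand.chrom, cand.pos, cand.ref, cand.alt)
        if key in seen:
            continue
        seen.add(key)
        cand.status = oracle_nmd_status(cand, tx, genomes[tx.chrom])
        bg_pool.append(cand)

    founder_idx = set(
        rng.choice(len(pos_pool), size=params.founder_count, replace=False).tolist()
    )

    variants: list[CohortVariant] = []
    rows: list[dict] = []

    def emit(cand: _Candidate, true_class: str, ac: int, an: int,
             filt: str, founder: bool) -> None:
        v = CohortVariant(
            chrom=cand.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
            filter_status=filt, ac_adj=ac, an_adj=an, gene=cand.gene,
        )
        variants.append(v)
        rows.append(
            {
                "chrom": cand.chrom, "pos": cand.pos, "ref": cand.ref,
                "alt": cand.alt, "gene": cand.gene,
                "true_class": true_class,
                "true_category": cand.category,
                "true_nmd_status": cand.status.status,
                "true_nmd_reason": cand.status.reason,
                "planted_founder": founder,
                "ac_adj": ac, "an_adj": an, "filter_status": filt,
            }
        )

    for i, cand in enumerate(pos_pool):
        if i in founder_idx:
            ac = int(rng.integers(*params.founder_ac_range, endpoint=True))
            an = _draw_an(rng, params, allow_shallow=False)
            emit(cand, "pathogenic", ac, an, "PASS", True)
            continue
        if rng.random() < params.absent_fraction:
            ac = 0
        elif rng.random() < params.singleton_fraction:
            ac = 1
        else:
            ac = int(rng.integers(2, 4))
        an = _draw_an(rng, params)
        filt = (
            "LOW_QUAL" if rng.random() < params.non_pass_fraction else "PASS"
        )
        emit(cand, "pathogenic", ac, an, filt, False)

    for cand, cls_pool in ((c, "benign_lof_escape") for c in neg_pool):
        an = _draw_an(rng, params)
        maf = 10 ** rng.uniform(-5, np.log10(5e-3))
        ac = max(1, int(round(maf * an)))
        filt = "LOW_QUAL" if rng.random() < params.non_pass_fraction else "PASS"
        emit(cand, cls_pool, ac, an, filt, False)

    for cand in bg_pool:
        an = _draw_an(rng, params)
        maf = 10 ** rng.uniform(-5, np.log10(5e-2))
        ac = max(1, int(round(maf * an)))
        filt = "LOW_QUAL" if rng.random() < params.non_pass_fraction else "PASS"
        emit(cand, "background", ac, an, filt, False)

    order = sorted(range(len(variants)), key=lambda i: (
        variants[i].chrom, variants[i].pos, variants[i].ref, variants[i].alt
    ))
    variants = [variants[i] for i in order]
    manifest = pd.DataFrame([rows[i] for i in order])
    return variants, manifest


# ---------------------------------------------------------------------------
# submissions & publications
# ---------------------------------------------------------------------------

def generate_submissions(
    manifest: pd.DataFrame, params: GeneratorParams
) -> list[SubmissionRecord]:
    """ClinVar-style assertion table over the planted variants.

    Pathogenic variants receive 0–max trusted P/LP assertions, with a small
    configurable chance that one assertion is a VUS (creating a conflict);
    benign-class variants receive B/LB assertions similarly. An untrusted
    submitter occasionally chimes in.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    if not params.trusted_submitters:
        return []
    records: list[SubmissionRecord] = []
    kmax = min(params.max_submitters_per_variant, len(params.trusted_submitters))
    for row in manifest.itertuples(index=False):
        n_sub = int(rng.integers(0, kmax + 1))
        subs = rng.choice(
            params.trusted_submitters, size=n_sub, replace=False
        ).tolist()
        pathogenic = row.true_class == "pathogenic"
        labels = ("P", "LP") if pathogenic else ("B", "LB")
        for i, sub in enumerate(subs):
            cls = labels[int(rng.integers(0, 2))]
            if i == 0 and n_sub >= 2 and rng.random() < params.conflict_rate:
                cls = "VUS"
            records.append(
                SubmissionRecord(
                    chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                    alt=row.alt, submitter=str(sub), classification=cls,
                    gene=row.gene,
                )
            )
        if params.untrusted_submitters and rng.random() < 0.1:
            records.append(
                SubmissionRecord(
                    chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                    alt=row.alt,
                    submitter=str(params.untrusted_submitters[0]),
                    classification="P" if pathogenic else "B",
                    gene=row.gene,
                )
            )
    return records


def write_bundle(params: GeneratorParams, outdir) -> dict:
    """Generate everything and write the on-disk bundle.

    Emits genome FASTA, transcript GFF3, cohort VCF, submissions /
    publications / ground-truth-manifest TSVs and a matching pipeline
    config YAML. Output bytes are a pure function of ``params`` (fixed seed
    ⇒ identical files). Returns the path map plus the in-memory objects.
    """
    from pathlib import Path

    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, transcripts = generate_reference(params)
    variants, manifest = generate_cohort(transcripts, genomes, params)
    submissions = generate_submissions(manifest, params)
    publications = generate_publications(manifest, params)

    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "transcripts.gff3",
        "vcf": outdir / "cohort.vcf",
        "submissions": outdir / "submissions.tsv",
        "publications": outdir / "publications.tsv",
        "manifest": outdir / "manifest.tsv",
        "config": outdir / "config.yaml",
    }
    io_mod.write_genome_fasta(genomes, paths["fasta"])
    io_mod.write_transcripts_gff3(transcripts, paths["gff3"])
    io_mod.write_cohort_vcf(
        variants, paths["vcf"],
        contig_lengths={c: len(g) for c, g in genomes.items()},
    )
    io_mod.write_submissions_tsv(submissions, paths["submissions"])
    io_mod.write_publications_tsv(publications, paths["publications"])
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    config = io_mod.PipelineConfig(
        trusted_submitters=params.trusted_submitters,
        lof_mechanism_genes=tuple(sorted({t.gene for t in transcripts})),
        seed=params.seed,
    )
    io_mod.save_config(config, paths["config"])
    return {
        "paths": paths,
        "genomes": genomes,
        "transcripts": transcripts,
        "variants": variants,
        "manifest": manifest,
        "submissions": submissions,
        "publications": publications,
        "config": config,
    }


def generate_publications(
    manifest: pd.DataFrame, params: GeneratorParams
) -> list[PublicationRecord]:
    """Publication counts with a planted positive MAF dependence for
    pathogenic variants; benign counts are mostly zero.

    Pathogenic counts are negative-binomial with mean
    base · (maf / 1e-4) ** exponent, so log-mean rises with log-MAF; benign
    counts are zero with probability ``benign_zero_fraction`` and small
    Poisson otherwise. Only variants observed in the cohort (AC ≥ 1) carry a
    defined MAF and are emitted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    records: list[PublicationRecord] = []
    for row in manifest.itertuples(index=False):
        if row.ac_adj < 1 or row.an_adj < 1:
            continue
        maf = row.ac_adj / row.an_adj
        if row.true_class == "pathogenic":
            mean = params.pathogenic_pub_base * (maf / 1e-4) ** (
                params.pathogenic_pub_maf_exponent
            )
            r = params.pathogenic_pub_dispersion
            p = r / (r + mean)
            count = int(rng.negative_binomial(r, p)) + 1  # always published
            cls = "pathogenic"
        else:
            if rng.random() < params.benign_zero_fraction:
                count = 0
            else:
                count = int(rng.poisson(params.benign_pub_mean))
            cls = "benign"
        records.append(
            PublicationRecord(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                consensus_class=cls, maf=maf, publication_count=count,
            )
        )
    return records
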