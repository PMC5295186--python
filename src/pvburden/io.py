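"""Format readers and writers plus pipeline configuration.

Formats supported: FASTA genomes (Biopython), transcript models as GFF3
(gene/mRNA/exon/CDS dialect, round-trip stable with the writer here) or
BED12 (blocks = exons, thickStart/thickEnd = CDS, converted from 0-based
half-open to the package's 1-based inclusive coordinates), cohort VCF with
AC_Adj/AN_Adj-style INFO keys (pysam; multi-allelic records are decomposed
into one row per alternate allele), and plain TSV for submissions,
adjudications, escape overrides and publication counts. All readers raise
``FormatError`` naming the offending column/key and line where possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import CohortVariant, FrequencyBin
from .consensus import AdjudicationRecord, SubmissionRecord
from .nmd import EscapeOverrideList
from .stats import PublicationRecord
from .transcripts import GenomeSequence, TranscriptModel


class FormatError(ValueError):
    """An input file does not match the expected schema."""


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters of the burden pipeline.

    ``bin_edges_percent`` are the interior bin edges as percentages (the
    bins cover [0, inf) with left-closed intervals); ``escape_window`` is
    the NMD 50-bp rule window in spliced-transcript bases.
    """

    min_total_alleles: int = 80_000
    recurrence_ac: int = 3
    bin_edges_percent: tuple[float, ...] = (0.005, 0.01, 0.05, 0.1)
    escape_window: int = 50
    trusted_submitters: tuple[str, ...] = ()
    lof_mechanism_genes: tuple[str, ...] = ()
    clinically_relevant_transcripts: dict[str, str] = field(default_factory=dict)
    correlation_method: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total_alleles <= 0 or self.recurrence_ac <= 0:
            raise ConfigError("thresholds must be positive")
        if self.escape_window <= 0:
            raise ConfigError("escape_window must be positive")
        edges = tuple(float(e) for e in self.bin_edges_percent)
        if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0:
            raise ConfigError("bin edges must be positive and strictly increasing")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigError(
                f"correlation_method {self.correlation_method!r} unknown"
            )
        self.bin_edges_percent = edges

    def bins(self) -> tuple[FrequencyBin, ...]:
        import math

        edges = [0.0] + [e / 100.0 for e in self.bin_edges_percent] + [math.inf]
        labels = (
            [f"<{self.bin_edges_percent[0]}%"]
            + [
                f"{a}-{b}%"
                for a, b in zip(self.bin_edges_percent, self.bin_edges_percent[1:])
            ]
            + [f">={self.bin_edges_percent[-1]}%"]
        )
        return tuple(
            FrequencyBin(lab, lo, hi)
            for lab, lo, hi in zip(labels, edges, edges[1:])
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON — YAML is a superset) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("trusted_submitters", "lof_mechanism_genes", "bin_edges_percent"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    genomes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genomes:
        raise FormatError(f"{path}: no FASTA records found")
    return genomes


def write_genome_fasta(
    genomes: Mapping[str, GenomeSequence], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(genomes[name].seq), id=name, description="")
        for name in sorted(genomes)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED12 transcript models
# ---------------------------------------------------------------------------

def write_transcripts_gff3(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    """gene/mRNA/exon/CDS dialect; coordinates 1-based inclusive."""
    lines = ["##gff-version 3"]
    for tx in sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
        lo, hi = tx.span
        gene_id = tx.gene
        lines.append(
            f"{tx.chrom}\tpvburden\tgene\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
            f"ID=gene:{gene_id};Name={gene_id}"
        )
        relevant = "true" if tx.clinically_relevant else "false"
        lines.append(
            f"{tx.chrom}\tpvburden\tmRNA\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
            f"ID=tx:{tx.transcript_id};Parent=gene:{gene_id};"
            f"clinically_relevant={relevant}"
        )
        for i, (s, e) in enumerate(tx.exons, start=1):
            lines.append(
                f"{tx.chrom}\tpvburden\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID=exon:{tx.transcript_id}.{i};Parent=tx:{tx.transcript_id}"
            )
        # CDS pieces: exon overlaps with [cds_start, cds_end], phase in
        # transcription order
        pieces = [
            (max(s, tx.cds_start), min(e, tx.cds_end))
            for s, e in tx.exons
            if e >= tx.cds_start and s <= tx.cds_end
        ]
        tx_order = pieces if tx.strand == "+" else pieces[::-1]
        done = 0
        phased = {}
        for s, e in tx_order:
            phased[(s, e)] = (3 - done % 3) % 3
            done += e - s + 1
        for i, (s, e) in enumerate(pieces, start=1):
            lines.append(
                f"{tx.chrom}\tpvburden\tCDS\t{s}\t{e}\t.\t{tx.strand}\t"
                f"{phased[(s, e)]}\t"
                f"ID=cds:{tx.transcript_id}.{i};Parent=tx:{tx.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff3_attributes(field9: str, path, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in field9.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"{path}:{lineno}: malformed attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def read_transcripts_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse the gene/mRNA/exon/CDS dialect written by this package."""
    mrnas: dict[str, dict] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _, ftype, start, end, _, strand, _, attr_s = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _gff3_attributes(attr_s, path, lineno)
            if ftype == "gene":
                gene_of[attrs.get("ID", "")] = attrs.get(
                    "Name", attrs.get("ID", "").removeprefix("gene:")
                )
            elif ftype == "mRNA":
                tx_id = attrs.get("ID", "").removeprefix("tx:")
                if not tx_id:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID")
                mrnas[attrs["ID"]] = {
                    "transcript_id": tx_id,
                    "gene": gene_of.get(attrs.get("Parent", ""), attrs.get("Parent", "")),
                    "chrom": chrom,
                    "strand": strand,
                    "clinically_relevant": attrs.get("clinically_relevant", "true")
                    == "true",
                    "exons": [],
                    "cds": [],
                }
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent not in mrnas:
                    raise FormatError(
                        f"{path}:{lineno}: {ftype} Parent {parent!r} refers to "
                        "no preceding mRNA"
                    )
                mrnas[parent]["exons" if ftype == "exon" else "cds"].append(
                    (start_i, end_i)
                )
    transcripts = []
    for spec in mrnas.values():
        if not spec["cds"]:
            raise FormatError(
                f"{path}: transcript {spec['transcript_id']} has no CDS features"
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=spec["transcript_id"],
                gene=spec["gene"],
                chrom=spec["chrom"],
                strand=spec["strand"],
                exons=tuple(sorted(spec["exons"])),
                cds_start=min(s for s, _ in spec["cds"]),
                cds_end=max(e for _, e in spec["cds"]),
                clinically_relevant=spec["clinically_relevant"],
            )
        )
    if not transcripts:
        raise FormatError(f"{path}: no mRNA features found")
    return transcripts


def read_transcripts_bed12(path: str | Path) -> list[TranscriptModel]:
    """BED12: blocks = exons, thickStart/thickEnd = CDS.

    BED coordinates are 0-based half-open; they are converted to 1-based
    inclusive here. The name column is interpreted as gene|transcript_id
    (or used for both when there is no pipe).
    """
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}"
                )
            chrom, chrom_start, _, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount disagrees with "
                    "blockSizes/blockStarts"
                )
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            gene, _, tx_id = name.partition("|")
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id or name,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start + 1,
                    cds_end=thick_end,
                )
            )
    if not transcripts:
        raise FormatError(f"{path}: no BED12 records found")
    return transcripts


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC_Adj,Number=A,Type=Integer,Description="Adjusted allele count">
##INFO=<ID=AN_Adj,Number=1,Type=Integer,Description="Adjusted total alleles">
##FILTER=<ID=LOW_QUAL,Description="Failed cohort quality filters">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_cohort_vcf(
    variants: Sequence[CohortVariant],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """One record per alternate allele, AC_Adj/AN_Adj in INFO."""
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={c},length={contig_lengths[c]}>\n"
            for c in sorted(contig_lengths)
        )
    lines = [_VCF_HEADER.format(contigs=contigs).rstrip("\n")]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t"
            f"AC_Adj={v.ac_adj};AN_Adj={v.an_adj}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort_vcf(
    path: str | Path,
    ac_field: str = "AC_Adj",
    an_field: str = "AN_Adj",
) -> list[CohortVariant]:
    """Read a cohort VCF, decomposing multi-allelic records.

    ``ac_field`` must be A-typed (one count per alternate allele);
    ``an_field`` is shared across alleles at the site. Set them to "AC"/"AN"
    for VCFs without adjusted counts.
    """
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for key in (ac_field, an_field):
            if key not in vcf.header.info:
                raise FormatError(
                    f"{path}: INFO key {key} missing from the VCF header"
                )
        for rec in vcf:
            if rec.alts is None:
                continue
            try:
                ac_raw = rec.info[ac_field]
            except KeyError as exc:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{ac_field}"
                ) from exc
            try:
                an = int(rec.info[an_field])
            except KeyError as exc:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{an_field}"
                ) from exc
            acs = (
                [int(a) for a in ac_raw]
                if isinstance(ac_raw, tuple)
                else [int(ac_raw)]
            )
            if len(acs) != len(rec.alts):
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} has {len(acs)} "
                    f"{ac_field} values for {len(rec.alts)} ALT alleles"
                )
            filt = list(rec.filter.keys())
            status = filt[0] if filt else "PASS"
            for alt, ac in zip(rec.alts, acs):
                variants.append(
                    CohortVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        filter_status=status,
                        ac_adj=ac,
                        an_adj=an,
                    )
                )
    return variants


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_submissions_tsv(path: str | Path) -> list[SubmissionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(
        df, ["chrom", "pos", "ref", "alt", "submitter", "classification"], path
    )
    return [
        SubmissionRecord(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            submitter=r.submitter, classification=r.classification,
            gene=getattr(r, "gene", None),
        )
        for r in df.itertuples(index=False)
    ]


def write_submissions_tsv(
    records: Sequence[SubmissionRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "gene": r.gene, "submitter": r.submitter,
                "classification": r.classification,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_adjudications_tsv(path: str | Path) -> list[AdjudicationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "pos", "ref", "alt", "classification"], path)
    return [
        AdjudicationRecord(
            key=(r.chrom, int(r.pos), r.ref, r.alt),
            classification=r.classification,
            rationale=str(getattr(r, "rationale", "")),
        )
        for r in df.itertuples(index=False)
    ]


def read_overrides_tsv(path: str | Path) -> EscapeOverrideList:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "pos", "ref", "alt", "citation"], path)
    return EscapeOverrideList(
        entries={
            (r.chrom, int(r.pos), r.ref, r.alt): str(r.citation)
            for r in df.itertuples(index=False)
        }
    )


def write_overrides_tsv(overrides: EscapeOverrideList, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "citation": cit}
            for (c, p, r, a), cit in sorted(overrides.entries.items())
        ],
        columns=["chrom", "pos", "ref", "alt", "citation"],
    ).to_csv(path, sep="\t", index=False)


def read_publications_tsv(path: str | Path) -> list[PublicationRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, float_precision="round_trip"
    )
    _require_columns(
        df,
        ["chrom", "pos", "ref", "alt", "class", "maf", "publication_count"],
        path,
    )
    df = df.rename(columns={"class": "consensus_class"})
    return [
        PublicationRecord(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            consensus_class=r.consensus_class,
            maf=float(r.maf), publication_count=int(r.publication_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_publications_tsv(
    records: Sequence[PublicationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "class": r.consensus_class, "maf": r.maf,
                "publication_count": r.publication_count,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
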