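"""End-to-end pipeline driver: annotate → filter → consensus → burden → stats.

Reads the cohort VCF, transcript models and genome, classifies NMD fate on
the designated clinically relevant transcript per gene, applies the cohort
quality/depth filters, aggregates submissions into consensus calls,
assembles the pathogenic set, and emits frequency profiles, burden tables
and threshold reports as TSV plus one machine-readable JSON summary. Every
stage logs (input count, surviving count) so the reports reconcile.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cohort as cohort_mod
from . import consensus as consensus_mod
from . import io as io_mod
from . import nmd as nmd_mod
from . import stats as stats_mod

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineInputs:
    vcf: Path
    transcripts: Path  # GFF3 (.gff3/.gff) or BED12 (.bed)
    genome_fasta: Path
    submissions: Optional[Path] = None
    adjudications: Optional[Path] = None
    overrides: Optional[Path] = None
    publications: Optional[Path] = None

    def __post_init__(self) -> None:
        for name in ("vcf", "transcripts", "genome_fasta"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name}: {p} not found")
        for name in ("submissions", "adjudications", "overrides", "publications"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input {name}: {p} not found")


def _read_transcripts(path: Path):
    if str(path).endswith((".bed", ".bed12")):
        return io_mod.read_transcripts_bed12(path)
    return io_mod.read_transcripts_gff3(path)


def run_pipeline(
    config: io_mod.PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> dict:
    """Execute the full analysis; returns the JSON-ready summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    audit: dict[str, dict[str, int]] = {}

    def stage(name: str, n_in: int, n_out: int) -> None:
        audit[name] = {"input": n_in, "surviving": n_out}
        logger.info("%s: %d -> %d", name, n_in, n_out)

    genomes = io_mod.read_genome_fasta(inputs.genome_fasta)
    transcripts = _read_transcripts(inputs.transcripts)
    if config.clinically_relevant_transcripts:
        wanted = set(config.clinically_relevant_transcripts.values())
        transcripts = [
            dataclasses.replace(t, clinically_relevant=t.transcript_id in wanted)
            for t in transcripts
        ]
    variants = io_mod.read_cohort_vcf(inputs.vcf)
    overrides = (
        io_mod.read_overrides_tsv(inputs.overrides)
        if inputs.overrides
        else nmd_mod.EscapeOverrideList.empty()
    )

    # annotate
    annotated = nmd_mod.annotate_variants(
        variants, transcripts, genomes, overrides,
        escape_window=config.escape_window,
    )
    stage("annotate", len(variants), len(annotated))
    annotated.to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    gene_by_key = {
        (r.chrom, r.pos, r.ref, r.alt): r.gene
        for r in annotated.itertuples(index=False)
    }
    nmd_by_key = {
        (r.chrom, r.pos, r.ref, r.alt): r.nmd_status
        for r in annotated.itertuples(index=False)
    }
    variants = [
        dataclasses.replace(v, gene=gene_by_key[v.key])
        for v in variants
        if v.key in gene_by_key
    ]

    # cohort filters
    passing = [
        v
        for v in variants
        if cohort_mod.passes_cohort_filters(v, config.min_total_alleles)
    ]
    stage("cohort_filters", len(variants), len(passing))

    # consensus
    calls: dict = {}
    pathogenic_tags: dict = {}
    if inputs.submissions:
        submissions = io_mod.read_submissions_tsv(inputs.submissions)
        calls = consensus_mod.classify_all(submissions, config.trusted_submitters)
        adjudications = (
            io_mod.read_adjudications_tsv(inputs.adjudications)
            if inputs.adjudications
            else []
        )
        pathogenic_tags = consensus_mod.assemble_pathogenic_set(
            calls.values(),
            adjudications,
            nmd_status=nmd_by_key,
            lof_mechanism_genes=config.lof_mechanism_genes,
            variant_genes=gene_by_key,
        )
        stage("consensus", len(submissions), len(calls))
        pd.DataFrame(
            [
                {
                    "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                    "status": c.status, "n_trusted": c.n_trusted,
                }
                for k, c in sorted(calls.items())
            ]
        ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    elif config.lof_mechanism_genes:
        pathogenic_tags = consensus_mod.assemble_pathogenic_set(
            [], [], nmd_status=nmd_by_key,
            lof_mechanism_genes=config.lof_mechanism_genes,
            variant_genes=gene_by_key,
        )

    # burden table over filter-passing NMD-positive variants
    bins = config.bins()
    burden = cohort_mod.gene_burden_table(
        passing, nmd_by_key, bins, config.min_total_alleles
    )
    stage(
        "burden",
        len(passing),
        int(burden[[b.label for b in bins]].to_numpy().sum()) if len(burden) else 0,
    )
    burden.to_csv(outdir / "burden.tsv", sep="\t", index=False)

    # frequency profile + threshold report over the pathogenic set
    pathogenic_variants = [
        v for v in passing if v.key in pathogenic_tags
    ]
    stage("pathogenic_set", len(pathogenic_tags), len(pathogenic_variants))
    profile = stats_mod.frequency_profile(
        pathogenic_variants, recurrence_ac=config.recurrence_ac
    )
    report = stats_mod.threshold_report(pathogenic_variants)
    report.to_csv(outdir / "threshold_report.tsv", sep="\t", index=False)
    profile.outliers.to_csv(outdir / "founder_candidates.tsv", sep="\t", index=False)

    summary: dict = {
        "audit": audit,
        "n_variants": len(variants),
        "n_passing": len(passing),
        "pathogenic_set_size": len(pathogenic_tags),
        "profile": {
            "n_total": profile.n_total,
            "n_absent": profile.n_absent,
            "n_singleton": profile.n_singleton,
            "fraction_below": {
                f"{t:g}": f for t, f in profile.fraction_below.items()
            },
            "n_outliers": int(len(profile.outliers)),
        },
        "consensus_status_counts": (
            pd.Series([c.status for c in calls.values()])
            .value_counts()
            .to_dict()
            if calls
            else {}
        ),
    }

    # publication analysis
    if inputs.publications:
        pubs = io_mod.read_publications_tsv(inputs.publications)
        summary["publications"] = stats_mod.publication_summary(
            pubs, method=config.correlation_method
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
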