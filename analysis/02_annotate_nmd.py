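#!/usr/bin/env python
"""Classify the synthetic cohort's variants by predicted NMD fate and
audit the classifier against the generation-time reconstruction oracle.

Requires 01_simulate_cohort.py to have run (reads scratch/synthetic/).
Writes the annotation table and an agreement summary under results/.
"""

from pathlib import Path

import pandas as pd

from pvburden import annotate_variants
from pvburden.io import read_cohort_vcf, read_genome_fasta, read_transcripts_gff3

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "synthetic"
    genomes = read_genome_fasta(sim / "genome.fa")
    transcripts = read_transcripts_gff3(sim / "transcripts.gff3")
    variants = read_cohort_vcf(sim / "cohort.vcf")
    manifest = pd.read_csv(sim / "manifest.tsv", sep="\t")

    annotation = annotate_variants(variants, transcripts, genomes)
    merged = manifest.merge(
        annotation, on=["chrom", "pos", "ref", "alt"], suffixes=("_true", "")
    )
    truncating = merged[
        merged.true_category.isin(["nonsense", "frameshift", "splice"])
    ]
    agree = (truncating.true_nmd_status == truncating.nmd_status).mean()

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    annotation.to_csv(results / "02_nmd_annotation.tsv", sep="\t", index=False)
    summary = (
        merged.groupby(["nmd_status", "nmd_reason"]).size().rename("n").reset_index()
    )
    summary.to_csv(results / "02_nmd_reason_counts.tsv", sep="\t", index=False)

    print(f"annotated {len(annotation)} variants; "
          f"oracle agreement on {len(truncating)} truncating variants: "
          f"{100 * agree:.1f}%")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
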