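#!/usr/bin/env python
"""Aggregate the synthetic submission table into consensus calls and
assemble the analysis pathogenic set with provenance tags.

Requires 01 and 02 to have run. Writes status counts and the tagged
pathogenic set under results/.
"""

from pathlib import Path

import pandas as pd
import yaml

from pvburden.consensus import assemble_pathogenic_set, classify_all
from pvburden.io import read_submissions_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "synthetic"
    config = yaml.safe_load((sim / "config.yaml").read_text())
    submissions = read_submissions_tsv(sim / "submissions.tsv")
    annotation = pd.read_csv(ROOT / "results" / "02_nmd_annotation.tsv", sep="\t")

    calls = classify_all(submissions, config["trusted_submitters"])
    nmd = {
        (r.chrom, r.pos, r.ref, r.alt): r.nmd_status
        for r in annotation.itertuples(index=False)
    }
    genes = {
        (r.chrom, r.pos, r.ref, r.alt): r.gene
        for r in annotation.itertuples(index=False)
    }
    tags = assemble_pathogenic_set(
        calls.values(), [], nmd, config["lof_mechanism_genes"], genes
    )

    results = ROOT / "results"
    status_counts = (
        pd.Series([c.status for c in calls.values()]).value_counts().rename("n")
    )
    status_counts.to_csv(results / "03_consensus_status_counts.tsv", sep="\t")
    pd.DataFrame(
        [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "sources": ",".join(sorted(v))}
            for k, v in sorted(tags.items())
        ]
    ).to_csv(results / "03_pathogenic_set.tsv", sep="\t", index=False)

    n_both = sum(1 for v in tags.values() if len(v) > 1)
    print(f"{len(calls)} variants with assertions -> statuses:")
    print(status_counts.to_string())
    print(f"pathogenic set: {len(tags)} variants "
          f"({n_both} supported by both consensus and NMD prediction)")


if __name__ == "__main__":
    main()
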