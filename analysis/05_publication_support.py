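#!/usr/bin/env python
"""Publication support of high-frequency variants in the synthetic cohort.

Summarizes publication counts per consensus class for variants above the
0.01% frequency threshold (five-number summaries, zero-publication counts,
MAF–publication-count correlation, pathogenic-vs-benign rank-sum test).
Requires 01_simulate_cohort.py to have run.
"""

import json
from pathlib import Path

from pvburden.io import read_publications_tsv
from pvburden.stats import publication_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "synthetic"
    records = read_publications_tsv(sim / "publications.tsv")
    above = [r for r in records if r.maf >= 1e-4]
    summary = publication_summary(records)
    summary_above = publication_summary(above) if above else {}

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "05_publication_summary.json", "w") as fh:
        json.dump(
            {"all_observed": summary, "above_0.01_percent": summary_above},
            fh, indent=2, sort_keys=True,
        )

    for cls, entry in summary["classes"].items():
        print(f"{cls}: n={entry['n']}, median publications "
              f"{entry['summary']['median']:.0f}, "
              f"{entry['n_zero_publications']} with zero publications, "
              f"r={entry['r'] if entry['r'] is None else round(entry['r'], 3)}")
    rs = summary.get("rank_sum_pathogenic_vs_benign")
    if rs:
        print(f"pathogenic vs benign publication counts: "
              f"rank-sum p = {rs['p_value']:.2e}")


if __name__ == "__main__":
    main()
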