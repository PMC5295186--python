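#!/usr/bin/env python
"""Frequency profiles and threshold reports: packaged reference tables plus
the synthetic pathogenic set.

Reproduces the cohort arithmetic of the published gene panels (BRCA1/2
profile, 79-gene bin totals, gold-standard missense filtering) and runs the
same profile over the synthetic pathogenic set from 03. Writes tables under
results/.
"""

from pathlib import Path

import pandas as pd

from pvburden import fixtures
from pvburden.cohort import compute_maf, format_maf_percent, passes_cohort_filters
from pvburden.io import read_cohort_vcf
from pvburden.stats import frequency_profile, threshold_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    # --- BRCA1/2 pathogenic set -------------------------------------------
    brca = fixtures.brca_pathogenic_variants()
    profile = frequency_profile(brca)
    report = threshold_report(brca)
    report.to_csv(results / "04_brca_threshold_report.tsv", sep="\t", index=False)
    profile.outliers.to_csv(
        results / "04_brca_founder_candidates.tsv", sep="\t", index=False
    )
    print(f"BRCA1/2: {profile.n_total} pathogenic variants, "
          f"{profile.n_absent} absent "
          f"({100 * profile.n_absent / profile.n_total:.1f}%), "
          f"{len(profile.outliers)} founder candidates (AC > 3), "
          f"{100 * profile.fraction_below[5e-5]:.1f}% below 0.005%")

    # --- 79-gene panels ----------------------------------------------------
    rows = []
    for area, label in [
        (("hereditary_cancer",), "hereditary_cancer_excl_BRCA"),
        (("primary_ciliary_dyskinesia",), "primary_ciliary_dyskinesia"),
        (("arrhythmia_cardiomyopathy",), "arrhythmia_cardiomyopathy"),
        (None, "all_77_genes"),
    ]:
        t = fixtures.panel_bin_totals(area, exclude_genes=("BRCA1", "BRCA2"))
        rows.append({
            "panel": label,
            "n_total": int(t.sum()),
            "n_below_0.01%": int(t.iloc[0] + t.iloc[1]),
            "n_above_0.01%": int(t.iloc[2] + t.iloc[3] + t.iloc[4]),
            "n_above_0.05%": int(t.iloc[3] + t.iloc[4]),
        })
    panels = pd.DataFrame(rows)
    panels.to_csv(results / "04_panel_bin_totals.tsv", sep="\t", index=False)
    print(panels.to_string(index=False))

    # --- gold-standard missense set ----------------------------------------
    variants = fixtures.gold_standard_cohort_variants()
    cls = fixtures.gold_standard_classifications()
    path = [v for v, c in zip(variants, cls) if c == "Pathogenic"]
    kept = [v for v in path if passes_cohort_filters(v)]
    max_maf = max(compute_maf(v) for v in kept)
    print(f"gold-standard missense: {len(path)} pathogenic, {len(kept)} pass "
          f"filters, max MAF {format_maf_percent(max_maf)}")

    # --- synthetic pathogenic set -----------------------------------------
    sim = ROOT / "scratch" / "synthetic"
    if (sim / "cohort.vcf").exists():
        pathogenic_keys = set()
        tagged = pd.read_csv(ROOT / "results" / "03_pathogenic_set.tsv", sep="\t")
        pathogenic_keys = {
            (r.chrom, r.pos, r.ref, r.alt) for r in tagged.itertuples(index=False)
        }
        cohort = [
            v for v in read_cohort_vcf(sim / "cohort.vcf")
            if passes_cohort_filters(v) and v.key in pathogenic_keys
        ]
        sprof = frequency_profile(cohort)
        threshold_report(cohort).to_csv(
            results / "04_synthetic_threshold_report.tsv", sep="\t", index=False
        )
        print(f"synthetic pathogenic set: {sprof.n_total} observed+absent, "
              f"{len(sprof.outliers)} AC>3 outliers")
    else:
        print("scratch/synthetic missing; run 01-03 first for the synthetic part")


if __name__ == "__main__":
    main()
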