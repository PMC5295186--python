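"""Packaged reference tables and the cohort profiles derived from them.

Three machine-readable tables ship with the package (checksummed so edits
fail loudly):

* the fourteen recurrent/founder BRCA1/2 truncating variants with their
  cohort allele counts and frequencies;
* per-gene frequency-bin counts of NMD-positive variants for 79 genes
  across hereditary cancer, primary ciliary dyskinesia (PCD) and
  arrhythmia/cardiomyopathy panels;
* the 74-variant hypertrophic-cardiomyopathy "gold standard" missense set
  (41 pathogenic, 33 benign/likely benign) with shallow-coverage and
  quality-filter flags.

Cohort-variant reconstructions use synthetic variant identities (the
chromosome/position/allele columns are placeholders; allele counts and
total allele numbers are derived from the printed frequencies), so profile
arithmetic — absent/singleton fractions, fractions below thresholds,
founder outliers — is reproduced from real inputs while sequence-level
fields stay obviously artificial.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from io import BytesIO

import pandas as pd

from .cohort import CohortVariant

_CHECKSUMS = {
    "brca_recurrent_variants.tsv": (
        "acb52aba53e800650f73b923f60c8fdff2cbc865be8b76c2e6d330b2396a84f7"
    ),
    "panel_frequency_bins.tsv": (
        "7e4f6cf1722de0a5a6ba41ac8bf53b7c5a239a0a5d6a8bdc0759d420b4aefe6d"
    ),
    "hcm_gold_standard_missense.tsv": (
        "3b4d031dd7750bcd8d8bb609810ccc1b6b0fd97d6e0ae792e51c5ec699400387"
    ),
}

#: default total-allele number used when reconstructing a variant whose
#: printed frequency leaves AN unconstrained (deep-coverage locus)
_DEEP_AN = 121_000
#: seed AN for loci flagged as covered by fewer than 80,000 alleles
_SHALLOW_AN = 75_000

PANEL_BIN_COLUMNS = (
    "lt_0_005", "f_0_005_to_0_01", "f_0_01_to_0_05", "f_0_05_to_0_1", "ge_0_1",
)


class FixtureIntegrityError(RuntimeError):
    """A packaged table no longer matches its recorded checksum."""


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("pvburden.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} does not match the recorded "
            f"{_CHECKSUMS[name]}; the transcription has been edited"
        )
    return pd.read_csv(BytesIO(raw), sep="\t")


def load_brca_recurrent() -> pd.DataFrame:
    """The 14 recurrent/founder BRCA1/2 variants (AC > 3)."""
    return _load("brca_recurrent_variants.tsv")


def load_panel_bins() -> pd.DataFrame:
    """Per-gene NMD-positive frequency-bin counts for 79 genes."""
    return _load("panel_frequency_bins.tsv")


def load_gold_standard() -> pd.DataFrame:
    """The 74 hypertrophic-cardiomyopathy gold-standard missense variants."""
    return _load("hcm_gold_standard_missense.tsv")


def _reconstruct_ac_an(maf_percent: float, shallow: bool) -> tuple[int, int]:
    """(AC, AN) consistent with a printed frequency.

    AC is the nearest integer at a seed AN (121,000 deep / 75,000 shallow);
    AN is then re-derived so AC/AN reproduces the printed value exactly.
    """
    if maf_percent == 0:
        return 0, _SHALLOW_AN if shallow else _DEEP_AN
    maf = maf_percent / 100.0
    seed_an = _SHALLOW_AN if shallow else _DEEP_AN
    ac = max(1, round(maf * seed_an))
    an = round(ac / maf)
    return ac, an


def brca_pathogenic_variants() -> list[CohortVariant]:
    """The 1,364-variant BRCA1/2 pathogenic set as cohort records.

    Composition: 1,163 variants absent from the cohort (AC 0), 150
    singletons (AC 1), 37 at AC 2–3 (split 20/17; the most frequent
    non-recurrent allele sits at 3/121,000 ≈ 0.0025%), and the fourteen
    recurrent/founder variants with AC and AN reconstructed from their
    printed frequencies. Variant identities are synthetic placeholders.
    """
    variants: list[CohortVariant] = []
    counter = 0

    def emit(gene: str, ac: int, an: int) -> None:
        nonlocal counter
        counter += 1
        chrom = "17" if gene == "BRCA1" else "13"
        variants.append(
            CohortVariant(
                chrom=chrom,
                pos=1_000_000 + counter,
                ref="A",
                alt="C",
                filter_status="PASS",
                ac_adj=ac,
                an_adj=an,
                gene=gene,
            )
        )

    def bulk(n: int, ac: int) -> None:
        for i in range(n):
            emit("BRCA1" if i % 2 == 0 else "BRCA2", ac, _DEEP_AN)

    bulk(1163, 0)
    bulk(150, 1)
    bulk(20, 2)
    bulk(17, 3)
    for row in load_brca_recurrent().itertuples(index=False):
        ac, an = _reconstruct_ac_an(float(row.maf_percent), shallow=False)
        if ac != int(row.allele_count):  # trust the printed allele count
            ac = int(row.allele_count)
            an = round(ac / (float(row.maf_percent) / 100.0))
        emit(row.gene, ac, an)
    return variants


def gold_standard_cohort_variants() -> list[CohortVariant]:
    """Gold-standard missense set as cohort records.

    Loci flagged as covered by fewer than 80,000 alleles get a shallow AN;
    the variant flagged as failing the cohort quality filter is marked
    non-PASS. AC/AN pairs reproduce the printed frequencies.
    """
    variants = []
    for i, row in enumerate(load_gold_standard().itertuples(index=False), start=1):
        shallow = bool(row.low_an)
        ac, an = _reconstruct_ac_an(float(row.maf_percent), shallow)
        variants.append(
            CohortVariant(
                chrom="hcm",
                pos=10_000 + i,
                ref="G",
                alt="T",
                filter_status="LOW_QUAL" if row.non_pass else "PASS",
                ac_adj=ac,
                an_adj=an,
                gene=row.gene,
            )
        )
    return variants


def gold_standard_classifications() -> list[str]:
    """Printed classification per row, aligned with
    :func:`gold_standard_cohort_variants`."""
    return list(load_gold_standard()["classification"])


def panel_bin_totals(
    clinical_areas: tuple[str, ...] | None = None,
    exclude_genes: tuple[str, ...] = (),
) -> pd.Series:
    """Summed bin counts over a gene-panel selection."""
    df = load_panel_bins()
    if clinical_areas is not None:
        df = df[df["clinical_area"].isin(clinical_areas)]
    if exclude_genes:
        df = df[~df["gene"].isin(exclude_genes)]
    return df[list(PANEL_BIN_COLUMNS)].sum()
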