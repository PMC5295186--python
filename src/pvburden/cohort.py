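"""Cohort variant records, quality/depth filtering, MAF binning.

Allele frequencies are computed from quality-adjusted allele counts
(AC_Adj-style) over quality-adjusted total allele numbers (AN_Adj-style).
Sites failing the cohort's bioinformatics filter or genotyped in fewer than
80,000 alleles are excluded, so that frequency estimates at the very rare
end remain meaningful. Variants seen in more than three individuals are
flagged as founder/recurrent candidates requiring literature review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

DEFAULT_MIN_TOTAL_ALLELES = 80_000
DEFAULT_RECURRENCE_AC = 3


class UndefinedFrequencyError(ZeroDivisionError):
    """MAF requested at a locus with zero genotyped alleles."""


@dataclass(frozen=True)
class CohortVariant:
    """One alternate allele at one site (multi-allelics pre-decomposed)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    ac_adj: int = 0
    an_adj: int = 0
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if self.ac_adj < 0 or self.an_adj < 0:
            raise ValueError(f"{self.chrom}:{self.pos} negative AC/AN")
        if self.ac_adj > self.an_adj:
            raise ValueError(
                f"{self.chrom}:{self.pos} AC_Adj {self.ac_adj} exceeds "
                f"AN_Adj {self.an_adj}"
            )

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FrequencyBin:
    """Half-open MAF interval [lower, upper); upper may be +inf."""

    label: str
    lower: float
    upper: float


def default_bins() -> tuple[FrequencyBin, ...]:
    """The five standard report bins, in fractional units."""
    return (
        FrequencyBin("<0.005%", 0.0, 5e-5),
        FrequencyBin("0.005-0.01%", 5e-5, 1e-4),
        FrequencyBin("0.01-0.05%", 1e-4, 5e-4),
        FrequencyBin("0.05-0.1%", 5e-4, 1e-3),
        FrequencyBin(">=0.1%", 1e-3, math.inf),
    )


def validate_bins(bins: Sequence[FrequencyBin]) -> None:
    if not bins or bins[0].lower != 0.0 or not math.isinf(bins[-1].upper):
        raise ValueError("bins must cover [0, inf)")
    for a, b in zip(bins, bins[1:]):
        if a.upper != b.lower or a.lower >= a.upper:
            raise ValueError("bins must be ordered, disjoint and contiguous")


def passes_cohort_filters(
    v: CohortVariant, min_total_alleles: int = DEFAULT_MIN_TOTAL_ALLELES
) -> bool:
    """True iff the record is PASS and the locus depth floor is met
    (an_adj ≥ min_total_alleles, boundary inclusive)."""
    return v.filter_status == "PASS" and v.an_adj >= min_total_alleles


def compute_maf(v: CohortVariant) -> float:
    """Allele frequency ac_adj / an_adj as a fraction in [0, 1]."""
    if v.an_adj == 0:
        raise UndefinedFrequencyError(
            f"{v.chrom}:{v.pos} has AN_Adj = 0; frequency undefined"
        )
    return v.ac_adj / v.an_adj


def format_maf_percent(maf: float, sig: int = 2) -> str:
    """Display convention: percentage at 2 significant figures ('0' if absent)."""
    if maf == 0:
        return "0"
    pct = maf * 100.0
    ndigits = sig - 1 - math.floor(math.log10(abs(pct)))
    return f"{round(pct, ndigits):.{max(ndigits, 0)}f}%"


def bin_maf(maf: float, bins: Optional[Sequence[FrequencyBin]] = None) -> str:
    """Label of the unique bin with lower ≤ maf < upper."""
    if maf < 0:
        raise ValueError("negative MAF")
    bins = default_bins() if bins is None else bins
    for b in bins:
        if b.lower <= maf < b.upper:
            return b.label
    raise AssertionError("bins do not cover the MAF")  # pragma: no cover


def flag_recurrent(
    variants: Iterable[CohortVariant], max_ac: int = DEFAULT_RECURRENCE_AC
) -> list[CohortVariant]:
    """Founder/recurrent candidates: records with ac_adj strictly above
    ``max_ac``, sorted by allele count descending."""
    flagged = [v for v in variants if v.ac_adj > max_ac]
    return sorted(flagged, key=lambda v: (-v.ac_adj, v.chrom, v.pos, v.alt))


def gene_burden_table(
    variants: Sequence[CohortVariant],
    nmd_status: dict,
    bins: Optional[Sequence[FrequencyBin]] = None,
    min_total_alleles: int = DEFAULT_MIN_TOTAL_ALLELES,
    inheritance: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-gene bin counts of observed, filter-passing NMD-positive variants.

    Variants absent from the cohort (ac_adj = 0) are excluded from the bins
    and reported in a separate ``n_absent`` column. ``nmd_status`` maps the
    variant key to its status string; ``inheritance`` optionally maps gene
    to dominant/recessive for the report.
    """
    bins = default_bins() if bins is None else bins
    validate_bins(bins)
    labels = [b.label for b in bins]
    per_gene: dict[str, dict[str, int]] = {}
    for v in variants:
        if v.gene is None:
            continue
        row = per_gene.setdefault(
            v.gene, {lab: 0 for lab in labels} | {"n_absent": 0}
        )
        if nmd_status.get(v.key) != "NMD_positive":
            continue
        if not passes_cohort_filters(v, min_total_alleles):
            continue
        if v.ac_adj == 0:
            row["n_absent"] += 1
        else:
            row[bin_maf(compute_maf(v), bins)] += 1
    records = []
    for gene in sorted(per_gene):
        rec = {"gene": gene}
        if inheritance is not None:
            rec["inheritance"] = inheritance.get(gene, "")
        rec.update(per_gene[gene])
        records.append(rec)
    cols = ["gene"] + (["inheritance"] if inheritance is not None else [])
    return pd.DataFrame(records, columns=cols + labels + ["n_absent"])
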