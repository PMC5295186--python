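"""Distribution statistics over pathogenic-variant allele frequencies.

Frequency profiles (absent/singleton accounting, fraction below candidate
thresholds, founder-candidate outliers), two-sided Wilcoxon rank-sum
comparisons of MAF distributions, and the publication-support analysis
(per-class five-number summaries and MAF–publication-count correlations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    CohortVariant,
    DEFAULT_RECURRENCE_AC,
    compute_maf,
    flag_recurrent,
)

#: candidate thresholds, as fractions (0.0025% ... 0.1%)
DEFAULT_THRESHOLDS = (2.5e-5, 5e-5, 1e-4, 5e-4, 1e-3)


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PublicationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    consensus_class: str  # pathogenic | benign
    maf: float
    publication_count: int

    def __post_init__(self) -> None:
        if self.publication_count < 0:
            raise ValueError("negative publication count")


@dataclass
class FrequencyProfile:
    n_total: int
    n_absent: int
    n_singleton: int
    fraction_below: dict[float, Optional[float]]
    outliers: pd.DataFrame = field(repr=False)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon/Mann–Whitney rank-sum test.

    Exact enumeration when both samples have n ≤ 8 and there are no ties;
    otherwise the tie-corrected normal approximation. Degenerate input where
    every value is identical returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return StatResult(
            "wilcoxon_rank_sum", a.size * b.size / 2.0, 1.0, a.size, b.size
        )
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return StatResult(
        "wilcoxon_rank_sum", float(res.statistic), float(min(res.pvalue, 1.0)),
        a.size, b.size,
    )


def fraction_below(mafs: Iterable[float], threshold: float) -> Optional[float]:
    """|{m : m < threshold}| / n; None for an empty input.

    Strictly-below counting, so absent variants (MAF 0) fall below every
    positive threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mafs = list(mafs)
    if not mafs:
        return None
    return sum(1 for m in mafs if m < threshold) / len(mafs)


def frequency_profile(
    variants: Sequence[CohortVariant],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    recurrence_ac: int = DEFAULT_RECURRENCE_AC,
) -> FrequencyProfile:
    """Summary of a pathogenic set's cohort frequencies.

    Counts absent (AC 0) and singleton (AC 1) variants, the fraction below
    each candidate threshold, and the AC > ``recurrence_ac`` outlier list
    (founder candidates) with allele counts and frequencies.
    """
    n = len(variants)
    n_absent = sum(1 for v in variants if v.ac_adj == 0)
    n_singleton = sum(1 for v in variants if v.ac_adj == 1)
    mafs = [compute_maf(v) for v in variants]
    below = {t: fraction_below(mafs, t) for t in sorted(thresholds)}
    flagged = flag_recurrent(variants, recurrence_ac)
    outliers = pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "ac_adj": v.ac_adj,
                "an_adj": v.an_adj,
                "maf": compute_maf(v),
            }
            for v in flagged
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "ac_adj", "an_adj", "maf"],
    )
    return FrequencyProfile(n, n_absent, n_singleton, below, outliers)


def threshold_report(
    variants: Sequence[CohortVariant],
    candidate_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One row per candidate threshold plus the outliers above it.

    A variant "above" a threshold means MAF ≥ threshold (bins are
    left-closed); everything below is "captured". Every variant above a
    threshold is listed by identity with its AC/MAF and flagged as requiring
    literature review.
    """
    rows = []
    mafs = [(v, compute_maf(v)) for v in variants]
    n = len(mafs)
    for t in sorted(candidate_thresholds):
        above = sorted(
            (pair for pair in mafs if pair[1] >= t), key=lambda p: -p[1]
        )
        captured = n - len(above)
        rows.append(
            {
                "threshold": t,
                "threshold_percent": t * 100.0,
                "n_total": n,
                "n_captured": captured,
                "captured_percent": (100.0 * captured / n) if n else math.nan,
                "n_above": len(above),
                "outliers_above": ";".join(
                    f"{v.gene or '.'}|{v.chrom}:{v.pos}:{v.ref}>{v.alt}"
                    f"|AC={v.ac_adj}|MAF={m:.3g}|requires literature review"
                    for v, m in above
                ),
            }
        )
    return pd.DataFrame(rows)


def _five_number(values: np.ndarray) -> dict[str, float]:
    # linear-interpolation quartiles, whiskers = min/max
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
    }


def publication_summary(
    records: Sequence[PublicationRecord], method: str = "pearson"
) -> dict:
    """Publication support per consensus class.

    For each class: five-number summary of publication counts (linear
    interpolation, whiskers = min/max), the number of zero-publication
    variants, and the correlation r between MAF and publication count with
    its p-value (``method``: 'pearson' product-moment on raw values, or
    'spearman'; None when a class has fewer than 3 records or zero
    variance). Also reports the two-sided rank-sum p comparing pathogenic
    vs benign publication counts.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    out: dict = {"correlation_method": method, "classes": {}}
    by_class: dict[str, list[PublicationRecord]] = {}
    for r in records:
        by_class.setdefault(r.consensus_class, []).append(r)
    for cls, recs in sorted(by_class.items()):
        counts = np.array([r.publication_count for r in recs], dtype=float)
        mafs = np.array([r.maf for r in recs], dtype=float)
        entry = {
            "n": len(recs),
            "summary": _five_number(counts),
            "n_zero_publications": int((counts == 0).sum()),
            "r": None,
            "r_p_value": None,
        }
        if len(recs) >= 3 and np.ptp(counts) > 0 and np.ptp(mafs) > 0:
            fn = sps.pearsonr if method == "pearson" else sps.spearmanr
            r, p = fn(mafs, counts)
            entry["r"] = float(r)
            entry["r_p_value"] = float(p)
        out["classes"][cls] = entry
    path = by_class.get("pathogenic")
    ben = by_class.get("benign")
    if path and ben:
        res = rank_sum_test(
            [r.publication_count for r in path],
            [r.publication_count for r in ben],
        )
        out["rank_sum_pathogenic_vs_benign"] = {
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
    return out
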