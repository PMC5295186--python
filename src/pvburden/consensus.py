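"""Consensus pathogenicity from per-submitter assertions.

Aggregates submission records (ClinVar-style) restricted to a trusted
submitter list: two or more trusted submitters unanimously asserting
pathogenic/likely pathogenic yield a consensus-pathogenic call; unanimous
benign/likely benign yields consensus-benign; any mix of P/LP with weaker
assertions is conflicting; a lone trusted P/LP assertion is tracked
separately for external adjudication. The analysis "pathogenic set" is then
the union of consensus-pathogenic calls, adjudicated single-submitter or
conflicting calls, and NMD-positive truncating variants in genes with an
established loss-of-function disease mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B")
PATHOGENIC = frozenset({"P", "LP"})
BENIGN = frozenset({"LB", "B"})

CONSENSUS_PATHOGENIC = "consensus_pathogenic"
SINGLE_SUBMITTER_PATHOGENIC = "single_submitter_pathogenic"
CONFLICTING = "conflicting"
CONSENSUS_BENIGN = "consensus_benign"
NO_TRUSTED_ASSERTION = "no_trusted_assertion"


@dataclass(frozen=True)
class SubmissionRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    submitter: str
    classification: str
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(
                f"classification {self.classification!r} outside the "
                f"5-level vocabulary {CLASSIFICATIONS}"
            )

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ConsensusCall:
    key: tuple
    status: str
    n_trusted: int


@dataclass(frozen=True)
class AdjudicationRecord:
    key: tuple
    classification: str
    rationale: str = ""


def consensus_classification(
    records: Sequence[SubmissionRecord], trusted: Iterable[str]
) -> ConsensusCall:
    """Aggregate one variant's assertions into a consensus category.

    Untrusted submitters are dropped first. With ≥2 remaining assertions:
    all P/LP → consensus_pathogenic; all LB/B → consensus_benign; P/LP mixed
    with anything weaker → conflicting. Exactly one trusted P/LP assertion →
    single_submitter_pathogenic. Everything else → no_trusted_assertion.
    """
    if not records:
        raise ValueError("no submission records supplied")
    keys = {r.key for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple variants: {sorted(keys)}")
    seen = set()
    for r in records:
        pair = (r.key, r.submitter)
        if pair in seen:
            raise ValueError(
                f"duplicate submission from {r.submitter} for {r.key}"
            )
        seen.add(pair)
    key = records[0].key
    trusted = set(trusted)
    kept = [r.classification for r in records if r.submitter in trusted]
    n = len(kept)
    if n >= 2:
        if all(c in PATHOGENIC for c in kept):
            return ConsensusCall(key, CONSENSUS_PATHOGENIC, n)
        if all(c in BENIGN for c in kept):
            return ConsensusCall(key, CONSENSUS_BENIGN, n)
        if any(c in PATHOGENIC for c in kept):
            return ConsensusCall(key, CONFLICTING, n)
        return ConsensusCall(key, NO_TRUSTED_ASSERTION, n)
    if n == 1 and kept[0] in PATHOGENIC:
        return ConsensusCall(key, SINGLE_SUBMITTER_PATHOGENIC, n)
    return ConsensusCall(key, NO_TRUSTED_ASSERTION, n)


def classify_all(
    records: Iterable[SubmissionRecord], trusted: Iterable[str]
) -> dict[tuple, ConsensusCall]:
    """Group records by variant and aggregate each group."""
    by_key: dict[tuple, list[SubmissionRecord]] = {}
    for r in records:
        by_key.setdefault(r.key, []).append(r)
    trusted = set(trusted)
    return {k: consensus_classification(v, trusted) for k, v in by_key.items()}


def assemble_pathogenic_set(
    calls: Iterable[ConsensusCall],
    adjudications: Iterable[AdjudicationRecord] = (),
    nmd_status: Optional[Mapping[tuple, str]] = None,
    lof_mechanism_genes: Iterable[str] = (),
    variant_genes: Optional[Mapping[tuple, str]] = None,
) -> dict[tuple, frozenset[str]]:
    """The analysis pathogenic set, tagged with each member's provenance.

    Members come from (a) consensus-pathogenic calls (tag
    ``clinvar_consensus``); (b) single-submitter or conflicting calls
    adjudicated P/LP externally (tag ``adjudicated``); (c) NMD-positive
    variants in loss-of-function-mechanism genes (tag ``nmd_positive``).
    An adjudication for a variant already at consensus is ignored with a
    warning (consensus wins). Idempotent and order-independent.
    """
    status_by_key = {c.key: c.status for c in calls}
    tags: dict[tuple, set[str]] = {}

    for key, status in status_by_key.items():
        if status == CONSENSUS_PATHOGENIC:
            tags.setdefault(key, set()).add("clinvar_consensus")

    for adj in adjudications:
        status = status_by_key.get(adj.key)
        if status == CONSENSUS_PATHOGENIC:
            logger.warning(
                "adjudication supplied for %s, already at consensus; ignored",
                adj.key,
            )
            continue
        if status in (SINGLE_SUBMITTER_PATHOGENIC, CONFLICTING) and (
            adj.classification in PATHOGENIC
        ):
            tags.setdefault(adj.key, set()).add("adjudicated")

    if nmd_status is not None:
        lof = set(lof_mechanism_genes)
        genes = variant_genes or {}
        for key, status in nmd_status.items():
            if status == "NMD_positive" and genes.get(key) in lof:
                tags.setdefault(key, set()).add("nmd_positive")

    return {k: frozenset(v) for k, v in tags.items()}
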