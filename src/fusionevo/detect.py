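"""Fusion-candidate detection from query-vs-subject protein alignments.

A pair of query genes is a fusion candidate on a subject protein when,
after per-alignment filtering, the two genes' merged alignment regions on
the subject protein overlap by no more than a small number of residues
(default 5 aa).  The merged region of a gene is the union over all of its
isoforms' subject-coordinate intervals.  A candidate is discarded when a
third gene's merged region covers both pair regions (containment), and
flagged for manual resolution when more than two genes map to the subject
protein without such containment.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GenePair, canonical_pair
from .align import ProteinAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionThresholds:
    """Alignment acceptance thresholds.

    * ``min_align_len`` — minimum alignment length in amino acids
      (inclusive, default 20).
    * ``max_region_overlap`` — maximum overlap between the two genes'
      merged regions, in amino acids (inclusive, default 5).
    * ``max_evalue`` — e-value cutoff (inclusive, default 0.1).
    * ``min_identity_by_species`` — percent-identity threshold per subject
      species; alignments must be strictly above it.
    """

    min_align_len: int = 20
    max_region_overlap: int = 5
    max_evalue: float = 0.1
    min_identity_by_species: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_align_len < 0 or self.max_region_overlap < 0 \
                or self.max_evalue < 0:
            raise ValueError("thresholds must be nonnegative")

    def min_identity(self, species: str) -> float:
        try:
            return self.min_identity_by_species[species]
        except KeyError:
            raise KeyError(
                f"no identity threshold configured for species {species!r}"
            ) from None


class CandidateStatus(str, Enum):
    ACCEPTED = "ACCEPTED"
    DISCARDED_CONTAINMENT = "DISCARDED_CONTAINMENT"
    FLAG_MANUAL = "FLAG_MANUAL"


@dataclass(frozen=True)
class MergedRegion:
    """Union of one gene's isoform alignment intervals on a subject protein."""

    query_gene: str
    subject_protein: str
    intervals: tuple[tuple[int, int], ...]  # disjoint, sorted, 1-based inclusive

    @property
    def covered_aa(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def positions(self) -> set[int]:
        return {p for s, e in self.intervals for p in range(s, e + 1)}


@dataclass(frozen=True)
class FusionCandidate:
    subject_protein: str
    gene_pair: GenePair
    region_a: MergedRegion
    region_b: MergedRegion
    overlap_aa: int
    status: CandidateStatus


def filter_alignments(alignments: Iterable[ProteinAlignment],
                      thresholds: DetectionThresholds,
                      drop_counts: Counter | None = None,
                      ) -> list[ProteinAlignment]:
    """Apply the per-alignment criteria: length >= min_align_len,
    e-value <= max_evalue (inclusive) and identity strictly above the
    species threshold.  ``drop_counts`` collects per-criterion drops."""
    kept = []
    counts = drop_counts if drop_counts is not None else Counter()
    for a in alignments:
        if a.align_len < thresholds.min_align_len:
            counts["align_len"] += 1
            continue
        if a.e_value > thresholds.max_evalue:
            counts["evalue"] += 1
            continue
        if a.pct_identity <= thresholds.min_identity(a.subject_species):
            counts["identity"] += 1
            continue
        kept.append(a)
    return kept


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:  # abutting intervals merge
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def merge_regions(alignments: Sequence[ProteinAlignment]) -> MergedRegion:
    """Union the subject-coordinate intervals of one gene's isoform
    alignments onto one subject protein."""
    if not alignments:
        raise ValueError("merge_regions requires at least one alignment")
    genes = {a.query_gene for a in alignments}
    subjects = {a.subject_protein for a in alignments}
    if len(genes) != 1 or len(subjects) != 1:
        raise ValueError("alignments must share query gene and subject protein")
    intervals = _merge_intervals([(a.s_start, a.s_end) for a in alignments])
    return MergedRegion(genes.pop(), subjects.pop(), intervals)


def _interval_overlap(r1: MergedRegion, r2: MergedRegion) -> int:
    """Total amino acids in the intersection of two interval unions."""
    total = 0
    for s1, e1 in r1.intervals:
        for s2, e2 in r2.intervals:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def _covers(outer: MergedRegion, inner: MergedRegion) -> bool:
    """True when ``outer`` covers every position of ``inner``."""
    return inner.positions() <= outer.positions()


def detect_fusion_candidates(alignments: Iterable[ProteinAlignment],
                             thresholds: DetectionThresholds,
                             *, strict_superset: bool = False,
                             ) -> list[FusionCandidate]:
    """Find query-gene pairs mapping to a single subject protein in
    near-disjoint regions.

    ``alignments`` must already have passed :func:`filter_alignments`.
    With ``strict_superset`` the containment rule requires the third
    gene's region to be a strict superset of the union of both pair
    regions rather than merely covering it.
    """
    by_subject: dict[str, dict[str, list[ProteinAlignment]]] = defaultdict(
        lambda: defaultdict(list))
    for a in alignments:
        by_subject[a.subject_protein][a.query_gene].append(a)

    candidates: list[FusionCandidate] = []
    for subject in sorted(by_subject):
        regions = {g: merge_regions(als)
                   for g, als in by_subject[subject].items()}
        genes = sorted(regions)
        if len(genes) < 2:
            continue
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:]:
                ra, rb = regions[ga], regions[gb]
                overlap = _interval_overlap(ra, rb)
                if overlap > thresholds.max_region_overlap:
                    continue
                status = CandidateStatus.ACCEPTED
                pair_positions = ra.positions() | rb.positions()
                for gc in genes:
                    if gc in (ga, gb):
                        continue
                    rc = regions[gc]
                    covered = pair_positions <= rc.positions()
                    if strict_superset:
                        covered = covered and rc.positions() != pair_positions
                    if covered:
                        status = CandidateStatus.DISCARDED_CONTAINMENT
                        break
                if status is CandidateStatus.ACCEPTED and len(genes) > 2:
                    status = CandidateStatus.FLAG_MANUAL
                candidates.append(FusionCandidate(
                    subject, GenePair(ga, gb), ra, rb, overlap, status))
    return candidates


def candidates_to_frame(candidates: Iterable[FusionCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "subject_protein": c.subject_protein,
            "gene_a": c.gene_pair.gene_a,
            "gene_b": c.gene_pair.gene_b,
            "region_a": ";".join(f"{s}-{e}" for s, e in c.region_a.intervals),
            "region_b": ";".join(f"{s}-{e}" for s, e in c.region_b.intervals),
            "overlap_aa": c.overlap_aa,
            "status": c.status.value,
        })
    return pd.DataFrame(rows, columns=["subject_protein", "gene_a", "gene_b",
                                       "region_a", "region_b", "overlap_aa",
                                       "status"])
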