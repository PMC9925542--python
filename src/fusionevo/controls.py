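"""Distance-matched randomized control pairs.

Two control constructions are provided, both matching the focal list's
intra-pair gene-count distance distribution at a configurable multiplier
(default 10x):

* genomic controls — for each focal same-chromosome pair at distance d,
  random coding genes are drawn and paired with the coding gene d+1 ranks
  downstream on the same chromosome; draws that fall off the chromosome
  end are rejected and redrawn.  Cross-chromosome focal pairs get uniform
  random cross-chromosome gene pairs.
* pool controls — for each focal pair, pairs of identical distance are
  sampled without replacement from a supplied pool of known-interacting,
  fusion-unrelated pairs.

"Without repetition" is enforced within each focal pair's draws; when a
stratum cannot supply the full multiplier, all available pairs are used.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (DIFFERENT_CHROMOSOME, GenePair, GenomeAnnotation,
                     distance_label)

logger = logging.getLogger(__name__)

#: Rejection-resampling guard for degenerate annotations.
MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class ControlDraw:
    focal_index: int
    draw_index: int
    pair: GenePair


@dataclass
class ControlSet:
    """A focal pair list together with its distance-matched control draws."""

    focal_pairs: list[GenePair]
    draws: list[ControlDraw]
    multiplier: int
    seed: int | None = None

    @property
    def control_pairs(self) -> list[GenePair]:
        return [d.pair for d in self.draws]

    def to_frame(self) -> pd.DataFrame:
        rows = [(d.focal_index, d.draw_index, d.pair.gene_a, d.pair.gene_b,
                 distance_label(d.pair.distance), d.pair.category.value)
                for d in self.draws]
        return pd.DataFrame(rows, columns=["focal_id", "draw", "gene_a",
                                           "gene_b", "distance", "category"])


def _draw_same_chromosome(annotation: GenomeAnnotation, d: int,
                          rng: np.random.Generator) -> GenePair | None:
    coding = annotation.coding_genes()
    g = coding[int(rng.integers(len(coding)))]
    partner = annotation.gene_at_rank(g.chromosome, g.rank + d + 1)
    if partner is None:  # fell off the chromosome end
        return None
    return annotation.make_pair(g.gene_id, partner.gene_id)


def _draw_cross_chromosome(annotation: GenomeAnnotation,
                           rng: np.random.Generator) -> GenePair | None:
    coding = annotation.coding_genes()
    i, j = rng.integers(len(coding), size=2)
    a, b = coding[int(i)], coding[int(j)]
    if a.chromosome == b.chromosome:
        return None
    return annotation.make_pair(a.gene_id, b.gene_id)


def sample_genomic_controls(focal_pairs: Sequence[GenePair],
                            annotation: GenomeAnnotation,
                            multiplier: int = 10,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> ControlSet:
    """Draw genome-wide distance-matched control pairs, ``multiplier``
    distinct draws per focal pair."""
    if len(annotation.coding_genes()) < 2:
        raise ValueError("annotation must contain at least 2 coding genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws: list[ControlDraw] = []
    for idx, focal in enumerate(focal_pairs):
        chosen: set[tuple[str, str]] = set()
        attempts = 0
        while len(chosen) < multiplier and attempts < MAX_ATTEMPTS:
            attempts += 1
            if focal.distance is DIFFERENT_CHROMOSOME:
                pair = _draw_cross_chromosome(annotation, rng)
            else:
                pair = _draw_same_chromosome(annotation, int(focal.distance), rng)
            if pair is None or pair.key in chosen or pair.key == focal.key:
                continue
            chosen.add(pair.key)
            draws.append(ControlDraw(idx, len(chosen) - 1, pair))
        if len(chosen) < multiplier:
            logger.info("focal pair %s: only %d/%d control pairs available",
                        focal.key, len(chosen), multiplier)
    return ControlSet(list(focal_pairs), draws, multiplier, seed)


def sample_pool_controls(focal_pairs: Sequence[GenePair],
                         pool_pairs: Sequence[GenePair],
                         multiplier: int = 10,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> ControlSet:
    """Sample distance-matched controls from an interaction pool.

    The pool is stratified by exact distance (cross-chromosome pairs form
    one stratum); each focal pair draws up to ``multiplier`` distinct pool
    pairs from its stratum, uniformly without replacement.  Pool pairs
    may repeat across focal pairs but never within one focal pair's draws.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    focal_keys = {p.key for p in focal_pairs}
    strata: dict[object, list[GenePair]] = defaultdict(list)
    for p in pool_pairs:
        if p.key in focal_keys:
            continue  # pool must be disjoint from the focal list
        strata[distance_label(p.distance)].append(p)
    draws: list[ControlDraw] = []
    for idx, focal in enumerate(focal_pairs):
        stratum = strata.get(distance_label(focal.distance), [])
        if not stratum:
            logger.info("no pool pairs at distance %s for focal %s",
                        distance_label(focal.distance), focal.key)
            continue
        k = min(multiplier, len(stratum))
        take = rng.choice(len(stratum), size=k, replace=False)
        for j, t in enumerate(sorted(int(x) for x in take)):
            draws.append(ControlDraw(idx, j, stratum[t]))
    return ControlSet(list(focal_pairs), draws, multiplier, seed)


def distance_histogram(pairs: Sequence[GenePair]) -> dict[str, int]:
    """Counts of pairs per exact distance value (``DC`` pooled)."""
    out: dict[str, int] = defaultdict(int)
    for p in pairs:
        out[distance_label(p.distance)] += 1
    return dict(out)
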