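"""Per-pair interaction measures.

Each measure is symmetric in the pair and returns ``None`` (missing) when
its inputs are unavailable for a gene; downstream tests exclude missing
pairs rather than zero-filling them.

* co-expression — Spearman correlation, either looked up from a
  precomputed score table or computed from an expression matrix with two
  aggregation methods (within-tissue across donors then averaged over
  tissues, or across tissue-level donor means).
* same-TAD presence — the number of independent TAD coordinate lists in
  which both genes fall entirely inside one domain.
* co-localization — whether any protein product of one gene shares a
  subcellular compartment term with any product of the other.
* cancer-fusion overlap — synonym-aware unordered membership of the pair
  in a list of cancer fusion pairs.
"""
from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (DIFFERENT_CHROMOSOME, GenePair, GenomeAnnotation,
                     canonical_pair)

logger = logging.getLogger(__name__)

#: Germline tissues excluded from the soma-only co-expression analysis.
GERMLINE_TISSUES = ("testis", "ovary")


# ---------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation with midranks for ties.

    Positions missing (NaN) in either vector are dropped first; returns
    ``None`` when fewer than 3 positions remain or either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return None
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector in spearman_rho; returning missing")
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus per-sample tissue/donor labels."""

    values: pd.DataFrame            # index: gene, columns: sample ids
    sample_meta: pd.DataFrame       # index: sample ids; columns tissue, donor

    def __post_init__(self):
        if not set(self.values.columns) <= set(self.sample_meta.index):
            raise ValueError("every sample column needs tissue/donor metadata")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")

    def tissues(self) -> list[str]:
        return sorted(self.sample_meta.loc[self.values.columns, "tissue"].unique())

    def samples_for_tissue(self, tissue: str) -> list[str]:
        meta = self.sample_meta.loc[self.values.columns]
        return list(meta.index[meta["tissue"] == tissue])

    @classmethod
    def from_files(cls, matrix_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    def write(self, matrix_path, meta_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.sample_meta.to_csv(meta_path, sep="\t")


def coexpression_gtex(pair: GenePair, matrix: ExpressionMatrix,
                      method: str = "per_tissue_mean",
                      exclude_tissues: Sequence[str] = (),
                      min_donors: int = 10) -> float | None:
    """Two-method Spearman co-expression from a tissue/donor expression
    matrix.

    ``per_tissue_mean`` computes the within-tissue Spearman across donors
    and averages it over tissues; ``tissue_profile`` computes one Spearman
    across tissues of the donor-averaged expression.  Tissues with fewer
    than ``min_donors`` samples, and any in ``exclude_tissues``, are
    dropped first.  Returns ``None`` when no usable data remain.
    """
    for g in pair.key:
        if g not in matrix.values.index:
            return None
    excluded = {t.lower() for t in exclude_tissues}
    usable = [t for t in matrix.tissues()
              if t.lower() not in excluded
              and len(matrix.samples_for_tissue(t)) >= min_donors]
    xa = matrix.values.loc[pair.gene_a]
    xb = matrix.values.loc[pair.gene_b]
    if method == "per_tissue_mean":
        rhos = []
        for t in usable:
            cols = matrix.samples_for_tissue(t)
            rho = spearman_rho(xa[cols].to_numpy(), xb[cols].to_numpy())
            if rho is not None:
                rhos.append(rho)
        return float(np.mean(rhos)) if rhos else None
    if method == "tissue_profile":
        if len(usable) < 2:
            return None
        prof_a = [xa[matrix.samples_for_tissue(t)].mean() for t in usable]
        prof_b = [xb[matrix.samples_for_tissue(t)].mean() for t in usable]
        return spearman_rho(prof_a, prof_b)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------
# TADs
# ---------------------------------------------------------------------

@dataclass
class TadList:
    """One experiment's TAD coordinates: chromosome -> sorted [start, end)
    half-open domains (BED convention)."""

    list_id: str
    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self):
        for chrom, ivs in self.intervals.items():
            ivs.sort()
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"{self.list_id}/{chrom}: empty domain [{s},{e})")

    @classmethod
    def from_bed(cls, path, list_id: str | None = None) -> "TadList":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        intervals: dict[str, list[tuple[int, int]]] = {}
        for r in df.itertuples(index=False):
            intervals.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
        return cls(list_id or str(path), intervals)

    def contains_gene(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Domains [s, e) with s <= start and end < e (whole-gene
        containment)."""
        return [(s, e) for s, e in self.intervals.get(chrom, [])
                if s <= start and end < e]


def tad_copresence_count(pair: GenePair, tad_lists: Sequence[TadList],
                         annotation: GenomeAnnotation) -> int:
    """Number of TAD lists in which both genes lie entirely within one
    common domain.  Cross-chromosome pairs are outside this analysis."""
    ga, gb = annotation[pair.gene_a], annotation[pair.gene_b]
    if ga.chromosome != gb.chromosome:
        raise ValueError(
            "tad_copresence_count is defined for same-chromosome pairs only; "
            "exclude DC pairs upstream")
    n = 0
    for tl in tad_lists:
        doms_a = set(tl.contains_gene(ga.chromosome, ga.start, ga.end))
        doms_b = set(tl.contains_gene(gb.chromosome, gb.start, gb.end))
        if doms_a & doms_b:
            n += 1
    return n


# ---------------------------------------------------------------------
# co-localization
# ---------------------------------------------------------------------

def load_localization_map(path_or_buffer) -> dict[str, frozenset[str]]:
    """Two-column TSV (gene, compartment term) -> gene term sets."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:2])
    out: dict[str, set[str]] = {}
    for g, t in df[cols].itertuples(index=False):
        out.setdefault(str(g), set()).add(str(t))
    return {g: frozenset(ts) for g, ts in out.items()}


def is_colocalized(pair: GenePair,
                   localization_map: Mapping[str, frozenset[str]],
                   ) -> bool | None:
    """True when the two genes' products share any compartment term;
    ``None`` (excluded) when either gene is unmapped."""
    terms_a = localization_map.get(pair.gene_a)
    terms_b = localization_map.get(pair.gene_b)
    if not terms_a or not terms_b:
        return None
    return bool(terms_a & terms_b)


# ---------------------------------------------------------------------
# cancer-fusion overlap
# ---------------------------------------------------------------------

def load_symbol_pairs(path_or_buffer, case_insensitive: bool = True,
                      ) -> set[tuple[str, str]]:
    """Two-column TSV of (symbol_a, symbol_b) cancer fusion pairs."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:2])
    out = set()
    for a, b in df[cols].itertuples(index=False):
        a, b = str(a), str(b)
        if case_insensitive:
            a, b = a.lower(), b.lower()
        if a != b:
            out.add(canonical_pair(a, b))
    return out


def load_synonym_map(path_or_buffer) -> dict[str, set[str]]:
    """TSV (symbol, gene_id) -> gene_id to full symbol set (including the
    gene id itself as identity fallback)."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:2])
    out: dict[str, set[str]] = {}
    for sym, gid in df[cols].itertuples(index=False):
        out.setdefault(str(gid), {str(gid)}).add(str(sym))
    return out


def is_cancer_overlap(pair: GenePair, cancer_pairs: set[tuple[str, str]],
                      synonym_map: Mapping[str, set[str]] | None = None,
                      case_insensitive: bool = True) -> bool:
    """True when any symbol of one gene pairs with any symbol of the other
    in the cancer fusion list (unordered)."""
    syn = synonym_map or {}
    symbols_a = set(syn.get(pair.gene_a, {pair.gene_a}))
    symbols_b = set(syn.get(pair.gene_b, {pair.gene_b}))
    if case_insensitive:
        symbols_a = {s.lower() for s in symbols_a}
        symbols_b = {s.lower() for s in symbols_b}
    for sa in symbols_a:
        for sb in symbols_b:
            if sa != sb and canonical_pair(sa, sb) in cancer_pairs:
                return True
    return False


# ---------------------------------------------------------------------
# pair score tables
# ---------------------------------------------------------------------

def load_pair_scores(path_or_buffer) -> dict[tuple[str, str], float]:
    """Three-column TSV (gene_a, gene_b, score) keyed by canonical pair."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:3])
    out: dict[tuple[str, str], float] = {}
    for a, b, s in df[cols].itertuples(index=False):
        out[canonical_pair(str(a), str(b))] = float(s)
    return out


def write_pair_scores(scores: Mapping[tuple[str, str], float], path) -> None:
    rows = [(a, b, s) for (a, b), s in scores.items()]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False)


def lookup_score(pair: GenePair,
                 table: Mapping[tuple[str, str], float]) -> float | None:
    return table.get(pair.key)
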