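"""Gene order on chromosomes and the gene-count genomic distance.

The genomic distance between two genes is measured as the number of
protein-coding genes strictly between them on the chromosome (the rank
difference minus one), with a dedicated sentinel for pairs on different
chromosomes.  Distances are binned into the standard categories used in
the enrichment reports: SC_0 (adjacent), SC_1-99, SC_100-499, SC_500+
and DC (different chromosomes).

Coordinates in input files are 1-based inclusive (NCBI feature-table
convention); only protein-coding genes receive ranks and only they count
toward distance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


class _DifferentChromosome:
    """Singleton sentinel for cross-chromosome pair distances."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "DIFFERENT_CHROMOSOME"

    def __reduce__(self):
        return (_DifferentChromosome, ())


#: Sentinel distance value for pairs whose members sit on different chromosomes.
DIFFERENT_CHROMOSOME = _DifferentChromosome()


class DistanceCategory(str, Enum):
    """Distance bins used for all stratified comparisons."""

    SC_0 = "SC_0"
    SC_1_99 = "SC_1_99"
    SC_100_499 = "SC_100_499"
    SC_500_PLUS = "SC_500_PLUS"
    DC = "DC"


#: Report row order: overall, same-chromosome aggregate, the four
#: same-chromosome bins, then different chromosomes.
GROUP_ORDER = (
    "All pairs",
    "Same chromosome",
    DistanceCategory.SC_0.value,
    DistanceCategory.SC_1_99.value,
    DistanceCategory.SC_100_499.value,
    DistanceCategory.SC_500_PLUS.value,
    DistanceCategory.DC.value,
)


def categorize_distance(d) -> DistanceCategory:
    """Map a gene-count distance (or the DC sentinel) to its category."""
    if d is DIFFERENT_CHROMOSOME:
        return DistanceCategory.DC
    d = int(d)
    if d < 0:
        raise ValueError(f"negative distance: {d}")
    if d == 0:
        return DistanceCategory.SC_0
    if d <= 99:
        return DistanceCategory.SC_1_99
    if d <= 499:
        return DistanceCategory.SC_100_499
    return DistanceCategory.SC_500_PLUS


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-insensitive key for an unordered gene pair.

    Raises ``ValueError`` for a self-pair.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: location, strand, coding flag and (for coding genes) the
    ordinal rank among coding genes on its chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    coding: bool = True
    rank: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GenePair:
    """Canonical unordered gene pair with its genomic distance."""

    gene_a: str
    gene_b: str
    distance: object = None  # int or DIFFERENT_CHROMOSOME or None (unknown)
    category: DistanceCategory | None = None

    def __post_init__(self):
        a, b = canonical_pair(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        if self.distance is not None and self.category is None:
            object.__setattr__(self, "category", categorize_distance(self.distance))

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def __eq__(self, other):
        return isinstance(other, GenePair) and self.key == other.key

    def __hash__(self):
        return hash(self.key)


class GenomeAnnotation:
    """Ordered collection of gene annotations.

    Coding genes on each chromosome are ranked 1..n by start coordinate
    (ties broken by end, then gene id); non-coding genes are retained but
    unranked and invisible to the distance measure.
    """

    def __init__(self, genes: Iterable[GeneAnnotation]):
        raw = list(genes)
        seen: set[str] = set()
        for g in raw:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            seen.add(g.gene_id)
        self._genes: dict[str, GeneAnnotation] = {}
        self._by_chrom: dict[str, list[GeneAnnotation]] = {}
        coding_by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in raw:
            if g.coding:
                coding_by_chrom.setdefault(g.chromosome, []).append(g)
            else:
                self._genes[g.gene_id] = g
        for chrom, gl in coding_by_chrom.items():
            gl.sort(key=lambda g: (g.start, g.end, g.gene_id))
            ranked = [
                GeneAnnotation(g.gene_id, g.chromosome, g.start, g.end, g.strand,
                               True, rank=i + 1)
                for i, g in enumerate(gl)
            ]
            self._by_chrom[chrom] = ranked
            for g in ranked:
                self._genes[g.gene_id] = g

    # -- access -------------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene: {gene_id}") from None

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def coding_genes(self, chromosome: str | None = None) -> list[GeneAnnotation]:
        if chromosome is not None:
            return list(self._by_chrom.get(chromosome, []))
        return [g for c in sorted(self._by_chrom) for g in self._by_chrom[c]]

    def gene_at_rank(self, chromosome: str, rank: int) -> GeneAnnotation | None:
        gl = self._by_chrom.get(chromosome, [])
        if 1 <= rank <= len(gl):
            return gl[rank - 1]
        return None

    # -- distance -----------------------------------------------------
    def _ranked(self, gene_id: str) -> GeneAnnotation:
        g = self[gene_id]
        if not g.coding or g.rank is None:
            raise ValueError(f"gene {gene_id} is not a ranked coding gene")
        return g

    def intergenic_count(self, gene_a: str, gene_b: str):
        """Number of coding genes strictly between the two genes, or the
        DIFFERENT_CHROMOSOME sentinel."""
        a = self._ranked(gene_a)
        b = self._ranked(gene_b)
        if a.chromosome != b.chromosome:
            return DIFFERENT_CHROMOSOME
        return abs(a.rank - b.rank) - 1

    def make_pair(self, gene_a: str, gene_b: str) -> GenePair:
        d = self.intergenic_count(gene_a, gene_b)
        return GenePair(gene_a, gene_b, distance=d)


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

TSV_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "coding"]


def load_annotation(path_or_buffer) -> GenomeAnnotation:
    """Read a gene feature table (TSV with header gene_id, chromosome,
    start, end, strand, coding).

    Rows with start > end are dropped with a logged warning; duplicate
    gene ids are an error.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"chromosome": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start > end:
            logger.warning("dropping %s: start %d > end %d", row.gene_id, start, end)
            continue
        coding = row.coding in (True, 1, "1", "true", "True", "yes")
        genes.append(GeneAnnotation(str(row.gene_id), str(row.chromosome),
                                    start, end, str(row.strand), coding))
    return GenomeAnnotation(genes)


def load_annotation_gff3(path) -> GenomeAnnotation:
    """Read gene features from GFF3, treating ``gene_biotype=protein_coding``
    (or ``biotype=protein_coding``) as the coding flag."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene"):
        biotype = (feat.attributes.get("gene_biotype")
                   or feat.attributes.get("biotype") or [""])[0]
        gid = (feat.attributes.get("ID") or feat.attributes.get("gene_id")
               or [feat.id])[0]
        genes.append(GeneAnnotation(gid, feat.seqid, feat.start, feat.end,
                                    feat.strand or "+",
                                    biotype == "protein_coding"))
    return GenomeAnnotation(genes)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    rows = []
    for chrom in annotation.chromosomes:
        for g in annotation.coding_genes(chrom):
            rows.append((g.gene_id, g.chromosome, g.start, g.end, g.strand, 1))
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def distance_label(d) -> str:
    """Serialize a distance for TSV output (``DC`` for cross-chromosome)."""
    return "DC" if d is DIFFERENT_CHROMOSOME else str(int(d))


def parse_distance_label(s: str):
    return DIFFERENT_CHROMOSOME if s == "DC" else int(s)


def load_pair_list(path_or_buffer, annotation: GenomeAnnotation | None = None,
                   ) -> list[GenePair]:
    """Read a two-column (gene_a, gene_b) TSV into canonical pairs,
    de-duplicated, computing distances when an annotation is given."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:2])
    out: dict[tuple[str, str], GenePair] = {}
    for a, b in df[cols].itertuples(index=False):
        a, b = str(a), str(b)
        if a == b:
            continue
        key = canonical_pair(a, b)
        if key in out:
            continue
        if annotation is not None:
            out[key] = annotation.make_pair(a, b)
        else:
            out[key] = GenePair(a, b)
    return list(out.values())
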