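"""Protein local alignment: built-in Smith-Waterman and tabular readers.

The built-in aligner is exact Smith-Waterman (via Bio.Align.PairwiseAligner)
under BLOSUM62 with affine gap penalties (open 11, extend 1), reporting
percent identity over aligned columns and a Karlin-Altschul e-value
E = K * m * n * exp(-lambda * S) with gapped constants.  Unknown residues
(X, and the ambiguity codes B/Z) score 0 against everything.

External alignments are read from the 12-column BLAST tabular dialect
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) together with a two-column protein-to-gene map.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

#: Gapped Karlin-Altschul constants for BLOSUM62 with open 11 / extend 1.
LAMBDA = 0.267
K = 0.041

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteinAlignment:
    """One local alignment of a query isoform onto a subject protein.

    Coordinates are 1-based inclusive on both sequences.
    """

    query_protein: str
    query_gene: str
    subject_protein: str
    subject_species: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    align_len: int
    pct_identity: float
    e_value: float
    score: float

    def __post_init__(self):
        if self.s_start > self.s_end:
            raise ValueError("s_start > s_end")
        if self.align_len < 1:
            raise ValueError("align_len < 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of [0, 100]")
        if self.e_value < 0:
            raise ValueError("negative e_value")


@lru_cache(maxsize=1)
def _blosum62_x0():
    """BLOSUM62 with X/B/Z (and *) rows and columns zeroed."""
    mat = substitution_matrices.load("BLOSUM62").copy()
    for c in "XBZ*":
        for other in mat.alphabet:
            mat[c, other] = 0.0
            mat[other, c] = 0.0
    return mat


@lru_cache(maxsize=1)
def _aligner(open_gap: float = -11.0, extend_gap: float = -1.0):
    al = Align.PairwiseAligner(mode="local",
                               substitution_matrix=_blosum62_x0(),
                               open_gap_score=open_gap,
                               extend_gap_score=extend_gap)
    return al


def evalue(score: float, m: int, n: int,
           lam: float = LAMBDA, k: float = K) -> float:
    """Karlin-Altschul expectation for a local alignment score."""
    return k * m * n * math.exp(-lam * score)


def local_align(query_seq: str, subject_seq: str, *,
                query_protein: str = "query", query_gene: str = "query",
                subject_protein: str = "subject",
                subject_species: str = "subject",
                ) -> ProteinAlignment | None:
    """Best Smith-Waterman local alignment of two amino-acid sequences.

    Returns ``None`` when no positively scoring local alignment exists.
    Raises ``ValueError`` on empty input.
    """
    if not query_seq or not subject_seq:
        raise ValueError("empty sequence")
    al = _aligner()
    alignments = al.align(query_seq, subject_seq)
    if alignments.score <= 0:
        return None
    best = alignments[0]
    return _alignment_record(best, query_seq, subject_seq,
                             query_protein, query_gene,
                             subject_protein, subject_species)


def _alignment_record(best, query_seq, subject_seq, query_protein,
                      query_gene, subject_protein, subject_species):
    qblocks, sblocks = best.aligned
    q_start = int(qblocks[0][0])
    q_end = int(qblocks[-1][1])
    s_start = int(sblocks[0][0])
    s_end = int(sblocks[-1][1])
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_cols += qe - qs
        for i in range(qe - qs):
            if query_seq[qs + i] == subject_seq[ss + i]:
                matches += 1
    # gap columns contribute to alignment length, blast-style
    gap_cols = (q_end - q_start - aligned_cols) + (s_end - s_start - aligned_cols)
    align_len = aligned_cols + gap_cols
    pct = 100.0 * matches / align_len if align_len else 0.0
    score = float(best.score)
    ev = evalue(score, len(query_seq), len(subject_seq))
    return ProteinAlignment(query_protein, query_gene, subject_protein,
                            subject_species,
                            q_start + 1, q_end, s_start + 1, s_end,
                            align_len, pct, ev, score)


def align_proteomes(queries: Mapping[str, str], subjects: Mapping[str, str],
                    protein_to_gene: Mapping[str, str],
                    subject_species: str = "subject", *,
                    min_score: float | None = None,
                    max_evalue: float | None = None,
                    ) -> list[ProteinAlignment]:
    """All-vs-all best local alignments of query isoforms onto subject
    proteins.

    A score-only pass prunes pairs before traceback; with ``max_evalue``
    set, the pruning threshold is the exact score at which the e-value
    would exceed the cutoff, so no qualifying alignment is lost.
    """
    al = _aligner()
    out: list[ProteinAlignment] = []
    for qid, qseq in queries.items():
        gene = protein_to_gene.get(qid, qid)
        for sid, sseq in subjects.items():
            score = al.score(qseq, sseq)
            if score <= 0:
                continue
            threshold = min_score if min_score is not None else 0.0
            if max_evalue is not None:
                # E <= max_evalue  <=>  S >= ln(K m n / E) / lambda
                s_cut = math.log(K * len(qseq) * len(sseq) / max_evalue) / LAMBDA
                threshold = max(threshold, s_cut)
            if score < threshold:
                continue
            best = al.align(qseq, sseq)[0]
            out.append(_alignment_record(best, qseq, sseq, qid, gene, sid,
                                         subject_species))
    return out


# ---------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------

TABULAR_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def read_tabular_alignments(path_or_buffer, protein_to_gene: Mapping[str, str],
                            subject_species: str = "subject",
                            ) -> list[ProteinAlignment]:
    """Read BLAST outfmt-6-style alignments (no header, 12 columns)."""
    df = pd.read_csv(path_or_buffer, sep="\t", names=TABULAR_COLUMNS,
                     comment="#")
    out = []
    for r in df.itertuples(index=False):
        qid = str(r.qseqid)
        out.append(ProteinAlignment(
            qid, protein_to_gene.get(qid, qid), str(r.sseqid),
            subject_species, int(r.qstart), int(r.qend),
            int(r.sstart), int(r.send), int(r.length),
            float(r.pident), float(r.evalue), float(r.bitscore)))
    return out


def write_tabular_alignments(alignments: Iterable[ProteinAlignment], path) -> None:
    rows = [(a.query_protein, a.subject_protein, round(a.pct_identity, 2),
             a.align_len, "", "", a.q_start, a.q_end, a.s_start, a.s_end,
             a.e_value, a.score) for a in alignments]
    pd.DataFrame(rows, columns=TABULAR_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False)


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n")
            seq = seqs[sid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_protein_gene_map(path_or_buffer) -> dict[str, str]:
    """Two-column TSV (protein_id, gene_id)."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    cols = list(df.columns[:2])
    return {str(p): str(g) for p, g in df[cols].itertuples(index=False)}
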