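"""End-to-end orchestration: detect -> distance -> controls -> measures
-> enrichment -> phylogeny.

Every stage reads and writes plain TSV so any stage can be rerun
standalone on user data; a JSON manifest records the seed, versions and
counts at each filtering step (including per-criterion alignment drop
counts).
"""
from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__, align, controls, detect, genome, metrics, phylo, stats
from .detect import CandidateStatus, DetectionThresholds
from .genome import DIFFERENT_CHROMOSOME, GenePair, GenomeAnnotation

logger = logging.getLogger(__name__)

ALL_MEASURES = ("coexpression", "tad", "colocalization", "cancer")


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    dataset_dir: str
    outdir: str
    seed: int = 0
    multiplier: int = 10
    thresholds: DetectionThresholds = field(
        default_factory=lambda: DetectionThresholds(
            min_identity_by_species={"SyntheticPrimate": 60.0}))
    measures: tuple[str, ...] = ALL_MEASURES
    exclude_tissues: tuple[str, ...] = ()

    def validate(self):
        d = Path(self.dataset_dir)
        if not d.is_dir():
            raise FileNotFoundError(f"dataset directory not found: {d}")
        unknown = set(self.measures) - set(ALL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


def detect_stage(config: RunConfig, outdir: Path) -> tuple[pd.DataFrame, dict]:
    """Align the query proteome onto the subject proteome and extract
    fusion candidates."""
    d = Path(config.dataset_dir)
    queries = align.read_fasta(d / "query_proteome.fasta")
    subjects = align.read_fasta(d / "subject_proteome.fasta")
    p2g = align.read_protein_gene_map(d / "protein_gene_map.tsv")
    species = next(iter(config.thresholds.min_identity_by_species))
    alignments = align.align_proteomes(queries, subjects, p2g, species,
                                       max_evalue=config.thresholds.max_evalue)
    drops: Counter = Counter()
    kept = detect.filter_alignments(alignments, config.thresholds, drops)
    candidates = detect.detect_fusion_candidates(kept, config.thresholds)
    frame = detect.candidates_to_frame(candidates)
    frame.to_csv(outdir / "fusion_candidates.tsv", sep="\t", index=False)
    info = {"n_alignments": len(alignments), "n_passing": len(kept),
            "drop_counts": dict(drops),
            "n_candidates": int((frame["status"] ==
                                 CandidateStatus.ACCEPTED.value).sum())}
    return frame, info


def _focal_pairs(config: RunConfig,
                 annotation: GenomeAnnotation) -> list[GenePair]:
    return genome.load_pair_list(Path(config.dataset_dir) / "fusion_pairs.tsv",
                                 annotation)


def controls_stage(config: RunConfig, annotation: GenomeAnnotation,
                   focal: Sequence[GenePair], outdir: Path,
                   ) -> tuple[controls.ControlSet, controls.ControlSet]:
    genomic = controls.sample_genomic_controls(
        focal, annotation, config.multiplier, seed=config.seed)
    pool = genome.load_pair_list(Path(config.dataset_dir) / "pool_pairs.tsv",
                                 annotation)
    pool_set = controls.sample_pool_controls(
        focal, pool, config.multiplier, seed=config.seed + 1)
    genomic.to_frame().to_csv(outdir / "controls_genomic.tsv", sep="\t",
                              index=False)
    pool_set.to_frame().to_csv(outdir / "controls_pool.tsv", sep="\t",
                               index=False)
    return genomic, pool_set


def _measure_values(measure: str, pairs: Sequence[GenePair],
                    config: RunConfig, annotation: GenomeAnnotation,
                    inputs: dict) -> list[tuple[GenePair, object]]:
    out = []
    for p in pairs:
        if measure == "coexpression":
            v = inputs["scores"].get(p.key)
        elif measure == "tad":
            if p.distance is DIFFERENT_CHROMOSOME:
                v = None
            else:
                v = metrics.tad_copresence_count(p, inputs["tads"], annotation)
        elif measure == "colocalization":
            v = metrics.is_colocalized(p, inputs["localization"])
        elif measure == "cancer":
            v = metrics.is_cancer_overlap(p, inputs["cancer"],
                                          inputs["synonyms"])
        else:  # pragma: no cover
            raise ValueError(measure)
        out.append((p, v))
    return out


_TEST_KIND = {"coexpression": "mannwhitney", "tad": "mannwhitney",
              "colocalization": "fisher", "cancer": "fisher"}

#: TADs are intra-chromosomal; the DC rows do not apply.
_TAD_GROUPS = ("All pairs", "Same chromosome", "SC_0", "SC_1_99",
               "SC_100_499", "SC_500_PLUS")


def enrichment_stage(config: RunConfig, annotation: GenomeAnnotation,
                     focal: Sequence[GenePair],
                     control_sets: Mapping[str, controls.ControlSet],
                     outdir: Path) -> dict[str, pd.DataFrame]:
    d = Path(config.dataset_dir)
    inputs = {
        "scores": metrics.load_pair_scores(d / "coexpression.tsv"),
        "tads": [metrics.TadList.from_bed(p, p.stem)
                 for p in sorted(d.glob("tad_*.bed"))],
        "localization": metrics.load_localization_map(d / "localization.tsv"),
        "cancer": metrics.load_symbol_pairs(d / "cancer_pairs.tsv"),
        "synonyms": metrics.load_synonym_map(d / "synonyms.tsv"),
    }
    reports: dict[str, pd.DataFrame] = {}
    for measure in config.measures:
        for cname, cset in control_sets.items():
            fvals = _measure_values(measure, focal, config, annotation, inputs)
            if measure == "tad":
                fvals = [(p, v) for p, v in fvals
                         if p.distance is not DIFFERENT_CHROMOSOME]
            cpairs = cset.control_pairs
            if measure == "tad":
                cpairs = [p for p in cpairs
                          if p.distance is not DIFFERENT_CHROMOSOME]
            cvals = _measure_values(measure, cpairs, config, annotation, inputs)
            groups = _TAD_GROUPS if measure == "tad" else genome.GROUP_ORDER
            table = stats.build_enrichment_table(fvals, cvals,
                                                 _TEST_KIND[measure],
                                                 groups=groups)
            key = f"{measure}_{cname}"
            reports[key] = table
            table.to_csv(outdir / f"enrichment_{key}.tsv", sep="\t",
                         index=False)
    return reports


def phylo_stage(config: RunConfig, outdir: Path) -> dict:
    d = Path(config.dataset_dir)
    tree_file = d / "tree.nwk"
    tree = phylo.load_tree(tree_file.read_text() if tree_file.exists()
                           else None)
    patterns = phylo.load_patterns(d / "presence_patterns.tsv", tree)
    summary = phylo.summarize_dataset(patterns, tree)
    phylo.summary_to_frame(summary).to_csv(outdir / "phylo_events.tsv",
                                           sep="\t", index=False)
    lo, hi = summary.ratio_range
    return {"n_patterns": len(patterns),
            "fusion_total_range": list(summary.fusion_total_range),
            "fission_total_range": list(summary.fission_total_range),
            "ratio_range": [lo, None if hi == float("inf") else hi]}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the JSON-serializable manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "multiplier": config.multiplier,
                      "measures": list(config.measures)}
    try:
        _, detect_info = detect_stage(config, outdir)
        manifest["detection"] = detect_info
    except Exception as exc:
        raise RuntimeError(f"[detect] stage failed: {exc}") from exc
    try:
        annotation = genome.load_annotation(
            Path(config.dataset_dir) / "annotation.tsv")
        focal = _focal_pairs(config, annotation)
        manifest["n_focal_pairs"] = len(focal)
    except Exception as exc:
        raise RuntimeError(f"[distance] stage failed: {exc}") from exc
    try:
        genomic, pool_set = controls_stage(config, annotation, focal, outdir)
        manifest["n_genomic_controls"] = len(genomic.draws)
        manifest["n_pool_controls"] = len(pool_set.draws)
    except Exception as exc:
        raise RuntimeError(f"[controls] stage failed: {exc}") from exc
    if config.measures:
        try:
            reports = enrichment_stage(config, annotation, focal,
                                       {"genomic": genomic, "pool": pool_set},
                                       outdir)
            manifest["enrichment"] = {
                k: {"min_p": (None if t["p"].dropna().empty
                              else float(t["p"].min()))}
                for k, t in reports.items()}
        except Exception as exc:
            raise RuntimeError(f"[enrich] stage failed: {exc}") from exc
    try:
        manifest["phylo"] = phylo_stage(config, outdir)
    except Exception as exc:
        raise RuntimeError(f"[phylo] stage failed: {exc}") from exc
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
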