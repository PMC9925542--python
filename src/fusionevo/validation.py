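"""Self-validation experiments on synthetic data.

These are the simulation studies the test suite and the reproduction
script share: planted-fusion recovery, type-I calibration and power of
the distance-matched enrichment test, exactness of distance matching,
and parsimony recovery of the fusion:fission ratio.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from . import align, controls, detect, phylo, simulate, stats
from .detect import CandidateStatus, DetectionThresholds
from .simulate import SimulationConfig, SUBJECT_SPECIES


def planted_fusion_recovery(config: SimulationConfig | None = None,
                            min_identity: float = 60.0) -> dict:
    """Run the full detection pipeline on a synthetic dataset with
    planted fusions; report recall and precision against the truth table.
    """
    if config is None:
        config = SimulationConfig(seed=7)
    streams = config.streams()
    annotation, cores, isoforms, p2g = simulate.generate_genome(
        config, streams["genome"])
    truth_pairs = simulate.draw_truth_pairs(config, annotation,
                                            streams["truth"])
    proteome, _ = simulate.generate_fused_proteome(
        config, annotation, cores, truth_pairs, streams["proteome"])
    thresholds = DetectionThresholds(
        min_identity_by_species={SUBJECT_SPECIES: min_identity})
    alignments = align.align_proteomes(isoforms, proteome, p2g,
                                       SUBJECT_SPECIES,
                                       max_evalue=thresholds.max_evalue)
    kept = detect.filter_alignments(alignments, thresholds)
    candidates = detect.detect_fusion_candidates(kept, thresholds)
    accepted = {c.gene_pair.key for c in candidates
                if c.status is CandidateStatus.ACCEPTED}
    truth_keys = {p.key for p in truth_pairs}
    tp = len(accepted & truth_keys)
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    precision = tp / len(accepted) if accepted else float("nan")
    return {"recall": recall, "precision": precision,
            "n_planted": len(truth_keys), "n_accepted": len(accepted)}


def _replicate_pvalue(config: SimulationConfig, annotation,
                      rng: np.random.Generator) -> float:
    """One enrichment replicate: draw focal pairs, distance-matched
    genomic controls, per-pair scores, one-sided Mann-Whitney."""
    focal = simulate.draw_truth_pairs(config, annotation, rng)
    cset = controls.sample_genomic_controls(focal, annotation,
                                            multiplier=10, rng=rng)
    truth_keys = {p.key for p in focal}
    score_cache: dict[tuple[str, str], float] = {}
    for p in list(focal) + cset.control_pairs:
        if p.key not in score_cache:
            score_cache[p.key] = simulate.pair_score(p, truth_keys, config, rng)
    x = [score_cache[p.key] for p in focal]
    y = [score_cache[p.key] for p in cset.control_pairs]
    return stats.mann_whitney_one_sided(x, y).p_one_sided


#: Replicate-study genome: enough coding genes for disjoint focal pairs.
CALIBRATION_CONFIG = dict(n_chromosomes=2, genes_per_chromosome=100,
                          n_fusion_pairs=40, interaction_effect=0.0)
POWER_CONFIG = dict(n_chromosomes=4, genes_per_chromosome=120,
                    n_fusion_pairs=200, interaction_effect=2.0)


def null_rejection_rate(n_replicates: int = 500, alpha: float = 0.05,
                        seed: int = 0,
                        config_kwargs: Mapping | None = None) -> dict:
    """Type-I error of the distance-matched test with no planted effect."""
    kwargs = dict(CALIBRATION_CONFIG)
    kwargs.update(config_kwargs or {})
    config = SimulationConfig(seed=seed, **kwargs)
    annotation, *_ = simulate.generate_genome(config)
    root = np.random.SeedSequence(seed)
    rejections = 0
    for child in root.spawn(n_replicates):
        p = _replicate_pvalue(config, annotation, np.random.default_rng(child))
        if p < alpha:
            rejections += 1
    return {"rate": rejections / n_replicates, "n": n_replicates,
            "alpha": alpha}


def power_estimate(n_seeds: int = 100, alpha: float = 0.01, seed: int = 0,
                   config_kwargs: Mapping | None = None) -> dict:
    """Power of the same test with the planted effect (delta in noise-SD
    units) switched on."""
    kwargs = dict(POWER_CONFIG)
    kwargs.update(config_kwargs or {})
    config = SimulationConfig(seed=seed, **kwargs)
    annotation, *_ = simulate.generate_genome(config)
    root = np.random.SeedSequence(seed + 1)
    rejections = 0
    for child in root.spawn(n_seeds):
        p = _replicate_pvalue(config, annotation, np.random.default_rng(child))
        if p < alpha:
            rejections += 1
    return {"power": rejections / n_seeds, "n": n_seeds, "alpha": alpha}


def distance_match_exactness(seed: int = 0,
                             config_kwargs: Mapping | None = None) -> dict:
    """Check that control distance histograms are exact multiples of the
    focal histogram when every stratum reaches the full multiplier."""
    kwargs = dict(CALIBRATION_CONFIG)
    kwargs.update(config_kwargs or {})
    config = SimulationConfig(seed=seed, **kwargs)
    streams = config.streams()
    annotation, *_ = simulate.generate_genome(config, streams["genome"])
    focal = simulate.draw_truth_pairs(config, annotation, streams["truth"])
    cset = controls.sample_genomic_controls(focal, annotation, multiplier=10,
                                            rng=streams["controls"])
    fh = controls.distance_histogram(focal)
    ch = controls.distance_histogram(cset.control_pairs)
    full = len(cset.draws) == 10 * len(focal)
    exact = full and all(ch.get(k, 0) == 10 * v for k, v in fh.items())
    return {"full_multiplier": full, "exact_match": exact,
            "n_focal": len(focal), "n_controls": len(cset.draws)}


def parsimony_ratio_recovery(n_patterns: int = 1000, seed: int = 11,
                             config_kwargs: Mapping | None = None) -> dict:
    """Simulate gain-dominated histories on the primate tree and compare
    the parsimony-inferred fusion:fission totals with the truth."""
    kwargs = dict(config_kwargs or {})
    config = SimulationConfig(seed=seed, **kwargs)
    tree = phylo.load_tree()
    patterns, truth = simulate.generate_presence_patterns(
        config, tree, n_patterns=n_patterns,
        rng=np.random.default_rng(seed))
    summary = phylo.summarize_dataset(patterns, tree)
    true_gains = int(truth["true_gains"].sum())
    true_losses = int(truth["true_losses"].sum())
    lo, hi = summary.ratio_range
    return {"n_patterns": len(patterns),
            "rate_ratio": config.gain_rate / config.loss_rate
            if config.loss_rate > 0 else float("inf"),
            "true_gains": true_gains, "true_losses": true_losses,
            "fusion_range": list(summary.fusion_total_range),
            "fission_range": list(summary.fission_total_range),
            "ratio_lo": lo, "ratio_hi": hi}
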