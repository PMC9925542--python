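"""Seeded synthetic inputs with the statistical structure the pipeline
assumes.

The generator plants the features each analysis stage is meant to
recover:

* a genome of non-overlapping coding genes with 1-3 protein isoforms per
  gene sharing a core sequence;
* a "subject species" proteome containing, for chosen truth pairs, the
  concatenation of one isoform per gene mutated at a configurable
  per-site divergence, plus single-gene decoys and unrelated random
  proteins;
* per-pair interaction scores with a distance-decaying baseline
  exp(-d / kappa) — encoding the known correlation between proximity and
  interaction that the distance-matched controls must neutralize — plus
  an additive effect delta (in noise-SD units) for truth pairs;
* an expression matrix whose truth pairs share tissue profiles, TAD
  lists, localization terms, a cancer-fusion pair list, and a
  known-interacting pool for pool controls;
* presence/absence patterns evolved on the species tree with independent
  per-edge gain and loss probabilities from an ancestral separate state,
  recording the true event counts.

All generators draw from RNG streams spawned per stage from the master
seed, so outputs are reproducible and adding one generator does not
perturb the others.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import align, genome, metrics, phylo
from .genome import (DIFFERENT_CHROMOSOME, GeneAnnotation, GenomeAnnotation,
                     GenePair, canonical_pair)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic datasets."""

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    n_fusion_pairs: int = 12
    fraction_nearby: float = 0.5          # truth pairs at small distances
    protein_length_range: tuple[int, int] = (80, 200)
    n_isoforms_range: tuple[int, int] = (1, 3)
    divergence: float = 0.05              # per-site substitution prob
    interaction_effect: float = 2.0       # delta, in units of noise SD
    noise_sd: float = 1.0
    distance_decay: float = 100.0         # kappa, genes
    n_tissues: int = 12
    donors_per_tissue: int = 15
    tad_lists: int = 5
    domains_per_chromosome: int = 12
    cancer_overlap_prob: float = 0.3
    cancer_background_pairs: int = 40
    pool_per_focal: int = 15
    n_decoy_genes: int = 25
    n_random_decoys: int = 15
    gain_rate: float = 0.15
    loss_rate: float = 0.003
    n_patterns: int = 100

    def __post_init__(self):
        for p in (self.fraction_nearby, self.divergence,
                  self.cancer_overlap_prob, self.gain_rate, self.loss_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if min(self.n_chromosomes, self.genes_per_chromosome,
               self.n_fusion_pairs, self.n_tissues,
               self.donors_per_tissue) < 1:
            raise ValueError("sizes must be >= 1")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named RNG streams spawned from the master seed."""
        names = ("genome", "truth", "proteome", "interaction",
                 "patterns", "controls")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate``, uniformly over the
    19 alternative residues."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = AA[AA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


# ---------------------------------------------------------------------
# genome + query proteome
# ---------------------------------------------------------------------

def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[GenomeAnnotation, dict[str, str], dict[str, str],
                               dict[str, str]]:
    """Build the annotation, gene core sequences, the isoform FASTA and
    the protein -> gene map.

    Returns ``(annotation, core_seqs, isoforms, protein_to_gene)``.
    """
    if rng is None:
        rng = config.streams()["genome"]
    lo, hi = config.protein_length_range
    iso_lo, iso_hi = config.n_isoforms_range
    genes: list[GeneAnnotation] = []
    cores: dict[str, str] = {}
    isoforms: dict[str, str] = {}
    protein_to_gene: dict[str, str] = {}
    for c in range(1, config.n_chromosomes + 1):
        pos = 1000
        for g in range(1, config.genes_per_chromosome + 1):
            gid = f"G{c:02d}_{g:04d}"
            length_aa = int(rng.integers(lo, hi + 1))
            span = length_aa * 3 + int(rng.integers(200, 2000))
            genes.append(GeneAnnotation(gid, f"chr{c}", pos, pos + span,
                                        "+" if rng.random() < 0.5 else "-",
                                        True))
            pos += span + int(rng.integers(500, 5000))
            core = _random_protein(rng, length_aa)
            cores[gid] = core
            n_iso = int(rng.integers(iso_lo, iso_hi + 1))
            for k in range(1, n_iso + 1):
                # isoforms share the core; later ones lose a random
                # N- or C-terminal stretch (up to 20%)
                seq = core
                if k > 1:
                    cut = int(rng.integers(0, max(1, length_aa // 5)))
                    seq = seq[cut:] if rng.random() < 0.5 else \
                        seq[:length_aa - cut] if cut else seq
                pid = f"{gid}.iso{k}"
                isoforms[pid] = seq
                protein_to_gene[pid] = gid
    return GenomeAnnotation(genes), cores, isoforms, protein_to_gene


def draw_truth_pairs(config: SimulationConfig, annotation: GenomeAnnotation,
                     rng: np.random.Generator | None = None,
                     ) -> list[GenePair]:
    """Choose the planted fusion-related pairs over disjoint genes,
    honoring ``fraction_nearby`` (nearby = same chromosome, small
    gene-count distance)."""
    if rng is None:
        rng = config.streams()["truth"]
    used: set[str] = set()
    pairs: list[GenePair] = []
    n_nearby = int(round(config.n_fusion_pairs * config.fraction_nearby))
    coding = annotation.coding_genes()
    attempts = 0
    while len(pairs) < config.n_fusion_pairs and attempts < 100_000:
        attempts += 1
        g1 = coding[int(rng.integers(len(coding)))]
        if g1.gene_id in used:
            continue
        if len(pairs) < n_nearby:
            # nearby: distance drawn geometrically, same chromosome
            d = int(rng.geometric(0.25)) - 1
            partner = annotation.gene_at_rank(g1.chromosome, g1.rank + d + 1)
            if partner is None or partner.gene_id in used:
                continue
        else:
            partner = coding[int(rng.integers(len(coding)))]
            if partner.gene_id in used or partner.gene_id == g1.gene_id:
                continue
        pairs.append(annotation.make_pair(g1.gene_id, partner.gene_id))
        used.update([g1.gene_id, partner.gene_id])
    if len(pairs) < config.n_fusion_pairs:
        raise RuntimeError("could not place the requested truth pairs")
    return pairs


# ---------------------------------------------------------------------
# fused subject proteome
# ---------------------------------------------------------------------

SUBJECT_SPECIES = "SyntheticPrimate"


def generate_fused_proteome(config: SimulationConfig,
                            annotation: GenomeAnnotation,
                            cores: Mapping[str, str],
                            truth_pairs: Sequence[GenePair],
                            rng: np.random.Generator | None = None,
                            ) -> tuple[dict[str, str], pd.DataFrame]:
    """Subject-species proteome with planted concatenation fusions.

    Returns the proteome and a truth table (subject_protein, gene_a,
    gene_b).  Decoys are mutated single-gene copies and unrelated random
    sequences.
    """
    if rng is None:
        rng = config.streams()["proteome"]
    proteome: dict[str, str] = {}
    rows = []
    for i, pair in enumerate(truth_pairs, start=1):
        fused = cores[pair.gene_a] + cores[pair.gene_b]
        sid = f"FUS{i:03d}"
        proteome[sid] = _mutate(fused, config.divergence, rng)
        rows.append((sid, pair.gene_a, pair.gene_b))
    truth_genes = {g for p in truth_pairs for g in p.key}
    other = [g for g in cores if g not in truth_genes]
    rng.shuffle(other)
    for j, gid in enumerate(other[:config.n_decoy_genes], start=1):
        proteome[f"ORTH{j:03d}"] = _mutate(cores[gid], config.divergence, rng)
    lo, hi = config.protein_length_range
    for j in range(1, config.n_random_decoys + 1):
        proteome[f"RAND{j:03d}"] = _random_protein(
            rng, int(rng.integers(lo, 2 * hi)))
    truth = pd.DataFrame(rows, columns=["subject_protein", "gene_a", "gene_b"])
    return proteome, truth


# ---------------------------------------------------------------------
# interaction data
# ---------------------------------------------------------------------

@dataclass
class InteractionData:
    coexpression: dict[tuple[str, str], float]
    expression: metrics.ExpressionMatrix
    tad_lists: list[metrics.TadList]
    localization: dict[str, frozenset[str]]
    cancer_pairs: set[tuple[str, str]]
    synonym_map: dict[str, set[str]]
    pool_pairs: list[GenePair]


def pair_score(pair: GenePair, truth_keys: set[tuple[str, str]],
               config: SimulationConfig, rng: np.random.Generator) -> float:
    """Baseline distance decay + planted effect + Gaussian noise."""
    if pair.distance is DIFFERENT_CHROMOSOME:
        base = 0.0
    else:
        base = float(np.exp(-float(pair.distance) / config.distance_decay))
    eff = config.interaction_effect * config.noise_sd \
        if pair.key in truth_keys else 0.0
    return base + eff + float(rng.normal(0.0, config.noise_sd))


def generate_pool_pairs(config: SimulationConfig,
                        annotation: GenomeAnnotation,
                        truth_pairs: Sequence[GenePair],
                        rng: np.random.Generator) -> list[GenePair]:
    """Known-interacting, fusion-unrelated pairs with strata covering
    every focal distance (the pool the pool-control sampler draws from)."""
    from .controls import _draw_cross_chromosome, _draw_same_chromosome
    truth_keys = {p.key for p in truth_pairs}
    pool: dict[tuple[str, str], GenePair] = {}
    for focal in truth_pairs:
        made = 0
        attempts = 0
        while made < config.pool_per_focal and attempts < 10_000:
            attempts += 1
            if focal.distance is DIFFERENT_CHROMOSOME:
                p = _draw_cross_chromosome(annotation, rng)
            else:
                p = _draw_same_chromosome(annotation, int(focal.distance), rng)
            if p is None or p.key in truth_keys or p.key in pool:
                continue
            pool[p.key] = p
            made += 1
    return list(pool.values())


def generate_interaction_data(config: SimulationConfig,
                              annotation: GenomeAnnotation,
                              truth_pairs: Sequence[GenePair],
                              extra_pairs: Sequence[GenePair] = (),
                              rng: np.random.Generator | None = None,
                              ) -> InteractionData:
    """Scores, expression, TADs, localization and cancer list with
    planted effects for truth pairs.

    ``extra_pairs`` (e.g. control draws) are scored too, so every pair a
    downstream test touches has a value.
    """
    if rng is None:
        rng = config.streams()["interaction"]
    truth_keys = {p.key for p in truth_pairs}
    pool = generate_pool_pairs(config, annotation, truth_pairs, rng)

    scored: dict[tuple[str, str], float] = {}
    for p in list(truth_pairs) + pool + list(extra_pairs):
        if p.key not in scored:
            scored[p.key] = pair_score(p, truth_keys, config, rng)

    expression = _generate_expression(config, annotation, truth_keys, rng)
    tads = _generate_tads(config, annotation, rng)
    localization = _generate_localization(config, annotation, truth_keys, rng)
    cancer, synonyms = _generate_cancer(config, annotation, truth_pairs, rng)
    return InteractionData(scored, expression, tads, localization, cancer,
                           synonyms, pool)


def _generate_expression(config, annotation, truth_keys, rng):
    genes = [g.gene_id for g in annotation.coding_genes()]
    tissues = [f"tissue{t:02d}" for t in range(1, config.n_tissues - 1)]
    tissues += ["testis", "ovary"]  # germline tissues, excludable
    samples, meta_rows = [], []
    for t in tissues:
        for d in range(1, config.donors_per_tissue + 1):
            sid = f"{t}_D{d:02d}"
            samples.append(sid)
            meta_rows.append((sid, t, f"D{d:02d}"))
    # per-gene tissue profiles; truth-pair members share one profile
    profiles = {g: rng.normal(2.0, 1.0, size=len(tissues)) for g in genes}
    for (a, b) in truth_keys:
        if a in profiles and b in profiles:
            profiles[b] = profiles[a] + rng.normal(0.0, 0.15, size=len(tissues))
    values = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        col = 0
        for ti in range(len(tissues)):
            for _ in range(config.donors_per_tissue):
                values[gi, col] = profiles[g][ti] + rng.normal(0.0, 0.5)
                col += 1
    values = np.exp(values)  # TPM-like, nonnegative
    vdf = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "tissue", "donor"]
                        ).set_index("sample_id")
    return metrics.ExpressionMatrix(vdf, meta)


def _generate_tads(config, annotation, rng):
    tads = []
    for li in range(1, config.tad_lists + 1):
        intervals = {}
        for chrom in annotation.chromosomes:
            gl = annotation.coding_genes(chrom)
            span_end = max(g.end for g in gl) + 10_000
            bounds = np.sort(rng.integers(
                0, span_end, size=config.domains_per_chromosome - 1))
            edges = np.concatenate([[0], bounds, [span_end]])
            intervals[chrom] = [(int(s), int(e))
                                for s, e in zip(edges[:-1], edges[1:]) if e > s]
        tads.append(metrics.TadList(f"list{li}", intervals))
    return tads


_COMPARTMENTS = ("nucleus", "cytosol", "mitochondrion", "extracellular",
                 "plasma_membrane", "endoplasmic_reticulum", "golgi",
                 "peroxisome", "lysosome")


def _generate_localization(config, annotation, truth_keys, rng):
    terms: dict[str, set[str]] = {}
    for g in annotation.coding_genes():
        k = 1 + int(rng.integers(0, 2))
        terms[g.gene_id] = set(rng.choice(_COMPARTMENTS, size=k, replace=False))
    for (a, b) in truth_keys:
        if rng.random() < 0.8:  # planted co-localization excess
            shared = str(rng.choice(_COMPARTMENTS))
            terms[a].add(shared)
            terms[b].add(shared)
    return {g: frozenset(t) for g, t in terms.items()}


def _generate_cancer(config, annotation, truth_pairs, rng):
    # symbols: each gene gets its id plus one synonym
    synonyms: dict[str, set[str]] = {}
    for g in annotation.coding_genes():
        synonyms[g.gene_id] = {g.gene_id, f"SYN_{g.gene_id}"}
    cancer: set[tuple[str, str]] = set()
    for p in truth_pairs:
        if rng.random() < config.cancer_overlap_prob:
            # record under a random choice of symbols and case
            sa = str(rng.choice(sorted(synonyms[p.gene_a])))
            sb = str(rng.choice(sorted(synonyms[p.gene_b])))
            cancer.add(canonical_pair(sa.lower(), sb.lower()))
    coding = annotation.coding_genes()
    while len(cancer) < config.cancer_background_pairs:
        i, j = rng.integers(len(coding), size=2)
        if i == j:
            continue
        cancer.add(canonical_pair(coding[int(i)].gene_id.lower(),
                                  coding[int(j)].gene_id.lower()))
    return cancer, synonyms


# ---------------------------------------------------------------------
# presence patterns on the tree
# ---------------------------------------------------------------------

def generate_presence_patterns(config: SimulationConfig,
                               tree: dendropy.Tree,
                               n_patterns: int | None = None,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[list[phylo.PresencePattern],
                                          pd.DataFrame]:
    """Evolve 0/1 fusion states down the tree: on every edge (including
    the pre-root edge) a separate pair fuses with ``gain_rate`` and a
    fused pair splits with ``loss_rate``.  The truth table records the
    true gain/loss counts per pattern."""
    if rng is None:
        rng = config.streams()["patterns"]
    if n_patterns is None:
        n_patterns = config.n_patterns
    patterns, rows = [], []
    order = list(tree.preorder_node_iter())
    for i in range(1, n_patterns + 1):
        states: dict[object, int] = {}
        gains = losses = 0
        for node in order:
            parent_state = 0 if node.parent_node is None \
                else states[node.parent_node]
            s = parent_state
            if parent_state == 0 and rng.random() < config.gain_rate:
                s, gains = 1, gains + 1
            elif parent_state == 1 and rng.random() < config.loss_rate:
                s, losses = 0, losses + 1
            states[node] = s
        leaf_states = {n.taxon.label: states[n] for n in tree.leaf_node_iter()}
        if not any(leaf_states.values()):
            continue  # unobservable pattern: fusion present nowhere
        pid = f"P{i:05d}"
        patterns.append(phylo.PresencePattern(pid, leaf_states))
        rows.append((pid, gains, losses))
    truth = pd.DataFrame(rows, columns=["pair_id", "true_gains", "true_losses"])
    return patterns, truth


# ---------------------------------------------------------------------
# full dataset to disk
# ---------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir) -> dict[str, object]:
    """Generate every input the pipeline consumes and write it under
    ``outdir`` in plain-text formats.  Returns the in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = config.streams()
    annotation, cores, isoforms, p2g = generate_genome(config, streams["genome"])
    truth_pairs = draw_truth_pairs(config, annotation, streams["truth"])
    proteome, truth = generate_fused_proteome(config, annotation, cores,
                                              truth_pairs, streams["proteome"])
    data = generate_interaction_data(config, annotation, truth_pairs,
                                     rng=streams["interaction"])
    tree = phylo.load_tree()
    patterns, pattern_truth = generate_presence_patterns(
        config, tree, rng=streams["patterns"])

    genome.write_annotation(annotation, outdir / "annotation.tsv")
    align.write_fasta(isoforms, outdir / "query_proteome.fasta")
    align.write_fasta(proteome, outdir / "subject_proteome.fasta")
    pd.DataFrame(sorted(p2g.items()), columns=["protein_id", "gene_id"]
                 ).to_csv(outdir / "protein_gene_map.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "fusion_truth.tsv", sep="\t", index=False)
    pd.DataFrame([(p.gene_a, p.gene_b) for p in truth_pairs],
                 columns=["gene_a", "gene_b"]
                 ).to_csv(outdir / "fusion_pairs.tsv", sep="\t", index=False)
    metrics.write_pair_scores(data.coexpression, outdir / "coexpression.tsv")
    data.expression.write(outdir / "expression.tsv",
                          outdir / "expression_meta.tsv")
    for tl in data.tad_lists:
        rows = [(c, s, e) for c, ivs in sorted(tl.intervals.items())
                for s, e in ivs]
        pd.DataFrame(rows).to_csv(outdir / f"tad_{tl.list_id}.bed", sep="\t",
                                  index=False, header=False)
    pd.DataFrame([(g, t) for g, ts in sorted(data.localization.items())
                  for t in sorted(ts)], columns=["gene", "term"]
                 ).to_csv(outdir / "localization.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(data.cancer_pairs), columns=["symbol_a", "symbol_b"]
                 ).to_csv(outdir / "cancer_pairs.tsv", sep="\t", index=False)
    pd.DataFrame([(s, g) for g, ss in sorted(data.synonym_map.items())
                  for s in sorted(ss)], columns=["symbol", "gene_id"]
                 ).to_csv(outdir / "synonyms.tsv", sep="\t", index=False)
    pd.DataFrame([(p.gene_a, p.gene_b) for p in data.pool_pairs],
                 columns=["gene_a", "gene_b"]
                 ).to_csv(outdir / "pool_pairs.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(phylo.DEFAULT_TREE_NEWICK + "\n")
    phylo.write_patterns(patterns, tree, outdir / "presence_patterns.tsv")
    pattern_truth.to_csv(outdir / "pattern_truth.tsv", sep="\t", index=False)
    return {"annotation": annotation, "cores": cores, "isoforms": isoforms,
            "protein_to_gene": p2g, "truth_pairs": truth_pairs,
            "subject_proteome": proteome, "fusion_truth": truth,
            "interaction": data, "tree": tree, "patterns": patterns,
            "pattern_truth": pattern_truth}
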