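# Methods

## The question and the comparison design

Two genes that are separate in one genome but fused into a single
coding unit in another genome are called a *fusion-related pair*.  The
analyses here ask whether fusion-related pairs interact more than
expected — by co-expression, same-TAD presence, subcellular
co-localization, functional-annotation similarity, or overlap with
cancer-fusion pairs — once the genomic distance between pair members is
controlled.  Distance control is essential: proximity alone predicts
both interaction and fusion, so an unmatched comparison would confound
the two.

Distance is the number of protein-coding genes strictly between the
pair members on a chromosome (rank difference − 1, ranks assigned per
chromosome by start coordinate, ties broken by end then id; non-coding
genes are invisible to the measure).  Pairs are stratified as SC_0
(adjacent), SC_1–99, SC_100–499, SC_500+ and DC (different
chromosomes), and every test is run per stratum plus "all pairs" and
"same chromosome" aggregates.

## Distance-matched controls

For each focal pair two control constructions are available, both at a
10× multiplier, drawn without repetition *within* each focal pair's
draws (repetition across focal pairs is permitted — forbidding it
globally can make strata infeasible):

* **genomic control** — draw a coding gene uniformly, pair it with the
  coding gene `d + 1` ranks downstream on the same chromosome
  (downstream = higher rank); redraw when the partner falls off the
  chromosome end, duplicates an earlier draw, or equals the focal pair
  itself.  Cross-chromosome focal pairs draw uniform cross-chromosome
  gene pairs — the minimal extension consistent with reporting DC
  control strata.  A 10,000-attempt cap guards degenerate annotations.
* **pool control** — stratify a supplied pool of known-interacting,
  fusion-unrelated pairs by exact distance and sample uniformly without
  replacement from the focal pair's stratum.

When a stratum cannot supply the full multiplier, all available pairs
are used.  When every stratum is full, the control distance histogram
is *exactly* 10× the focal histogram (tested).

## Interaction measures

* **Co-expression**: either an opaque per-pair score table (as supplied
  by co-expression databases), or Spearman correlation computed from a
  gene × sample expression matrix under two aggregations: (1) within
  each tissue across donors, averaged over tissues; (2) across tissues
  of donor-averaged expression.  Tissues with fewer than 10 samples are
  excluded; a soma-only variant excludes testis and ovary.  Spearman
  uses midranks; a constant vector yields a missing value.
* **Same-TAD presence**: the number of independent TAD coordinate lists
  in which both genes lie entirely inside one common domain.  Domains
  are half-open `[start, end)` (BED convention); whole-gene containment
  means `start_domain ≤ gene_start` and `gene_end < end_domain`.
  Defined for same-chromosome pairs only.
* **Co-localization**: true when any protein product of one gene shares
  a compartment term with any product of the other.
* **Cancer-fusion overlap**: unordered, synonym-aware membership of the
  pair in a cancer-fusion pair list; symbol matching is
  case-insensitive by default (cancer databases mix cases) with a
  toggle.

Pairs with a missing measure are excluded from the corresponding test
on both sides, never zero-filled.

## Statistics

Score measures use the one-sided Mann–Whitney–Wilcoxon test
(alternative: focal stochastically greater).  The reported W is the
focal rank-sum minus `n_f(n_f+1)/2` (the U statistic, as printed by R's
`wilcox.test`).  The exact null is used when both samples have ≤ 50
observations and no ties; otherwise the normal approximation with tie
correction and 0.5 continuity correction.  The ≤ 50 cutoff keeps the
exact path wherever it is computationally trivial; beyond it the
approximation is indistinguishable at the reported precision.

Binary measures use the one-sided Fisher exact test,
`p = Σ_{x ≥ a} hypergeom(x; margins)`, with the **conditional
maximum-likelihood odds ratio** — the ψ maximizing the noncentral
hypergeometric likelihood given all margins.  This is the convention of
R's `fisher.test` (and `scipy.stats.contingency.odds_ratio`), *not* the
sample cross-product ad/bc; the two differ materially in small or
unbalanced tables (e.g. counts (5, 22, 6, 264): CMLE 9.84 vs
cross-product 10.0; counts (6, 21, 6, 264): CMLE 12.33 vs cross-product
12.57).  Conventions: a = 0 → OR 0; c = 0 with a > 0 → OR ∞.  p-values
are never truncated except for rendering below 2.2e-16 as
"< 2.20E−16".  No multiple-testing correction is applied: each distance
group row is an individual test, reported as-is.

## Fusion-candidate detection

Query isoforms are locally aligned to every subject protein
(Smith–Waterman via Biopython's PairwiseAligner, BLOSUM62, gap open 11 /
extend 1).  The unknown/ambiguity residues X, B, Z score 0 against
everything.  E-values use the Karlin–Altschul form
`E = K·m·n·e^(−λS)` with gapped constants λ = 0.267, K = 0.041 and
m·n = query length × subject length; a score-only prepass prunes pairs
below the exact score at which E would exceed the cutoff, so no
qualifying alignment is lost.  Externally computed alignments in the
12-column tabular format are accepted unchanged and carry their own
e-values.

Per-alignment acceptance: length ≥ 20 aa (inclusive), e-value ≤ 0.1
(inclusive), identity strictly above the per-species threshold.
Identity is matches / alignment length including gap columns.  The
*merged region* of a gene on a subject protein is the union of its
passing isoforms' subject-coordinate intervals (abutting intervals
merge).  Alignment regions live in subject-protein coordinates — the
fused protein is the only frame in which overlap between the two genes'
mappings is meaningful.  Two genes form a candidate when their merged
regions intersect by ≤ 5 aa (total intersection of the interval unions,
not hull overlap).  If a third gene's merged region covers every
position of both pair regions, the candidate is discarded
(a strict-superset variant is available as a toggle); otherwise, if
more than two genes map to the subject protein, the pair is flagged for
manual resolution rather than resolved automatically.

**Per-species identity threshold.**  The appropriate threshold depends
on the evolutionary distance of each subject species and is a free
parameter.  The default for the synthetic species is 60%: short random
local alignments under BLOSUM62 plateau around 50–55% identity, while
true homologs at the generator's default 5% divergence align at ≈ 95%,
so 60% cleanly separates signal from the random background.  Real
analyses should calibrate this per species.

## Fusion/fission inference

Each pair's fusion presence/absence across species is a binary
character on a rooted tree (default topology:
`(Microcebus,((Aotus,Callithrix),(Macaca,(Gorilla,(Pan,Homo)))))`).
Minimum state changes are computed by unweighted parsimony
(Sankoff-style DP generalizing to multifurcations) under the
**ancestral-separate convention**: a pre-root edge from fixed state 0
is appended, because a fused gene is derived by definition relative to
its separate ancestral genes; clade-wide presence therefore costs one
fusion, never zero events.  All ancestral labelings attaining the
minimum are enumerated (branch-and-bound over labelings, verified
against exhaustive enumeration), each classified into per-edge FUSION
(0→1) and FISSION (1→0) events.  Patterns are summarized as
single-origin, recurrent-fusion (every minimal scenario has ≥ 2
fusions) or ambiguous, and dataset totals are reported as [min, max]
ranges over per-pattern scenario choices, with the fusion:fission ratio
range derived from them.  Ambiguity is reported, not resolved: the
ranges make explicit how much the scenario choice matters.

## Synthetic data

The generator is first-class, seeded code (RNG streams are spawned
per stage from one master seed, so adding a generator never perturbs
another).  Defaults define the study conditions used by the tests:

| parameter | default | meaning |
|---|---|---|
| n_chromosomes × genes_per_chromosome | 2 × 50 | non-overlapping coding genes |
| n_fusion_pairs | 12 | planted fusion-related pairs (disjoint genes) |
| fraction_nearby | 0.5 | share of truth pairs at small same-chromosome distances (geometric, p = 0.25) |
| protein_length_range | 80–200 aa | core protein lengths; 1–3 isoforms share a core with terminal truncations |
| divergence | 0.05 | per-site substitution probability in planted fused proteins (uniform over the 19 alternatives — no rate matrix; sufficient for threshold behavior) |
| distance_decay κ | 100 | baseline interaction score exp(−d/κ) — the proximity–interaction correlation the controls must neutralize |
| interaction_effect δ | 2.0 | additive score shift for truth pairs, in noise-SD units |
| noise_sd | 1.0 | Gaussian score noise |
| gain_rate : loss_rate | 0.15 : 0.003 | per-edge fusion/fission probabilities on the tree (50:1) |

The subject proteome contains one concatenated, mutated isoform pair
per truth pair plus mutated single-gene orthologs and unrelated random
proteins as decoys.  Expression matrices plant shared tissue profiles
for truth pairs; localization terms are shared with elevated
probability; the cancer list contains each truth pair with probability
0.3 (recorded under random synonym/case variants) plus random
background pairs; presence patterns evolve 0→1/1→0 along tree edges
from the ancestral separate state, with true event counts recorded.

**What the generator does not emulate**: real tissue covariance
structure, realistic TAD size distributions, paralogy (decoys share no
homology with planted fusions), gene-family structure, and incomplete
database coverage beyond score-table sparsity.  Passing tests therefore
demonstrate the correctness and calibration of the *machinery* — they
do not re-establish the empirical biological findings.

## Validation experiments and problem sizes

* **Planted-fusion recovery**: 12 planted fusions at 5% divergence;
  recall and precision are both 1.0 (the built-in aligner makes this a
  ~10 s computation at the default genome size).
* **Null calibration**: 500 replicates of the full
  draw-pairs → match-controls → test cycle with δ = 0 on a 200-gene
  genome with 40 focal pairs; the one-sided test rejects at the nominal
  5% within binomial 99% bounds.  **Power**: 100 replicates with
  δ = 2 SD and 200 focal pairs reject at p < 0.01 in ≥ 95% of runs.
* **Parsimony ratio recovery**: 1,000 histories at the 50:1 gain:loss
  rates; the inferred fusion:fission [min, max] ratio range reaches the
  factor-of-two band around 50.  Parsimony merges parallel gains, so
  point under-estimation is expected — the range, not a point, is the
  honest summary.
* **Exact-test oracles**: Fisher p equals exhaustive enumeration of all
  tables with fixed margins on a dense grid of small tables;
  Mann–Whitney exact p equals full permutation enumeration for combined
  n ≤ 10; the Fitch layer equals brute force over all 2^6 ancestral
  labelings for every one of the 2^7 leaf patterns on the default tree.

These sizes keep the default test suite and the reproduction script
comfortably within interactive runtimes while leaving every estimate's
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The FLAG_MANUAL category (more than two genes on one subject protein
  without a containment discard) is flagged, never resolved; resolving
  it requires case-by-case similarity analysis.
* The e-value model applies fixed gapped Karlin–Altschul constants to
  all inputs of the built-in aligner; externally computed e-values are
  preferred for real data.
* Whether the ≤ 5 aa overlap should be assessed on merged regions or
  per best isoform pair is ambiguous in principle; the merged-region
  reading is adopted because the overlap rule is stated in terms of the
  same regions the merge defines.
* Genomic controls for DC pairs (uniform cross-chromosome draws) are a
  design choice; only the same-chromosome mechanism is fully specified
  by the matching construction.
* The conditional-MLE odds ratio is undefined for tables with an empty
  margin; the 0/∞ conventions above follow the standard exact-test
  implementations.
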