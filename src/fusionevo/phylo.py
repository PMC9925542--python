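"""Fusion/fission event inference on a species tree by Fitch parsimony.

Each gene pair contributes a binary presence/absence pattern over the
leaves (1 = the pair is fused in that species).  The minimum number of
state changes is computed by unweighted parsimony, generalized to
multifurcations, under the ancestral-separate convention: a pre-root
edge from fixed state 0 (separate) is appended, so a fusion present
across the whole clade still costs one fusion event.  All
equally-parsimonious ancestral labelings are enumerated and classified
into per-edge FUSION (0 -> 1) and FISSION (1 -> 0) events; dataset
totals are reported as [min, max] ranges over the per-pattern scenario
choices.
"""
from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

#: Default topology: six primate species plus human.
DEFAULT_TREE_NEWICK = \
    "(Microcebus,((Aotus,Callithrix),(Macaca,(Gorilla,(Pan,Homo)))));"

FUSION = "FUSION"
FISSION = "FISSION"


def load_tree(newick: str | None = None) -> dendropy.Tree:
    """Parse a rooted newick tree (defaults to the primate topology)."""
    tree = dendropy.Tree.get(data=newick or DEFAULT_TREE_NEWICK,
                             schema="newick", rooting="force-rooted")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("leaf labels must be unique")
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


@dataclass(frozen=True)
class PresencePattern:
    """Fusion presence (1) / absence (0) per leaf for one gene pair."""

    pair_id: str
    states: Mapping[str, int]

    def __post_init__(self):
        if not self.states:
            raise ValueError("empty pattern")
        for leaf, s in self.states.items():
            if s not in (0, 1):
                raise ValueError(f"state for {leaf} must be 0/1, got {s}")


@dataclass(frozen=True)
class EventScenario:
    """One most-parsimonious ancestral labeling with its edge events."""

    labeling: tuple[tuple[str, int], ...]   # (node key, state), internal nodes
    events: tuple[tuple[str, str], ...]     # (edge child key, FUSION/FISSION)

    @property
    def n_fusion(self) -> int:
        return sum(1 for _, t in self.events if t == FUSION)

    @property
    def n_fission(self) -> int:
        return sum(1 for _, t in self.events if t == FISSION)


def node_keys(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable node names: leaf labels for leaves, N<preorder index> for
    internal nodes."""
    keys = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        keys[node] = node.taxon.label if node.taxon is not None else f"N{i}"
    return keys


def _prepare(pattern: PresencePattern, tree: dendropy.Tree):
    leaves = leaf_labels(tree)
    missing = [l for l in leaves if l not in pattern.states]
    if missing:
        raise ValueError(f"pattern {pattern.pair_id} missing leaves: {missing}")
    return leaves


def _min_change_costs(pattern: PresencePattern, tree: dendropy.Tree):
    """Sankoff-style DP: cost[node][s] = min changes in the subtree when
    the node has state s.  Works on multifurcations."""
    cost: dict[dendropy.Node, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = pattern.states[node.taxon.label]
            cost[node] = (0.0 if s == 0 else float("inf"),
                          0.0 if s == 1 else float("inf"))
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                ch0, ch1 = cost[child]
                c0 += min(ch0, ch1 + 1)
                c1 += min(ch0 + 1, ch1)
            cost[node] = (c0, c1)
    return cost


def fitch_min_changes(pattern: PresencePattern, tree: dendropy.Tree) -> int:
    """Minimum number of state changes, counting the pre-root edge from
    ancestral state 0."""
    _prepare(pattern, tree)
    cost = _min_change_costs(pattern, tree)
    r0, r1 = cost[tree.seed_node]
    return int(min(r0, r1 + 1))


def enumerate_scenarios(pattern: PresencePattern, tree: dendropy.Tree,
                        ) -> list[EventScenario]:
    """All ancestral labelings achieving the parsimony minimum, with
    their per-edge event classifications."""
    _prepare(pattern, tree)
    minimum = fitch_min_changes(pattern, tree)

    scenarios: list[EventScenario] = []
    order = list(tree.preorder_node_iter())
    keys = node_keys(tree)

    def recurse(i: int, states: dict[dendropy.Node, int], changes: int):
        if changes > minimum:
            return
        if i == len(order):
            if changes != minimum:
                return
            labeling = tuple(sorted(
                (keys[n], s) for n, s in states.items() if not n.is_leaf()))
            events = []
            for node in order:
                parent_state = 0 if node.parent_node is None \
                    else states[node.parent_node]
                if states[node] != parent_state:
                    events.append((keys[node],
                                   FUSION if states[node] == 1 else FISSION))
            scenarios.append(EventScenario(labeling, tuple(sorted(events))))
            return
        node = order[i]
        parent_state = 0 if node.parent_node is None else states[node.parent_node]
        if node.is_leaf():
            s = pattern.states[node.taxon.label]
            states[node] = s
            recurse(i + 1, states, changes + (1 if s != parent_state else 0))
            del states[node]
        else:
            for s in (0, 1):
                states[node] = s
                recurse(i + 1, states, changes + (1 if s != parent_state else 0))
                del states[node]

    recurse(0, {}, 0)
    # deduplicate by labeling
    seen = {}
    for sc in scenarios:
        seen.setdefault(sc.labeling, sc)
    return list(seen.values())


# ---------------------------------------------------------------------
# dataset summary
# ---------------------------------------------------------------------

RECURRENT_FUSION = "RECURRENT_FUSION"
SINGLE_ORIGIN = "SINGLE_ORIGIN"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class PatternSummary:
    pair_id: str
    min_changes: int
    event_counts: frozenset[tuple[int, int]]   # {(n_fusion, n_fission)}
    recurrence: str

    @property
    def fusion_range(self) -> tuple[int, int]:
        fus = [f for f, _ in self.event_counts]
        return (min(fus), max(fus))

    @property
    def fission_range(self) -> tuple[int, int]:
        fis = [f for _, f in self.event_counts]
        return (min(fis), max(fis))


def summarize_pattern(pattern: PresencePattern,
                      tree: dendropy.Tree) -> PatternSummary:
    scenarios = enumerate_scenarios(pattern, tree)
    counts = frozenset((sc.n_fusion, sc.n_fission) for sc in scenarios)
    n_fus = sorted({f for f, _ in counts})
    if all(f >= 2 for f in n_fus):
        recurrence = RECURRENT_FUSION
    elif all(f <= 1 for f in n_fus):
        recurrence = SINGLE_ORIGIN
    else:
        recurrence = AMBIGUOUS
    return PatternSummary(pattern.pair_id,
                          fitch_min_changes(pattern, tree), counts, recurrence)


@dataclass(frozen=True)
class DatasetSummary:
    patterns: tuple[PatternSummary, ...]
    fusion_total_range: tuple[int, int]
    fission_total_range: tuple[int, int]

    @property
    def ratio_range(self) -> tuple[float, float]:
        """[min, max] of total fusions / total fissions over scenario
        choices (inf when no scenario requires a fission)."""
        fmin, fmax = self.fusion_total_range
        gmin, gmax = self.fission_total_range
        lo = fmin / gmax if gmax > 0 else float("inf")
        hi = fmax / gmin if gmin > 0 else float("inf")
        return (lo, hi)


def summarize_dataset(patterns: Sequence[PresencePattern],
                      tree: dendropy.Tree) -> DatasetSummary:
    if not patterns:
        raise ValueError("no patterns supplied")
    summaries = tuple(summarize_pattern(p, tree) for p in patterns)
    fus_min = sum(s.fusion_range[0] for s in summaries)
    fus_max = sum(s.fusion_range[1] for s in summaries)
    fis_min = sum(s.fission_range[0] for s in summaries)
    fis_max = sum(s.fission_range[1] for s in summaries)
    return DatasetSummary(summaries, (fus_min, fus_max), (fis_min, fis_max))


# ---------------------------------------------------------------------
# io
# ---------------------------------------------------------------------

def load_patterns(path_or_buffer, tree: dendropy.Tree) -> list[PresencePattern]:
    """TSV with pair_id column then one 0/1 column per leaf label."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    leaves = leaf_labels(tree)
    missing = set(leaves) - set(df.columns)
    if missing:
        raise ValueError(f"pattern file missing leaf columns: {sorted(missing)}")
    id_col = df.columns[0]
    return [PresencePattern(str(r[id_col]),
                            {l: int(r[l]) for l in leaves})
            for _, r in df.iterrows()]


def write_patterns(patterns: Sequence[PresencePattern],
                   tree: dendropy.Tree, path) -> None:
    leaves = leaf_labels(tree)
    rows = [{"pair_id": p.pair_id, **{l: p.states[l] for l in leaves}}
            for p in patterns]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summary_to_frame(summary: DatasetSummary) -> pd.DataFrame:
    rows = []
    for s in summary.patterns:
        counts = "|".join(f"({f},{g})" for f, g in sorted(s.event_counts))
        rows.append({"pair_id": s.pair_id, "min_changes": s.min_changes,
                     "scenarios": counts, "recurrence": s.recurrence})
    return pd.DataFrame(rows)
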