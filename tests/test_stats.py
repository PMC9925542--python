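"""Exact-test layer against brute-force enumeration oracles."""
import math
from itertools import combinations

import numpy as np
import pytest
from scipy.special import comb

from fusionevo.genome import GenePair, GeneAnnotation, GenomeAnnotation
from fusionevo.stats import (build_enrichment_table, fisher_one_sided,
                             format_pvalue, mann_whitney_one_sided)


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def fisher_p_by_enumeration(a, b, c, d):
    """Upper-tail Fisher p by direct enumeration of all 2x2 tables with
    the observed margins."""
    row1, col1 = a + b, a + c
    n = a + b + c + d
    def table_prob(x):
        return (comb(row1, x, exact=True)
                * comb(n - row1, col1 - x, exact=True)) / comb(n, col1,
                                                               exact=True)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if x >= a:
            total += table_prob(x)
    return total


def mw_p_by_permutation(x, y):
    """Exact one-sided Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the focal sample."""
    pooled = sorted(x + y, reverse=True)
    nx = len(x)
    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) \
            + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)
    observed = u_stat(x, y)
    count = total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(xs, ys) >= observed - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------
# Fisher exact + conditional-MLE odds ratio
# ---------------------------------------------------------------------

class TestFisher:
    @pytest.mark.parametrize("table,p,or_", [
        # reference contingency rows with their published statistics
        ((67, 58, 458, 792), 1.75e-4, 2.00),
        ((5, 22, 6, 264), 1.36e-3, 9.84),
        ((49, 24, 397, 333), 2.38e-2, 1.71),
        ((12, 7, 54, 136), 3.01e-3, 4.28),
        ((168, 11123, 1091, 111819), 3.97e-7, 1.548),
        ((126, 691, 769, 7401), 1.68e-7, 1.755),
        ((6, 8524, 8, 85292), 8.89e-4, 7.505),
    ])
    def test_reproduces_published_statistics(self, table, p, or_):
        res = fisher_one_sided(*table)
        assert res.p_one_sided == pytest.approx(p, rel=5e-3)
        assert res.odds_ratio == pytest.approx(or_, rel=5e-3)

    def test_conditional_mle_differs_from_cross_product(self):
        # small unbalanced table where the two estimators separate
        res = fisher_one_sided(5, 22, 6, 264)
        cross = (5 * 264) / (22 * 6)
        assert res.odds_ratio < cross
        assert res.odds_ratio == pytest.approx(9.84, abs=0.01)

    def test_empty_upper_tail(self):
        res = fisher_one_sided(0, 10, 0, 100)
        assert res.p_one_sided == pytest.approx(1.0)
        assert res.odds_ratio == 0.0

    def test_all_focal_positive_infinite_or(self):
        res = fisher_one_sided(1, 166, 0, 1670)
        assert math.isinf(res.odds_ratio)
        assert res.p_one_sided == pytest.approx(9.09e-2, rel=5e-3)

    def test_balanced_small_table(self):
        assert fisher_one_sided(2, 1, 1, 2).p_one_sided == pytest.approx(0.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)

    def test_matches_enumeration_for_small_margins(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b == 0 or c + d == 0:
                continue
            expected = fisher_p_by_enumeration(a, b, c, d)
            assert fisher_one_sided(a, b, c, d).p_one_sided \
                == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_cmle_shrinks_toward_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, size=4))
            res = fisher_one_sided(a, b, c, d)
            cross = (a * d) / (b * c)
            if cross > 1:
                assert res.odds_ratio <= cross + 1e-9
            elif cross < 1:
                assert res.odds_ratio >= cross - 1e-9
            assert 0 < res.odds_ratio < math.inf


# ---------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------

class TestMannWhitney:
    def test_small_exact_example(self):
        res = mann_whitney_one_sided([3, 4, 5], [1, 2])
        assert res.W == 6
        assert res.p_one_sided == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        res = mann_whitney_one_sided([1, 2, 3], [1, 2, 3])
        assert res.W == pytest.approx(4.5)
        assert res.p_one_sided >= 0.5

    def test_exact_path_matches_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            # unique values: exact path applies
            pooled = rng.permutation(np.arange(100))[:nx + ny].astype(float)
            x, y = list(pooled[:nx]), list(pooled[nx:])
            expected = mw_p_by_permutation(x, y)
            res = mann_whitney_one_sided(x, y)
            assert res.p_one_sided == pytest.approx(expected, rel=1e-9)

    def test_shift_alternative_detected(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, size=200)
        x = rng.normal(0, 1, size=200) + 1.0
        assert mann_whitney_one_sided(x, y).p_one_sided < 1e-3

    def test_swapping_samples_complements_the_statistic(self):
        rng = np.random.default_rng(5)
        x = list(rng.normal(0, 1, 20))
        y = list(rng.normal(0.3, 1, 25))
        w_fwd = mann_whitney_one_sided(x, y).W
        w_rev = mann_whitney_one_sided(y, x).W
        assert w_fwd + w_rev == pytest.approx(len(x) * len(y))
        assert 0 <= w_fwd <= len(x) * len(y)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


def test_pvalue_formatting():
    assert format_pvalue(1e-20) == "< 2.20E-16"
    assert format_pvalue(3.97e-7) == "3.97E-07"


# ---------------------------------------------------------------------
# per-group report
# ---------------------------------------------------------------------

def _pairs_with_values(annotation, spec):
    """spec: list of (gene_a, gene_b, value)."""
    return [(annotation.make_pair(a, b), v) for a, b, v in spec]


class TestEnrichmentTable:
    @pytest.fixture
    def annotation(self, small_annotation):
        return small_annotation

    def test_groups_and_missing_exclusion(self, annotation):
        focal = _pairs_with_values(annotation, [
            ("A1", "A2", 1.0), ("A1", "A5", 2.0), ("A1", "B1", 3.0),
            ("A2", "A3", None),
        ])
        control = _pairs_with_values(annotation, [
            ("A3", "A4", 0.5), ("A2", "A6", 0.5), ("A2", "B2", 0.5),
        ])
        table = build_enrichment_table(focal, control, "mannwhitney")
        t = table.set_index("group")
        assert t.loc["All pairs", "n_focal"] == 3  # missing value excluded
        assert t.loc["Same chromosome", "n_focal"] == 2
        assert t.loc["SC_0", "n_focal"] == 1
        assert t.loc["DC", "n_focal"] == 1

    def test_constant_measure_never_significant(self, annotation):
        focal = _pairs_with_values(annotation,
                                   [("A1", "A2", 1.0), ("A3", "A5", 1.0)])
        control = _pairs_with_values(annotation,
                                     [("A2", "A3", 1.0), ("A4", "A6", 1.0)])
        table = build_enrichment_table(focal, control, "mannwhitney")
        ps = table["p"].dropna()
        assert (ps >= 0.5).all()

    def test_fisher_kind_produces_counts(self, annotation):
        focal = _pairs_with_values(annotation,
                                   [("A1", "A2", True), ("A3", "A5", False)])
        control = _pairs_with_values(annotation,
                                     [("A2", "A3", False), ("A4", "A6", False),
                                      ("A5", "A7", True)])
        t = build_enrichment_table(focal, control, "fisher").set_index("group")
        assert t.loc["All pairs", "positives_focal"] == 1
        assert t.loc["All pairs", "positives_control"] == 1
        assert 0 < t.loc["All pairs", "p"] <= 1

    def test_empty_group_row_reports_sizes_only(self, annotation):
        focal = _pairs_with_values(annotation, [("A1", "A2", 1.0)])
        control = _pairs_with_values(annotation, [("A3", "A4", 0.5)])
        t = build_enrichment_table(focal, control, "mannwhitney")
        dc = t.set_index("group").loc["DC"]
        assert dc["n_focal"] == 0 and math.isnan(dc["p"])
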