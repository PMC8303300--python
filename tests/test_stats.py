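from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from hgsoctype import (
    ContingencyTable,
    MutationMatrix,
    chi_square_rxc,
    correlation,
    fisher_exact_2x2,
    mann_whitney_u,
    mutual_exclusivity,
    one_way_anova,
    tmb,
)


def fisher_two_sided_oracle(table):
    """Enumerate all 2x2 tables with the observed margins; sum point
    probabilities no larger than the observed one (point-probability rule)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point_prob(a)
    return sum(
        point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= p_obs * (1 + 1e-7)
    )


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_of(range(nx))
    mean_u = nx * (len(pooled) - nx) / 2
    dev = abs(u_obs - mean_u)
    us = [u_of(idx) for idx in combinations(range(len(pooled)), nx)]
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12)
    return extreme / len(us)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 0], [5, 10]], 0.033),
            ([[9, 1], [7, 3]], 0.582),
            ([[6, 8], [4, 2]], 0.628),
        ],
    )
    def test_clinical_contingency_values(self, table, expected):
        assert round(fisher_exact_2x2(table), 3) == expected

    def test_proportional_table_p_one(self):
        assert fisher_exact_2x2([[6, 6], [4, 4]]) == pytest.approx(1.0)

    def test_degenerate_margin_flagged_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_transpose_and_swap_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, rel=1e-9)

    def test_exhaustive_small_tables_match_oracle(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        assert fisher_exact_2x2(t) == pytest.approx(
                            fisher_two_sided_oracle(t), rel=1e-9
                        ), t

    def test_type_one_error_conservative_under_independence(self):
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            row = rng.binomial(1, 0.5, size=20)
            col = rng.binomial(1, 0.5, size=20)
            t = [
                [int(((row == 1) & (col == 1)).sum()), int(((row == 1) & (col == 0)).sum())],
                [int(((row == 0) & (col == 1)).sum()), int(((row == 0) & (col == 0)).sum())],
            ]
            if min(sum(t[0]), sum(t[1]), t[0][0] + t[1][0], t[0][1] + t[1][1]) == 0:
                continue
            rejections += fisher_exact_2x2(t) < 0.05
        assert rejections / reps <= 0.05


class TestChiSquare:
    def test_residual_tumor_table(self):
        stat, df, p = chi_square_rxc([[9, 5], [1, 4], [0, 1]])
        assert stat == pytest.approx(3.943, abs=5e-4)
        assert df == 2
        assert round(p, 3) == 0.139

    def test_figo_stage_table(self):
        _, df, p = chi_square_rxc([[1, 1], [1, 0], [5, 6], [3, 3]])
        assert df == 3
        assert round(p, 3) == 0.779

    def test_proportional_table_statistic_zero(self):
        stat, _, p = chi_square_rxc([[2, 4], [3, 6], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="collapse"):
            chi_square_rxc([[0, 0], [3, 4]])

    def test_row_column_permutation_invariance(self):
        t = np.array([[9, 5], [1, 4], [0, 1]])
        stat, _, _ = chi_square_rxc(t)
        stat_perm, _, _ = chi_square_rxc(t[[2, 0, 1]][:, [1, 0]])
        assert stat_perm == pytest.approx(stat)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [3, 1, 2])
        assert p == pytest.approx(1.0)

    def test_single_observation_each(self):
        _, p = mann_whitney_u([1], [2])
        assert p == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("trial", range(8))
    def test_exact_p_matches_permutation_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pool = rng.choice(np.arange(100), size=nx + ny, replace=False).astype(float)
        x, y = pool[:nx], pool[nx:]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mwu_exact_oracle(x, y), rel=1e-9)


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        f, p = one_way_anova([[1, 2], [1, 2], [1, 2]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_within_variance_is_error(self):
        with pytest.raises(ValueError, match="within"):
            one_way_anova([[0, 0], [1, 1]])

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestCorrelation:
    def test_affine_relation_pearson_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlation(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self):
        x = [0.1, 1.0, 2.0, 3.5]
        r, _ = correlation(x, list(np.exp(x)), method="spearman")
        assert r == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        # ranks differ by d = (-1, 1, -1, 1, 0): sum d^2 = 4 -> rho = 0.8
        r, _ = correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], method="spearman")
        assert r == pytest.approx(0.8)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3])


class TestMutualExclusivity:
    def _matrix(self, rows, samples=None):
        samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
        return MutationMatrix(pd.DataFrame(rows, index=samples).T)

    def test_disjoint_mutations_detected(self):
        m = self._matrix(
            {"g1": [1, 1, 1, 1, 0, 0, 0, 0], "g2": [0, 0, 0, 0, 1, 1, 1, 1]}
        )
        out = mutual_exclusivity(m)
        assert len(out) == 1
        assert out.iloc[0]["both"] == 0
        assert out.iloc[0]["pvalue"] == pytest.approx(2 / 70, rel=1e-9)

    def test_cooccurrence_same_p_by_symmetry(self):
        m = self._matrix(
            {"g1": [1, 1, 1, 1, 0, 0, 0, 0], "g2": [1, 1, 1, 1, 0, 0, 0, 0]}
        )
        out = mutual_exclusivity(m)
        assert out.iloc[0]["pvalue"] == pytest.approx(2 / 70, rel=1e-9)

    def test_rarely_mutated_genes_excluded(self):
        m = self._matrix(
            {
                "g1": [1, 1, 1, 0, 0, 0],
                "g2": [0, 0, 1, 1, 1, 0],
                "rare": [1, 0, 0, 0, 0, 0],
            }
        )
        out = mutual_exclusivity(m, min_mutated=2)
        pairs = set(zip(out["gene_1"], out["gene_2"]))
        assert pairs == {("g1", "g2")}

    def test_no_self_pairs(self, default_cohort):
        out = mutual_exclusivity(default_cohort.mutations, min_mutated=1)
        assert (out["gene_1"] != out["gene_2"]).all()

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            MutationMatrix(pd.DataFrame({"s": [2]}, index=["g"]))


@pytest.mark.parametrize(
    "count,size,expected", [(30, 30.0, 1.0), (0, 30.0, 0.0), (45, 30.0, 1.5)]
)
def test_tmb(count, size, expected):
    assert tmb(count, size) == expected


def test_tmb_invalid_target():
    with pytest.raises(ValueError):
        tmb(10, 0.0)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1]]))
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -2], [0, 3]]))
    t = ContingencyTable(np.array([[1, 2], [3, 4]]))
    assert fisher_exact_2x2(t) == pytest.approx(fisher_two_sided_oracle([[1, 2], [3, 4]]))
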