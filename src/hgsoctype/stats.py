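"""Cohort statistics: contingency tests, group comparisons, correlation,
mutual-exclusivity screening, and tumor mutational burden.

Conventions chosen to match standard clinical-genomics reporting: the
two-sided Fisher exact test uses the point-probability rule (sum over
tables no more probable than the observed one), and Pearson's chi-square is
computed without Yates continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import bh_fdr

__all__ = [
    "ContingencyTable",
    "MutationMatrix",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "mann_whitney_u",
    "one_way_anova",
    "correlation",
    "mutual_exclusivity",
    "tmb",
]


@dataclass(frozen=True)
class ContingencyTable:
    """r x c count table with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if (np.asarray(self.counts) != arr).any():
            raise ValueError("counts must be integers")
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() < 1:
            raise ValueError("grand total must be >= 1")
        object.__setattr__(self, "counts", arr)


class MutationMatrix:
    """Binary gene x sample mutation indicator matrix."""

    def __init__(self, values: pd.DataFrame) -> None:
        arr = values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mutation matrix must be binary (0/1)")
        if values.index.duplicated().any() or values.columns.duplicated().any():
            raise ValueError("gene and sample IDs must be unique")
        self.values = values.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _as_2x2(t: ContingencyTable | np.ndarray | list) -> np.ndarray:
    arr = t.counts if isinstance(t, ContingencyTable) else np.asarray(t, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def fisher_exact_2x2(t: ContingencyTable | np.ndarray | list) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  A zero
    row or column margin yields p = 1 by convention (flagged with a warning).
    """
    arr = _as_2x2(t)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate margins (zero row/column total); p = 1 by convention")
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_rxc(t: ContingencyTable | np.ndarray | list) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (X^2, df, p).  A zero marginal makes expected counts undefined;
    the caller should collapse such rows/columns first.
    """
    arr = t.counts if isinstance(t, ContingencyTable) else np.asarray(t, dtype=int)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("chi-square requires an r x c table with r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError(
            "zero marginal row/column total; collapse empty categories before testing"
        )
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when n_x + n_y <= 20 and there are no ties,
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F test across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has < 2 values")
    within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if within == 0:
        raise ValueError("zero within-group variance; F statistic undefined")
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(res.statistic), float(res.pvalue)


def mutual_exclusivity(m: MutationMatrix, min_mutated: int = 2) -> pd.DataFrame:
    """Pairwise Fisher tests for co-occurrence vs exclusivity of mutations.

    Genes mutated in fewer than ``min_mutated`` samples are excluded.  For
    each remaining gene pair the 2x2 table (mutated/wild-type x
    mutated/wild-type) is tested two-sided; unadjusted p-values are the
    primary output (BH q-values are reported alongside).
    """
    totals = m.values.sum(axis=1)
    genes = [g for g in m.genes if totals[g] >= min_mutated]
    if len(genes) < 2:
        raise ValueError(
            f"need >= 2 genes mutated in >= {min_mutated} samples; found {len(genes)}"
        )
    rows = []
    for g1, g2 in combinations(genes, 2):
        v1 = m.values.loc[g1].to_numpy(dtype=bool)
        v2 = m.values.loc[g2].to_numpy(dtype=bool)
        both = int((v1 & v2).sum())
        only1 = int((v1 & ~v2).sum())
        only2 = int((~v1 & v2).sum())
        neither = int((~v1 & ~v2).sum())
        p = fisher_exact_2x2([[both, only1], [only2, neither]])
        rows.append(
            {
                "gene_1": g1,
                "gene_2": g2,
                "both": both,
                "only_1": only1,
                "only_2": only2,
                "neither": neither,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_fdr(out["pvalue"].tolist())
    return out


def tmb(mutation_count: int, target_size_mb: float) -> float:
    """Tumor mutational burden: somatic mutations per megabase of target."""
    if mutation_count < 0:
        raise ValueError("mutation count must be >= 0")
    if target_size_mb <= 0:
        raise ValueError("target size must be positive")
    return mutation_count / target_size_mb
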