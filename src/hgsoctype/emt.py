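"""EMT index scoring and median-split stratification.

The EMT index of a sample is the geometric mean of TPM values over a panel
of EMT transcription factors (38 genes by default).  An optional
pseudocount handles zero TPM entries: the index is

    exp( mean_g ln(TPM_g + c) ) - c

so that c = 0 recovers the plain geometric mean and the score is unbiased
at zero expression.  Cohorts are split at the median index into EMT-high
and EMT-low groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, GenePanel, Unit
from .panels import EMT38

__all__ = [
    "EMTIndexResult",
    "StratifiedCohort",
    "EMT_HIGH",
    "EMT_LOW",
    "emt_index",
    "stratify_by_median",
    "marker_correlation",
]

EMT_HIGH = "EMT-high"
EMT_LOW = "EMT-low"


@dataclass(frozen=True)
class EMTIndexResult:
    """Per-sample EMT index together with the scoring configuration."""

    index: pd.Series  # sample ID -> index, ordered as the input matrix
    panel: GenePanel
    pseudocount: float
    genes_matched: int

    @property
    def samples(self) -> list[str]:
        return list(self.index.index)

    def to_frame(self) -> pd.DataFrame:
        return self.index.rename("emt_index").to_frame()


@dataclass(frozen=True)
class StratifiedCohort:
    """Median-split group labels: EMT-high iff index >= threshold."""

    groups: pd.Series  # sample ID -> EMT_HIGH / EMT_LOW
    threshold: float

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    def high_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == EMT_HIGH])

    def low_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == EMT_LOW])


def emt_index(
    m: ExpressionMatrix,
    panel: GenePanel = EMT38,
    pseudocount: float = 0.0,
    *,
    strict: bool = False,
) -> EMTIndexResult:
    """Geometric-mean EMT index per sample.

    The score is computed over the intersection of ``panel`` with the
    matrix's genes; missing panel genes warn (error when ``strict``).  With
    pseudocount 0 a zero TPM in any matched gene drives that sample's index
    to 0, which is reported with a warning.
    """
    if m.unit != Unit.TPM:
        raise ValueError(f"EMT index is defined on TPM matrices, got unit={m.unit}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    sub = m.subset_genes(list(panel), strict=strict)
    x = sub.values.to_numpy()
    if pseudocount == 0.0:
        zero_samples = (x == 0).any(axis=0)
        if zero_samples.any():
            affected = list(np.array(sub.samples)[zero_samples])
            warnings.warn(
                f"zero TPM in panel genes drives the index to 0 for sample(s) "
                f"{affected}; consider a pseudocount"
            )
        with np.errstate(divide="ignore"):
            logs = np.log(x)
        idx = np.exp(logs.mean(axis=0))
        idx[zero_samples] = 0.0
    else:
        idx = np.exp(np.log(x + pseudocount).mean(axis=0)) - pseudocount
        # the shifted geometric mean is >= pseudocount, so this stays >= 0;
        # clip guards rounding at all-zero columns
        idx = np.clip(idx, 0.0, None)
    series = pd.Series(idx, index=sub.samples, name="emt_index")
    return EMTIndexResult(series, panel, pseudocount, genes_matched=sub.shape[0])


def stratify_by_median(r: EMTIndexResult) -> StratifiedCohort:
    """Split a cohort at the median index: EMT-high iff index >= median.

    For even n the threshold is the mean of the two middle values; the
    ``>=`` rule makes odd-n behaviour (where the median is attained) total.
    """
    if len(r.index) < 2:
        raise ValueError("stratification requires at least 2 samples")
    threshold = float(np.median(r.index.to_numpy()))
    groups = pd.Series(
        np.where(r.index.to_numpy() >= threshold, EMT_HIGH, EMT_LOW),
        index=r.index.index,
        name="group",
    )
    return StratifiedCohort(groups, threshold)


def marker_correlation(
    r: EMTIndexResult,
    m: ExpressionMatrix,
    marker: str,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate the EMT index with a marker gene's expression.

    Returns (coefficient, two-sided p-value) over the samples shared between
    the index result and the matrix.  Typical markers: CDH1 (expected down
    with EMT), VIM, CDH2, TGFB1 (expected up).
    """
    if marker not in m.values.index:
        raise KeyError(f"marker gene {marker!r} absent from matrix")
    shared = [s for s in r.samples if s in set(m.samples)]
    if len(shared) < 3:
        raise ValueError("marker correlation requires >= 3 shared samples")
    x = r.index.loc[shared].to_numpy()
    y = m.values.loc[marker, shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(res.statistic), float(res.pvalue)
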