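"""Expression matrices, unit conversion, and variable-gene selection.

The core container is :class:`ExpressionMatrix`, a gene x sample table of
abundances carrying an explicit unit tag (FPKM, TPM, or LOG2).  TPM columns
are required to sum to one million (or to one, for proportion-scale output),
which is what makes gene-panel scores comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GenePanel",
    "read_expression_table",
    "read_gene_panel",
    "fpkm_to_tpm",
    "log_transform",
    "select_variable_genes",
]

TPM_SCALE = 1e6
_TPM_RTOL = 1e-6


class Unit:
    """Allowed expression unit tags."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2 = "LOG2"

    ALL = (FPKM, TPM, LOG2)


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered set of gene symbols.

    Symbols must be unique and the panel non-empty.  Matching against
    expression matrices is exact and case-sensitive.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ValueError(f"gene panel {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if list(genes).count(g) > 1})
            raise ValueError(f"gene panel {self.name!r} has duplicate symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class ExpressionMatrix:
    """Gene x sample expression table with a declared unit.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample IDs as columns.
    unit
        One of ``Unit.FPKM``, ``Unit.TPM``, ``Unit.LOG2``.  Non-log units
        must be finite and non-negative; TPM columns must sum to 1e6
        (proportion-scale columns summing to 1 are also accepted).
    """

    def __init__(self, values: pd.DataFrame, unit: str, *, _check_tpm_sums: bool = True) -> None:
        if unit not in Unit.ALL:
            raise ValueError(f"unknown unit {unit!r}; expected one of {Unit.ALL}")
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if values.index.duplicated().any():
            dupes = sorted(values.index[values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if values.columns.duplicated().any():
            dupes = sorted(values.columns[values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if unit in (Unit.FPKM, Unit.TPM) and (arr < 0).any():
            raise ValueError(f"{unit} values must be non-negative")
        if unit == Unit.TPM and _check_tpm_sums:
            colsums = arr.sum(axis=0)
            if (colsums == 0).any():
                bad = list(values.columns[colsums == 0])
                raise ValueError(f"all-zero TPM columns: {bad}")
            target = TPM_SCALE if colsums.mean() > 1.0 else 1.0
            if not np.allclose(colsums, target, rtol=_TPM_RTOL):
                raise ValueError(
                    "TPM columns must sum to 1e6 (or 1.0 for proportion scale); "
                    f"observed sums range [{colsums.min():g}, {colsums.max():g}]"
                )
        self._df = values.astype(float)
        self.unit = unit

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        """Underlying DataFrame (genes x samples); treat as read-only."""
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def subset_genes(self, genes: Sequence[str], *, strict: bool = False) -> "ExpressionMatrix":
        """Restrict to ``genes`` (in the given order), keeping only those present.

        With ``strict=True`` a missing gene is an error; otherwise missing
        genes are reported via a warning.
        """
        present = [g for g in genes if g in self._df.index]
        missing = [g for g in genes if g not in self._df.index]
        if missing:
            if strict:
                raise KeyError(f"genes absent from matrix: {missing}")
            warnings.warn(f"{len(missing)} panel gene(s) absent from matrix: {missing}")
        if not present:
            raise KeyError("none of the requested genes are present in the matrix")
        # a gene subset of a TPM matrix no longer sums to 1e6 per column
        return ExpressionMatrix(self._df.loc[present], self.unit, _check_tpm_sums=False)

    def to_tsv(self, path: str | Path) -> None:
        out = self._df.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, unit={self.unit})"


def read_expression_table(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a delimited gene x sample table.

    First column holds gene symbols, header row holds sample IDs.  Duplicate
    gene rows and non-numeric cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df, unit)


def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` comments allowed."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GenePanel(name or path.stem, tuple(genes))


def fpkm_to_tpm(m: ExpressionMatrix, *, scale_to_million: bool = True) -> ExpressionMatrix:
    """Convert FPKM to TPM: each column is divided by its sum and rescaled.

    TPM[g, s] = FPKM[g, s] / sum_g FPKM[g, s] * 1e6.  With
    ``scale_to_million=False`` the columns are left as proportions (sum 1),
    which some workflows prefer.
    """
    if m.unit != Unit.FPKM:
        raise ValueError(f"fpkm_to_tpm expects unit=FPKM, got {m.unit}")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    out = m.values.div(colsums, axis=1)
    if scale_to_million:
        out = out * TPM_SCALE
    return ExpressionMatrix(out, Unit.TPM)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount); declared unit becomes LOG2."""
    if m.unit not in (Unit.FPKM, Unit.TPM):
        raise ValueError(f"log_transform expects FPKM or TPM input, got {m.unit}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(m.values + pseudocount), Unit.LOG2)


def select_variable_genes(m: ExpressionMatrix, n: int = 5000) -> GenePanel:
    """The ``n`` genes with highest per-gene variance across samples.

    Ties are broken by input gene order (stable sort), so the result does not
    depend on sample ordering.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > m.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {m.shape[0]}")
    variances = m.values.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")[:n]
    genes = tuple(m.values.index[i] for i in order)
    return GenePanel(f"top{n}_variable", genes)
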