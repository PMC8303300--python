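"""Gene-set overrepresentation against a GMT library.

A local stand-in for web-service transcription-factor enrichment: each set
in a GMT library (e.g. TF -> co-expressed targets) is tested for overlap
with a query gene list by the one-sided hypergeometric upper tail (Fisher
exact), p-values are adjusted by Benjamini-Hochberg, and the top hits below
an FDR cutoff are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import GenePanel

__all__ = [
    "GmtLibrary",
    "read_gmt",
    "overrepresentation",
    "bh_fdr",
    "top_enriched",
]


@dataclass(frozen=True)
class GmtLibrary:
    """Named gene sets (set name -> member genes)."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GmtLibrary:
    """Parse a Gene Matrix Transposed file.

    Each line: set name, description, then member genes, tab-delimited.
    Duplicate members within a set are de-duplicated with a warning;
    duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [g for g in fields[2:] if g]
        deduped = tuple(dict.fromkeys(members))
        if len(deduped) < len(members):
            warnings.warn(f"set {name!r}: duplicate member genes de-duplicated")
        if not deduped:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = deduped
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GmtLibrary(sets, source=str(path))


def overrepresentation(
    query: GenePanel,
    lib: GmtLibrary,
    background: int | list[str] | set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of ``query`` in each set.

    ``background`` is either the size of the gene universe or the universe
    itself; with an explicit universe, the query and every set are first
    intersected with it.  For overlap k the p-value is P(X >= k) drawing
    |query| genes from the universe containing |set| successes.  Returns a
    DataFrame indexed by set name with columns overlap, set_size,
    query_size, background, pvalue, qvalue, genes.
    """
    qgenes = set(query.genes)
    if isinstance(background, int):
        M = background
        universe = None
    else:
        universe = set(background)
        qgenes &= universe
        M = len(universe)
    if not qgenes:
        raise ValueError("query is empty (after universe intersection)")
    if len(qgenes) > M:
        raise ValueError(f"query size {len(qgenes)} exceeds background {M}")

    rows = []
    for name, members in lib.sets.items():
        mset = set(members)
        if universe is not None:
            mset &= universe
        K = len(mset)
        if K > M:
            raise ValueError(f"set {name!r} size {K} exceeds background {M}")
        overlap_genes = sorted(qgenes & mset)
        k = len(overlap_genes)
        # upper tail P(X >= k); k = 0 gives p = 1 by convention
        p = float(stats.hypergeom.sf(k - 1, M, K, len(qgenes))) if K else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": len(qgenes),
                "background": M,
                "pvalue": min(p, 1.0),
                "genes": ",".join(overlap_genes),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["qvalue"] = bh_fdr(out["pvalue"].tolist())
    return out[["overlap", "set_size", "query_size", "background", "pvalue", "qvalue", "genes"]]


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def top_enriched(
    result: pd.DataFrame,
    fdr_cut: float = 0.05,
    top_n: int = 10,
) -> pd.DataFrame:
    """Sets passing the FDR cut, best first, truncated to ``top_n``.

    Sorted by ascending p, ties by descending overlap then set name.  An
    empty result (nothing passes) is returned as-is, not an error.
    """
    passed = result[result["qvalue"] < fdr_cut].reset_index()
    passed = passed.sort_values(
        by=["pvalue", "overlap", "set"], ascending=[True, False, True], kind="stable"
    )
    return passed.set_index("set").head(top_n)
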