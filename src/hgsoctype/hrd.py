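"""Homologous-recombination-deficiency genomic scar scores.

Three integer counts are derived from a sample's allele-specific copy-number
segments, following the thresholds of the standard scar calculators:

* **LOH** — segments with one allele lost entirely (min(A, B) = 0,
  max(A, B) >= 1) longer than 15 Mb but not spanning a whole chromosome.
* **NtAI** — allelically imbalanced segments (A != B) that reach a telomere,
  do not cross the centromere, and exceed a minimum size (1 Mb).
* **LST** — large-scale state transitions: after dropping segments < 3 Mb
  and smoothing same-state neighbours, breakpoints between adjacent
  segments each >= 10 Mb and separated by < 3 Mb, counted per chromosome
  arm.

Their sum is the HRD score.  Coordinates are 1-based closed intervals, so
segment length = end - start + 1.  All thresholds are keyword-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .emt import EMTIndexResult

__all__ = [
    "Segment",
    "GenomeAnnotation",
    "SegmentProfile",
    "ScarScores",
    "toy_genome",
    "read_genome_annotation",
    "read_segment_table",
    "loh_score",
    "ntai_score",
    "lst_score",
    "hrd_sum",
    "emt_hrd_correlation",
]

MB = 1_000_000

LOH_MIN_LEN = 15 * MB
NTAI_MIN_LEN = 1 * MB
LST_MIN_FLANK = 10 * MB
LST_MAX_GAP = 3 * MB
LST_FILTER_LEN = 3 * MB


@dataclass(frozen=True)
class Segment:
    """Allele-specific copy-number segment (1-based, closed interval)."""

    chrom: str
    start: int
    end: int
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end}]")
        if self.a < 0 or self.b < 0:
            raise ValueError("allele copy numbers must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.a, self.b)

    @property
    def is_loh(self) -> bool:
        return min(self.a, self.b) == 0 and max(self.a, self.b) >= 1

    @property
    def is_imbalanced(self) -> bool:
        return self.a != self.b


@dataclass(frozen=True)
class GenomeAnnotation:
    """Chromosome lengths and centromere intervals (1-based, bp)."""

    chromosomes: dict[str, tuple[int, int, int]]  # name -> (length, cen_start, cen_end)

    def __post_init__(self) -> None:
        for name, (length, cs, ce) in self.chromosomes.items():
            if not 0 < cs < ce < length:
                raise ValueError(
                    f"chromosome {name!r}: need 0 < cen_start < cen_end < length, "
                    f"got ({length}, {cs}, {ce})"
                )

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom][0]

    def centromere(self, chrom: str) -> tuple[int, int]:
        _, cs, ce = self.chromosomes[chrom]
        return cs, ce

    def arm_boundary(self, chrom: str) -> float:
        cs, ce = self.centromere(chrom)
        return (cs + ce) / 2.0


def toy_genome() -> GenomeAnnotation:
    """Three-chromosome toy genome used by the synthetic cohort and tests."""
    return GenomeAnnotation(
        {
            "chr1": (230 * MB, 90 * MB, 95 * MB),
            "chr2": (180 * MB, 85 * MB, 90 * MB),
            "chr3": (160 * MB, 70 * MB, 75 * MB),
        }
    )


def read_genome_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "cen_start", "cen_end"}
    if not required <= set(df.columns):
        raise ValueError(f"genome annotation must have columns {sorted(required)}")
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names in genome annotation")
    return GenomeAnnotation(
        {
            str(r.chrom): (int(r.length), int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        }
    )


class SegmentProfile:
    """Per-sample list of non-overlapping segments, sorted by position."""

    def __init__(self, sample_id: str, segments: Iterable[Segment]) -> None:
        self.sample_id = sample_id
        segs = sorted(segments, key=lambda s: (s.chrom, s.start))
        for prev, cur in zip(segs, segs[1:]):
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise ValueError(
                    f"{sample_id}: overlapping segments on {cur.chrom} "
                    f"({prev.start}-{prev.end} and {cur.start}-{cur.end})"
                )
        self.segments: list[Segment] = segs

    def validate(self, genome: GenomeAnnotation) -> None:
        for seg in self.segments:
            if seg.chrom not in genome.chromosomes:
                raise ValueError(f"{self.sample_id}: unknown chromosome {seg.chrom!r}")
            if seg.end > genome.length(seg.chrom):
                raise ValueError(
                    f"{self.sample_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"exceeds chromosome length {genome.length(seg.chrom)}"
                )

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    loh: int
    ntai: int
    lst: int

    @property
    def hrd_sum(self) -> int:
        return self.loh + self.ntai + self.lst


def read_segment_table(path: str | Path) -> list[SegmentProfile]:
    """Read a TSV with columns sample, chrom, start, end, nA, nB."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "nA", "nB"}
    if not required <= set(df.columns):
        raise ValueError(f"segment table must have columns {sorted(required)}")
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        segs = [
            Segment(str(r.chrom), int(r.start), int(r.end), int(r.nA), int(r.nB))
            for r in grp.itertuples()
        ]
        profiles.append(SegmentProfile(str(sample), segs))
    return profiles


def loh_score(
    p: SegmentProfile, g: GenomeAnnotation, *, min_len: int = LOH_MIN_LEN
) -> int:
    """Count LOH segments longer than ``min_len``, excluding whole chromosomes."""
    p.validate(g)
    count = 0
    for seg in p.segments:
        whole = seg.start == 1 and seg.end == g.length(seg.chrom)
        if seg.is_loh and seg.length > min_len and not whole:
            count += 1
    return count


def ntai_score(
    p: SegmentProfile, g: GenomeAnnotation, *, min_len: int = NTAI_MIN_LEN
) -> int:
    """Count telomeric allelic imbalances not crossing the centromere."""
    p.validate(g)
    count = 0
    for seg in p.segments:
        if not seg.is_imbalanced or seg.length < min_len:
            continue
        telomeric = seg.start == 1 or seg.end == g.length(seg.chrom)
        cs, ce = g.centromere(seg.chrom)
        crosses_cen = seg.start <= ce and seg.end >= cs
        if telomeric and not crosses_cen:
            count += 1
    return count


def lst_score(
    p: SegmentProfile,
    g: GenomeAnnotation,
    *,
    min_flank: int = LST_MIN_FLANK,
    max_gap: int = LST_MAX_GAP,
    filter_len: int = LST_FILTER_LEN,
) -> int:
    """Count large-scale state transitions per chromosome arm.

    Segments shorter than ``filter_len`` are removed, then adjacent
    same-state segments closer than ``max_gap`` are merged; a breakpoint
    counts when both flanking segments are >= ``min_flank`` long, differ in
    state, sit on the same arm, and are separated by < ``max_gap``.
    """
    p.validate(g)
    count = 0
    for chrom, segs in p.by_chromosome().items():
        kept = [s for s in segs if s.length >= filter_len]
        merged: list[Segment] = []
        for seg in kept:
            if (
                merged
                and merged[-1].state == seg.state
                and seg.start - merged[-1].end - 1 < max_gap
            ):
                last = merged.pop()
                merged.append(Segment(chrom, last.start, seg.end, seg.a, seg.b))
            else:
                merged.append(seg)
        boundary = g.arm_boundary(chrom)
        for left, right in zip(merged, merged[1:]):
            gap = right.start - left.end - 1
            if (
                left.length >= min_flank
                and right.length >= min_flank
                and gap < max_gap
                and left.state != right.state
                and _arm_of(left, boundary) == _arm_of(right, boundary)
            ):
                count += 1
    return count


def _arm_of(seg: Segment, boundary: float) -> str:
    """Arm holding the larger share of the segment (split at centromere midpoint)."""
    p_share = max(0.0, min(seg.end, boundary) - seg.start + 1)
    q_share = max(0.0, seg.end - max(seg.start, boundary) + 1)
    return "p" if p_share >= q_share else "q"


def hrd_sum(p: SegmentProfile, g: GenomeAnnotation, **thresholds) -> ScarScores:
    """All three scar scores for one profile.

    Threshold overrides are routed by prefix: ``loh_min_len``,
    ``ntai_min_len``, ``lst_min_flank``, ``lst_max_gap``, ``lst_filter_len``.
    """
    loh_kw = {"min_len": thresholds["loh_min_len"]} if "loh_min_len" in thresholds else {}
    ntai_kw = {"min_len": thresholds["ntai_min_len"]} if "ntai_min_len" in thresholds else {}
    lst_kw = {
        k.removeprefix("lst_"): v for k, v in thresholds.items() if k.startswith("lst_")
    }
    unknown = set(thresholds) - {
        "loh_min_len", "ntai_min_len", "lst_min_flank", "lst_max_gap", "lst_filter_len",
    }
    if unknown:
        raise TypeError(f"unknown threshold keys: {sorted(unknown)}")
    return ScarScores(
        p.sample_id,
        loh=loh_score(p, g, **loh_kw),
        ntai=ntai_score(p, g, **ntai_kw),
        lst=lst_score(p, g, **lst_kw),
    )


def emt_hrd_correlation(
    scores: list[ScarScores], r: EMTIndexResult
) -> tuple[float, float]:
    """Spearman correlation between HRD sums and EMT indices (shared samples).

    In the two-type model the HRR-activated tumors carry the scars and the
    mesenchymal tumors the high EMT index, so a negative rho is expected.
    """
    by_sample = {s.sample_id: s.hrd_sum for s in scores}
    shared = [s for s in r.samples if s in by_sample]
    if len(shared) < 3:
        raise ValueError("Spearman correlation requires >= 3 shared samples")
    x = np.array([by_sample[s] for s in shared], dtype=float)
    y = r.index.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
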