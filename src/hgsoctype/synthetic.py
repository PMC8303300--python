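"""Synthetic two-subtype HGSOC cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without external data:

* log-normal expression (normal in log2 space, exponentiated, column-
  normalized to TPM) with EMT-TF genes, VIM and TGFB1 shifted up and CDH1
  shifted down in the mesenchymal subtype, and HRR genes shifted up in the
  HRR-activated subtype;
* exponential survival with a configurable hazard ratio for the
  mesenchymal group and independent uniform censoring;
* allele-specific copy-number segments realizing Poisson numbers of
  qualifying LOH / NtAI / LST events on a three-chromosome toy genome,
  with far more scar events in the HRR-activated group;
* a near-disjoint driver-mutation pattern (TP53 common to both subtypes,
  one subtype-biased driver per sample).

Everything is drawn from a single seeded generator, so a config + seed pair
reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import SUBTYPE_HRR, SUBTYPE_MES
from .expression import ExpressionMatrix, TPM_SCALE, Unit
from .hrd import MB, GenomeAnnotation, Segment, SegmentProfile, toy_genome
from .panels import EMT38, HRR30
from .stats import MutationMatrix
from .survival import SurvivalRecord

__all__ = ["CohortConfig", "SyntheticCohort", "generate", "truth_report", "write_cohort"]

MARKER_UP = ("VIM", "TGFB1")
MARKER_DOWN = ("CDH1",)

_TP53_RATE = 0.9
_HRR_DRIVERS = ("BRCA1", "BRCA2", "ATR", "ATRX", "RAD51B")
_MES_DRIVERS = ("NF1", "RB1", "CDK12", "PTEN", "CCNE1")

# segment-placement geometry (bp); gaps of >= 3 Mb keep independently
# placed events from forming unintended large-scale transitions
_TEL_RESERVE = 15 * MB
_EVENT_GAP = 3 * MB
_LOH_LEN = 16 * MB
_LST_SEG_MIN_MB, _LST_SEG_MAX_MB = 10, 12
_NTAI_MIN_MB, _NTAI_MAX_MB = 5, 12


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a two-subtype cohort.

    Defaults mirror a 20-sample design: 10 HRR-activated + 10 mesenchymal
    samples, 2000 genes including the EMT38 and HRR30 panels, log2 shifts
    of +2 (EMT program, mesenchymal) and +1.5 (HRR program, HRR-activated)
    over within-subtype noise of sd 0.5, exponential survival with a median
    of 45 months in the HRR-activated group and hazard ratio 2.5 for the
    mesenchymal group, and Poisson scar-event means (LOH, NtAI, LST) of
    (10, 8, 12) vs (2, 2, 3).
    """

    n_hrr: int = 10
    n_mes: int = 10
    n_genes: int = 2000
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    emt_shift: float = 2.0
    hrr_shift: float = 1.5
    noise_sd: float = 0.5
    median_survival_months: float = 45.0
    hazard_ratio: float = 2.5
    censor_range: tuple[float, float] = (20.0, 80.0)
    scar_means_hrr: tuple[float, float, float] = (10.0, 8.0, 12.0)
    scar_means_mes: tuple[float, float, float] = (2.0, 2.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hrr < 1 or self.n_mes < 1:
            raise ValueError("each subtype needs at least one sample")
        if self.base_log2_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.median_survival_months <= 0 or self.hazard_ratio <= 0:
            raise ValueError("survival parameters must be positive")
        if not 0 < self.censor_range[0] < self.censor_range[1]:
            raise ValueError("censor_range must be an increasing positive interval")
        if any(v <= 0 for v in self.scar_means_hrr + self.scar_means_mes):
            raise ValueError("scar-event means must be positive")
        reserved = len(self._named_genes())
        if self.n_genes < reserved:
            raise ValueError(f"n_genes must be >= {reserved} to embed the panels")

    @staticmethod
    def _named_genes() -> list[str]:
        named = list(EMT38) + [g for g in HRR30 if g not in set(EMT38)]
        for extra in MARKER_UP + MARKER_DOWN + ("TP53",) + _HRR_DRIVERS + _MES_DRIVERS:
            if extra not in named:
                named.append(extra)
        return named


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: all components share sample IDs."""

    expression: ExpressionMatrix
    subtypes: pd.Series  # sample ID -> SUBTYPE_HRR / SUBTYPE_MES
    survival: list[SurvivalRecord]
    segments: list[SegmentProfile]
    mutations: MutationMatrix
    genome: GenomeAnnotation
    config: CohortConfig
    realized_scars: pd.DataFrame  # sample x (loh, ntai, lst) placed events

    @property
    def samples(self) -> list[str]:
        return list(self.subtypes.index)


def generate(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Draw a full cohort from ``config`` (deterministic given config.seed)."""
    rng = np.random.default_rng(config.seed)
    genome = toy_genome()

    samples = [f"HRR{i + 1:02d}" for i in range(config.n_hrr)] + [
        f"MES{i + 1:02d}" for i in range(config.n_mes)
    ]
    subtypes = pd.Series(
        [SUBTYPE_HRR] * config.n_hrr + [SUBTYPE_MES] * config.n_mes,
        index=samples,
        name="subtype",
    )

    expression = _draw_expression(rng, config, samples, subtypes)
    survival = _draw_survival(rng, config, samples, subtypes)
    segments, realized = _draw_segments(rng, config, samples, subtypes, genome)
    mutations = _draw_mutations(rng, samples, subtypes)

    return SyntheticCohort(
        expression=expression,
        subtypes=subtypes,
        survival=survival,
        segments=segments,
        mutations=mutations,
        genome=genome,
        config=config,
        realized_scars=realized,
    )


def _gene_list(config: CohortConfig) -> list[str]:
    named = CohortConfig._named_genes()
    fillers = [f"G{i + 1:04d}" for i in range(config.n_genes - len(named))]
    return named + fillers


def _draw_expression(
    rng: np.random.Generator,
    config: CohortConfig,
    samples: list[str],
    subtypes: pd.Series,
) -> ExpressionMatrix:
    genes = _gene_list(config)
    n_g, n_s = len(genes), len(samples)
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_g)

    shift = np.zeros((n_g, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    mes_cols = np.array([subtypes[s] == SUBTYPE_MES for s in samples])
    hrr_cols = ~mes_cols
    for g in EMT38:
        shift[gene_pos[g], mes_cols] += config.emt_shift
    for g in MARKER_UP:
        shift[gene_pos[g], mes_cols] += config.emt_shift
    for g in MARKER_DOWN:
        shift[gene_pos[g], mes_cols] -= config.emt_shift
    for g in HRR30:
        shift[gene_pos[g], hrr_cols] += config.hrr_shift

    log2x = base[:, None] + shift + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    linear = np.exp2(log2x)
    tpm = linear / linear.sum(axis=0, keepdims=True) * TPM_SCALE
    return ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples), Unit.TPM)


def _draw_survival(
    rng: np.random.Generator,
    config: CohortConfig,
    samples: list[str],
    subtypes: pd.Series,
) -> list[SurvivalRecord]:
    lam_hrr = np.log(2.0) / config.median_survival_months
    records = []
    for s in samples:
        lam = lam_hrr * (config.hazard_ratio if subtypes[s] == SUBTYPE_MES else 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(*config.censor_range)
        observed = min(t_event, t_censor)
        records.append(
            SurvivalRecord(s, max(observed, 1e-6), int(t_event <= t_censor), subtypes[s])
        )
    return records


def _draw_segments(
    rng: np.random.Generator,
    config: CohortConfig,
    samples: list[str],
    subtypes: pd.Series,
    genome: GenomeAnnotation,
) -> tuple[list[SegmentProfile], pd.DataFrame]:
    profiles = []
    realized_rows = []
    for s in samples:
        means = (
            config.scar_means_mes
            if subtypes[s] == SUBTYPE_MES
            else config.scar_means_hrr
        )
        n_loh, n_ntai, n_lst = (int(rng.poisson(m)) for m in means)
        segs, realized = _place_events(rng, genome, n_loh, n_ntai, n_lst)
        profiles.append(SegmentProfile(s, segs))
        realized_rows.append({"sample": s, **realized})
    realized_df = pd.DataFrame(realized_rows).set_index("sample")
    return profiles, realized_df


def _place_events(
    rng: np.random.Generator,
    genome: GenomeAnnotation,
    n_loh: int,
    n_ntai: int,
    n_lst: int,
) -> tuple[list[Segment], dict[str, int]]:
    """Realize event counts as valid, non-interacting segments.

    Telomeric imbalances occupy chromosome ends; interstitial events are
    laid left-to-right inside arm interiors (telomere reserves and the
    centromere excluded) with >= 3 Mb spacing so each placed event
    contributes exactly one qualifying scar.  Counts exceeding the genome's
    capacity are truncated; the realized counts are returned.
    """
    segs: list[Segment] = []
    chroms = list(genome.chromosomes)

    # telomeric allelic imbalances: one slot per chromosome end
    slots = [(c, "p") for c in chroms] + [(c, "q") for c in chroms]
    placed_ntai = min(n_ntai, len(slots))
    for c, arm in slots[:placed_ntai]:
        tel_len = int(rng.integers(_NTAI_MIN_MB, _NTAI_MAX_MB + 1)) * MB
        L = genome.length(c)
        if arm == "p":
            segs.append(Segment(c, 1, tel_len, 2, 1))
        else:
            segs.append(Segment(c, L - tel_len + 1, L, 2, 1))

    # arm interiors available for interstitial events
    arms = []
    for c in chroms:
        L = genome.length(c)
        cs, ce = genome.centromere(c)
        arms.append({"chrom": c, "cursor": _TEL_RESERVE + 1, "hi": cs - 1})
        arms.append({"chrom": c, "cursor": ce + 1, "hi": L - _TEL_RESERVE})
    arms.sort(key=lambda a: a["cursor"] - a["hi"])  # widest first

    # large-scale transitions: chained runs of alternating-state segments,
    # each appended segment past the first adds one breakpoint
    placed_lst = 0
    for arm in arms:
        if placed_lst >= n_lst:
            break
        seg_len = lambda: int(rng.integers(_LST_SEG_MIN_MB, _LST_SEG_MAX_MB + 1)) * MB
        first = seg_len()
        if arm["hi"] - arm["cursor"] + 1 < first + _LST_SEG_MIN_MB * MB:
            continue
        start = arm["cursor"]
        segs.append(Segment(arm["chrom"], start, start + first - 1, 1, 1))
        arm["cursor"] = start + first
        state = (2, 1)
        while placed_lst < n_lst:
            ln = seg_len()
            if arm["hi"] - arm["cursor"] + 1 < ln:
                break
            segs.append(
                Segment(arm["chrom"], arm["cursor"], arm["cursor"] + ln - 1, *state)
            )
            arm["cursor"] += ln
            placed_lst += 1
            state = (1, 1) if state == (2, 1) else (2, 1)
        arm["cursor"] += _EVENT_GAP + 1

    # interstitial LOH blocks
    placed_loh = 0
    while placed_loh < n_loh:
        arm = next(
            (a for a in arms if a["hi"] - a["cursor"] + 1 >= _LOH_LEN), None
        )
        if arm is None:
            break
        segs.append(
            Segment(arm["chrom"], arm["cursor"], arm["cursor"] + _LOH_LEN - 1, 1, 0)
        )
        arm["cursor"] += _LOH_LEN + _EVENT_GAP + 1
        placed_loh += 1

    return segs, {"loh": placed_loh, "ntai": placed_ntai, "lst": placed_lst}


def _draw_mutations(
    rng: np.random.Generator, samples: list[str], subtypes: pd.Series
) -> MutationMatrix:
    genes = ["TP53", *_HRR_DRIVERS, *_MES_DRIVERS]
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for s in samples:
        if rng.uniform() < _TP53_RATE:
            mat.loc["TP53", s] = 1
        pool = _HRR_DRIVERS if subtypes[s] == SUBTYPE_HRR else _MES_DRIVERS
        mat.loc[pool[int(rng.integers(len(pool)))], s] = 1
    return MutationMatrix(mat)


def truth_report(c: SyntheticCohort) -> pd.DataFrame:
    """Per-sample ground truth used for parameter-recovery tests."""
    rows = []
    for s in c.samples:
        means = (
            c.config.scar_means_mes
            if c.subtypes[s] == SUBTYPE_MES
            else c.config.scar_means_hrr
        )
        realized = c.realized_scars.loc[s]
        rows.append(
            {
                "sample": s,
                "subtype": c.subtypes[s],
                "hazard_group": c.subtypes[s],
                "expected_scar_sum": float(sum(means)),
                "realized_loh": int(realized["loh"]),
                "realized_ntai": int(realized["ntai"]),
                "realized_lst": int(realized["lst"]),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def write_cohort(c: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the standard TSVs the CLIs consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["expression"] = outdir / "expression.tsv"
    c.expression.to_tsv(paths["expression"])

    paths["subtypes"] = outdir / "subtypes.tsv"
    c.subtypes.rename_axis("sample").to_frame().to_csv(paths["subtypes"], sep="\t")

    paths["survival"] = outdir / "survival.tsv"
    pd.DataFrame(
        [
            {"sample": r.sample_id, "time_months": r.time, "event": r.event, "group": r.group}
            for r in c.survival
        ]
    ).to_csv(paths["survival"], sep="\t", index=False)

    paths["segments"] = outdir / "segments.tsv"
    pd.DataFrame(
        [
            {
                "sample": p.sample_id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "nA": seg.a,
                "nB": seg.b,
            }
            for p in c.segments
            for seg in p.segments
        ],
        columns=["sample", "chrom", "start", "end", "nA", "nB"],
    ).to_csv(paths["segments"], sep="\t", index=False)

    paths["genome"] = outdir / "genome.tsv"
    pd.DataFrame(
        [
            {"chrom": name, "length": L, "cen_start": cs, "cen_end": ce}
            for name, (L, cs, ce) in c.genome.chromosomes.items()
        ]
    ).to_csv(paths["genome"], sep="\t", index=False)

    paths["mutations"] = outdir / "mutations.tsv"
    out = c.mutations.values.copy()
    out.index.name = "gene"
    out.to_csv(paths["mutations"], sep="\t")

    paths["truth"] = outdir / "truth.tsv"
    truth_report(c).to_csv(paths["truth"], sep="\t")
    return paths
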