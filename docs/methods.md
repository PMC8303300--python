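# Methods

This note documents the models, conventions and design choices behind
`hgsoctype`, in the spirit of a statistical-methods appendix.

## EMT index

The index is a geometric mean of TPM values over a transcription-factor
panel. The pseudocount variant is

    EMT(s) = exp( mean_g ln(x_gs + c) ) − c,   c ≥ 0,

which reduces to the plain geometric mean at `c = 0` and maps an all-zero
sample to 0 for any `c`. With `c = 0` a single zero TPM annihilates the
product; the scorer then returns 0 and warns, because public FPKM matrices
regularly contain zeros for rarely expressed TFs (e.g. TBXT) and a silent 0
would be easy to misread as biology. Whether the original index added a
pseudocount or filtered zeros is not documented; both behaviours are
exposed and the default is the literal geometric mean.

Properties relied on by tests: scale equivariance at `c = 0` (scaling all
panel TPMs by `k` scales the index by `k`), permutation invariance in genes
and samples, and the identity that a constant-TPM panel scores that
constant.

The median split labels a sample EMT-high iff `index ≥ median`. With an
even sample count the median (mean of the two middle values) is typically
not attained, so the boundary rule only matters for odd counts and ties; `≥`
makes it total and deterministic.

## Unit conversion

`fpkm_to_tpm` divides each column by its sum and rescales by 1e6 — standard
TPM. The proportion step is idempotent, and column sums of 1e6 are enforced
as a container invariant (proportion-scale output is available for
workflows that prefer sums of 1). Gene subsets of a TPM matrix keep the
unit tag but are exempt from the column-sum invariant.

For clustering, TPM values are log2(x + 1)-transformed. This is a declared
substitute for count-level variance stabilization: the package takes
abundance matrices as input and deliberately does not reimplement
count-based normalization.

## Subtyping

PCA treats samples as observations and centers each gene; components are
deterministic up to sign. K-means with k = 2 runs on the first two
principal coordinates (matching how the two clusters present visually in
PC space; full expression space is available by passing other coordinates),
with a fixed default seed (17) and 50 restarts, keeping the partition
reproducible and, on small cohorts, equal to the exhaustive minimal-WCSS
bipartition (verified against a brute-force oracle in tests). Hierarchical
clustering z-scores each panel gene, uses 1 − Pearson correlation between
samples and average linkage, and cuts the tree at two clusters — the common
expression-heatmap defaults, chosen because the original metric/linkage are
not documented.

Cluster naming and orientation rules are made explicit so results are
reproducible across runs:

- cluster "A" is the cluster with the lower mean EMT index (the
  HRR-activated side) when an index is supplied, else the cluster whose
  lexicographically first member comes first;
- the subtype rule labels the higher-mean-EMT cluster mesenchymal; an exact
  tie labels the smaller cluster mesenchymal and sets a flag;
- PC1's sign is oriented so the EMT index correlates positively with it, so
  "genes positively correlated with PC1" always means mesenchymal-side
  genes. Constant genes are excluded from correlation screens and reported
  in a skip list.

## Overrepresentation

The enrichment module is a local, single-library overrepresentation test:
one-sided hypergeometric upper tail `P(X ≥ k)` for overlap `k`, with
`P(X ≥ 0) = 1` by convention, BH step-up q-values across the library, and
top-10-under-FDR-0.05 reporting by default. Web services that integrate
multiple libraries by mean rank will agree in spirit, not numerically; the
hypergeometric is the standard ORA statistic and is what this module
promises. The default background should be the number of genes in the
filtered expression matrix.

## HRD scar scores

The three counts follow the thresholds of the established scar
calculators; the citing literature does not pin an implementation, so all
thresholds are keyword arguments with these defaults:

| score | rule | default thresholds |
|---|---|---|
| LOH | min(A,B) = 0, max(A,B) ≥ 1, not whole-chromosome | length > 15 Mb |
| NtAI | A ≠ B, reaches a telomere, no centromere overlap | length ≥ 1 Mb |
| LST | breakpoint between adjacent large segments on one arm | flanks ≥ 10 Mb, gap < 3 Mb, 3 Mb pre-filter |

Coordinates are 1-based closed intervals (length = end − start + 1). For
LST, segments < 3 Mb are removed, then same-state neighbours closer than
3 Mb are merged; arms split at the centromere midpoint, and a segment
overlapping the centromere belongs to the arm holding its larger share.
"Crossing the centromere" for NtAI means any overlap with the annotated
centromere interval. The scores are invariant to segment order, to a global
A/B allele swap, and are additive over chromosomes. Per-sample numeric
equality with any particular published scar pipeline is not claimed.

## Cohort statistics

Two conventions are fixed because they determine published-table p-values
to the printed decimals: the two-sided Fisher exact test sums the
hypergeometric point probabilities of all tables (same margins) no more
probable than the observed table, and Pearson's chi-square carries no Yates
continuity correction. Mann–Whitney uses the exact permutation null when
`n_x + n_y ≤ 20` with no ties, else the normal approximation with tie and
continuity corrections. The mutual-exclusivity screen reports unadjusted
pairwise Fisher p-values (the convention when the claim is "no pair
co-occurs"), with BH q-values always alongside; genes mutated in fewer
than 2 samples are excluded by default since their tables are
uninformative.

## Survival

Kaplan–Meier with the standard tie convention (censored subjects tied with
an event time are still at risk at that time), median survival as the first
event time with `S(t) ≤ 0.5` (`None` when never reached), and the two-group
log-rank test with hypergeometric variance. When a "mean survival" is
needed, the restricted mean up to the largest observed time is used, the
usual reading when no horizon is quoted. Cox regression is deliberately
out of scope — the stratified comparisons here are univariable — but the
log-rank statistic is cross-checked in tests against a numeric score test
of the two-group Cox partial likelihood.

## Synthetic cohort generator

The generator produces the data-generating process the analysis assumes,
not realistic RNA-seq reads:

- **Expression.** Per-gene baseline means drawn once from N(5, 2) in log2
  space; subtype shifts added (+2 on the EMT38 panel, VIM and TGFB1, −2 on
  CDH1 in mesenchymal samples; +1.5 on the HRR30 panel in HRR-activated
  samples); within-subtype noise N(0, 0.5²); exponentiated and column-
  normalized to TPM. Defaults give a 10 + 10 cohort that is recoverable but
  not trivially separable.
- **Survival.** Exponential with median 45 months for HRR-activated
  samples and hazard ratio 2.5 for mesenchymal samples; independent
  uniform censoring on [20, 80] months.
- **Scars.** Per-sample Poisson counts with means (LOH, NtAI, LST) =
  (10, 8, 12) for HRR-activated vs (2, 2, 3) for mesenchymal, realized as
  valid segments on a bundled three-chromosome toy genome (230/180/160 Mb,
  centromeres annotated). Telomeric imbalances occupy chromosome-end
  slots; interstitial events are laid left-to-right with ≥ 3 Mb spacing so
  each placed event contributes exactly one qualifying scar, and LST events
  are chained as alternating-state runs. Counts beyond the genome's
  capacity are truncated (relevant mainly to NtAI, capped at six telomere
  slots); the realized counts are the ground truth reported by
  `truth_report` and they equal what the scoring functions return on the
  generated profiles.
- **Mutations.** TP53 mutated in 90% of samples; every sample carries
  exactly one additional driver drawn from a subtype-specific list, giving
  the near-disjoint ("mutually exclusive") pattern the pairwise Fisher
  screen expects.

All draws come from one `numpy` generator seeded by the config, so a
config + seed pair regenerates the cohort bit for bit.

What the generator does **not** model: tumor purity and stromal admixture
(a major driver of real mesenchymal signatures), copy-number effects on
expression, library-size or gene-length biases, overdispersed count noise,
and correlation between expression programs beyond the two subtype shifts.
Passing recovery tests therefore demonstrates internal consistency of the
pipeline under its assumed model, not field performance on real cohorts.

## Problem sizes in tests and the acceptance script

Recovery checks use 100 generated cohorts at the default 20-sample design
(PCA on the top 1000 of 2000 genes — the generator's gene count makes the
top-5000 default moot), and survival power uses 200 replicates at 90 + 90
subjects with a reduced 100-gene expression matrix, since only the survival
component enters that check. Exhaustive oracle comparisons (Fisher margin
enumeration, Mann–Whitney permutation enumeration, k-means bipartition)
run at the small instance sizes where enumeration is exact.

## Known limitations

- Gene symbols match exactly and case-sensitively; no alias resolution.
- The HRR30 panel completes a partially published gene list with canonical
  HRR pathway members and is explicitly a replaceable default.
- Overrepresentation agrees with rank-integrating TF-enrichment services
  only qualitatively.
- Scar-score thresholds are literature defaults, not a re-derivation of any
  specific pipeline's output.
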