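# Methods

## Problem and model

`linematch` quantifies how closely each cell line in a panel resembles a
tumour cohort at the DNA level, for tumour types — exemplified by high-grade
serous ovarian cancer (HGSOC) — whose genomic signature is extensive
copy-number alteration, near-universal *TP53* mutation and a low coding
mutation rate. The comparison has three layers: copy-number concordance,
coverage-corrected mutation burden with marker-gene genotype, and an
expression-side corroboration.

### Copy-number layer

Segmented profiles carry per-segment log2 copy ratios
`CN = log2(sample intensity / reference intensity)`. Coordinates are
**1-based, fully closed** (the convention of portal SEG exports), so a
segment's length is `end − start + 1`; the fraction genome altered is

```
FGA(T) = Σ L(i)·[|CN_i| > T] / Σ L(i)
```

with strict inequality (a segment exactly at T is unaltered) and both gains
and losses counting as alterations. L(i) is the base-pair length — probe
counts are not used; this is an assumption, stated here because the two
choices differ when probe density varies. Thresholds default to T = 0.2 for
tumours and T = 0.3 for cell lines: tumour signal is attenuated by stromal
contamination and heterogeneity, cell lines are purer. The same purity
reasoning sets the high-level amplification call at log2 ratio **> 1.0**
(strict) for cell lines, and the homozygous-deletion call — which is not
given in the analysis being reproduced and is our symmetric choice — at
**< −1.0**; both are configurable.

Gene-level values are the **segment-length-weighted mean** of the log2
ratios of all segments overlapping the gene interval. The weighted mean is
robust for genes straddling breakpoints; a `largest_overlap` rule is
available as a config alternative. Genes covered by no segment are missing
for that sample, and missingness propagates (pairwise-complete correlation,
never silent zeros). The cohort's **mean CNA profile** is the per-gene
arithmetic mean over samples with a present value; by default it includes
every cohort sample, including any flat TP53-wild-type outliers (excluding
them is a caller-side subset choice). Similarity of a line to the cohort is
summarised three ways, all Pearson: against every single tumour (median and
maximum reported) and against the mean profile (component A of the score).
Undefined correlations — under three complete pairs, or an exactly constant
vector — are flagged, warned about, and excluded from the median.

### Mutation layer

Mutation catalogues are MAF-style records with a controlled classification
vocabulary; the spelling map from dataset dialects is an editable YAML
(`linematch/data/maf_classes.yaml`) because vocabularies drift. The
likely-functional filter removes intron, 5'/3' UTR, flank, intergenic,
silent and RNA classes; splice-site and in-frame indel classes are
retained. Burden is

```
frequency_per_mb = functional mutation count / bases covered × 10^6
```

with the denominator from either coverage dialect: per-base (count of
positions with ≥ 1 read; internally run-length encoded so genome-scale
tracks stay cheap) or per-exon (Σ exon_length × coverage_fraction,
accumulated in real arithmetic and rounded once at the end to avoid
per-row rounding bias). Each record counts once; multiple mutations in the
same gene are not collapsed (the alternative is a documented switch a
caller can implement by deduplicating records). Catalogues may contain
germline variants if the upstream data does — the burden reflects the
input's convention rather than hiding the asymmetry between cohorts.

A sample is a **hypermutator** when `frequency_per_mb > 10` and
`FGA < 0.25` (both configurable). The thresholds separate an outlier
archetype (≥ 13/Mb with visibly flat profiles in the motivating panel)
from a background around 4/Mb by a wide margin.

### Score and grouping

`S = w_A·A + w_B·B − w_C·C − w_D·D`. The published form of the score gives
the component definitions and sign language but not numeric weights; the
defaults (1, 0.5, 0.5, 0.25) make each term's dynamic range comparable
(A spans ≈ 1 unit; B and C half a unit; D/4 at most 1.75) and every run's
output embeds the weights used, so results are interpretable and
re-weightable. Mutation frequency enters only through the binary C, exactly
as the component definitions state. Ranking sorts by S descending with
exact ties broken by A descending then sample id (noted per entry); tiers
are either top/bottom counts (default 12/12, mirroring "the twelve best
candidates") or score cut points. The ordering separates better from worse
models; it is not a finely graduated ranking.

### Expression layer

Robust z-scores are `(x − median) / MAD` per gene, with the **plain** MAD —
no 1.4826 consistency factor — because that is the definition used in the
analysis being reproduced; a switch provides the scaled variant. Genes with
MAD = 0 have no defined z-score and are dropped with a logged count.
Variable genes are the top N by interquartile range (type-7
linear-interpolation quantiles; boundary ties broken lexicographically and
recorded), N = 5,000 by default. Sample distances are `1 − c` (Pearson),
clustered with Ward linkage for a single panel and complete linkage for
combined cell-line/tumour analyses (scipy's deterministic implementation).
PCA operates on the gene-centred matrix with the sign of each axis fixed so
its largest-magnitude loading is positive. `combine_datasets` z-scores two
platforms separately and joins them on the shared-gene intersection,
keeping per-sample dataset labels.

Cell lines are ranked by the mean of their Pearson correlations with all
tumours over shared genes, on the expression profiles **as given** (no
per-gene standardisation first). The reason is structural: per-dataset
per-gene centering forces every dataset's median profile to zero, so any
component common to a dataset is removed and the surviving cross-dataset
correlation is a product of fluctuations whose cohort-level mean sign is
not identifiable in a low-rank model — rankings computed that way are
sign-unstable. Plain profile correlations measure what the ranking intends:
whether a line's expression landscape looks like the tumours'. Callers who
want the standardised variant can pass z-scored matrices explicitly.

Concordance between the suitability and expression orderings is Kendall's
**tau-b** (tie-corrected, since tier-derived rankings may tie) with a
two-sided p-value from exhaustive permutation enumeration for n ≤ 8 and
from the tie-corrected normal approximation with a continuity correction
above; the method used is recorded in the result.

## Synthetic data: what it emulates and what it does not

The generator realises the statistical structure the analysis assumes, with
ground truth for every planted feature:

* **Tumours** (default 100 per cohort): recurrent gains/losses on the first
  sixteen synthetic chromosomes (middle two thirds of each, amplitude 0.9,
  prevalence 0.9, Gaussian segment noise σ = 0.1), sized so the cohort's
  median FGA sits near the ~46% characteristic of the emulated tumour type;
  *TP53* mutated with probability 0.95 among non-flat tumours; a 5% flat
  TP53-wild-type subpopulation; functional mutation rate 1.6/Mb over 30 Mb
  of per-exon coverage.
* **Cell lines** (default 30 HGSOC-like + 12 non-HGSOC + 5 hypermutators =
  47): HGSOC-like lines are the tumour mean profile plus per-gene noise
  (σ = 0.1), TP53-mutated, non-HGSOC panel clean; non-HGSOC lines are flat,
  TP53-wild-type, with 1–3 planted mutations from the seven-gene panel;
  hypermutators are flat with functional rate λ_high = 15/Mb versus the
  λ_background = 4/Mb of other lines, over 30 Mb of per-base coverage.
* **Mutation classes** follow a fixed mixture (70% missense, 10% silent,
  10% frameshift/nonsense, 10% non-coding), so rates are stated for
  *functional* mutations and total records are drawn at rate/0.8 — the
  functional filter always has work to do. Gene assignment is uniform over
  equal-length genes (length-proportional in general), with marker-gene
  statuses planted exactly and background draws excluded from status genes.
* **Expression** is a rank-one latent-tissue-factor model plus Gaussian
  noise; HGSOC-like lines share the tumours' factor loadings, other lines
  use an independent loading vector, and every cell line receives a
  constant batch offset (default 3.0) on a fixed half of the genes,
  emulating the platform/dataset split between cohorts.

Deliberately **not** emulated: dosage coupling between copy number and
expression, mutational signatures, subclonality, probe-level noise, and any
realistic gene length/position distribution. Passing tests therefore
demonstrate that the pipeline's statistics recover planted structure under
the stated noise model — they do not certify performance on real cohort
exports, where the score's discriminative power depends on biology the
generator does not model.

All generation flows through an explicit `numpy.random.default_rng(seed)`;
identical (spec, seed) pairs are bit-identical, and every artefact passes
the package's own format validators round-trip.

## Numerical and design notes

* Segment tables are validated on construction: `end > start`, no
  within-chromosome overlap, autosomes only by default (sex chromosomes
  dropped on read; the analysis is defined on chromosomes 1–22).
* Exact-constancy checks (`all values equal`) rather than `std == 0` guard
  undefined correlations: the summed-float standard deviation of a constant
  vector can be ~1e−17.
* Wig parsing supports fixedStep and variableStep with span; writing uses
  one span-block per covered run, keeping genome-scale tracks to a few
  hundred lines.
* The pipeline's stages communicate through TSV files; the manifest records
  the config hash, seed and version, and reruns are byte-identical.
* Desk-scale defaults (100 tumours × 1,000 genes; calibration experiments
  at 200 tumours × 330 genes) are the package's own choice of problem size:
  large enough that binomial/Poisson calibration intervals are tight and
  archetype recovery is measured over 100 seeds, small enough that the full
  suite runs in minutes on one CPU. `scripts/acceptance.py` states the `n`
  it used next to every reported value.

## Known limitations

* The score weights are defaults, not estimates; on real data the induced
  ordering (beyond the good/poor extremes) can change with re-weighting.
* The RB1 deletion threshold (−1.0) and the hypermutator thresholds are
  conventions exposed as config, not fitted quantities.
* Whether the cohort mean profile should exclude flat TP53-wild-type
  outliers is left to the caller (default: include all samples).
* The expression analyses assume complete matrices; missing expression
  values are not imputed.
* `kendall_concordance`'s exact mode enumerates n! permutations and is
  capped at n = 8 by default.
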