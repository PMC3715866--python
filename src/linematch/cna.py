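"""Copy-number concordance: fraction genome altered, gene-level mapping, and
similarity of a cell line's profile to a tumour cohort.

The fraction genome altered (FGA) of a segmented profile is

    FGA = sum_i L(i) * [|CN_i| > T] / sum_i L(i)

where ``CN_i = log2(sample intensity / reference intensity)`` is segment i's
mean log2 copy ratio, ``L(i)`` its length in bp (1-based closed intervals, so
``end - start + 1``), and ``T`` the alteration threshold.  Both gains and
losses count as alterations; the inequality is strict, so a segment sitting
exactly at T is unaltered.

Gene-level values are the segment-length-weighted mean of ``seg_mean`` over
the segments overlapping the gene's interval (an alternative largest-overlap
rule is available); genes covered by no segment are missing for that sample.

Similarity of a cell line to the cohort is summarised three ways, all with
Pearson correlation over pairwise-complete gene pairs: against every single
tumour (of which the median and the maximum are reported), and against the
cohort's mean copy-number profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SegmentedProfile, ValidationError, validate_gene_models

logger = logging.getLogger(__name__)


def fraction_genome_altered(profile: SegmentedProfile, threshold: float) -> float:
    """Length-weighted fraction of the profile with |log2 ratio| above ``threshold``."""
    if len(profile) == 0:
        raise ValidationError(f"sample {profile.sample_id!r}: empty profile")
    if threshold <= 0:
        raise ValueError(f"FGA threshold must be positive, got {threshold}")
    lengths = profile.lengths.astype(float)
    altered = np.abs(profile.segments["seg_mean"].to_numpy()) > threshold
    return float(lengths[altered].sum() / lengths.sum())


def map_segments_to_genes(
    profiles: Iterable[SegmentedProfile],
    gene_models: pd.DataFrame,
    rule: str = "weighted_mean",
) -> pd.DataFrame:
    """Map segmented profiles to a gene-by-sample log2 copy-ratio matrix.

    ``rule="weighted_mean"`` (default) averages overlapping segments' means
    weighted by the overlap length in bp; ``rule="largest_overlap"`` takes the
    single segment with the largest overlap.  Genes overlapping no segment are
    NaN for that sample.
    """
    if rule not in ("weighted_mean", "largest_overlap"):
        raise ValueError(f"unknown gene-mapping rule {rule!r}")
    genes = validate_gene_models(gene_models)
    if genes.empty:
        raise ValidationError("gene model table is empty")
    profiles = list(profiles)
    out = np.full((len(genes), len(profiles)), np.nan)
    by_chrom = {chrom: grp for chrom, grp in genes.groupby("chromosome", sort=False)}

    for j, prof in enumerate(profiles):
        for chrom, seg in prof.segments.groupby("chromosome", sort=False):
            grp = by_chrom.get(chrom)
            if grp is None:
                continue
            seg_start = seg["start"].to_numpy()
            seg_end = seg["end"].to_numpy()
            seg_mean = seg["seg_mean"].to_numpy()
            gs = grp["start"].to_numpy()
            ge = grp["end"].to_numpy()
            rows = grp.index.to_numpy()
            # segments are sorted and non-overlapping, so starts and ends are
            # both monotone: binary search gives the overlapping slice.
            i0 = np.searchsorted(seg_end, gs, side="left")
            i1 = np.searchsorted(seg_start, ge, side="right")
            n_overlap = i1 - i0
            single = n_overlap == 1
            out[rows[single], j] = seg_mean[i0[single]]
            for k in np.flatnonzero(n_overlap > 1):
                lo, hi = i0[k], i1[k]
                ov = (
                    np.minimum(ge[k], seg_end[lo:hi])
                    - np.maximum(gs[k], seg_start[lo:hi])
                    + 1
                ).astype(float)
                if rule == "weighted_mean":
                    out[rows[k], j] = float(np.average(seg_mean[lo:hi], weights=ov))
                else:
                    out[rows[k], j] = float(seg_mean[lo:hi][np.argmax(ov)])

    return pd.DataFrame(out, index=genes["gene"].to_numpy(), columns=[p.sample_id for p in profiles])


def mean_cna_profile(matrix: pd.DataFrame, cohort: Sequence[str]) -> pd.Series:
    """Per-gene arithmetic mean over the cohort samples with a present value.

    Genes missing in every cohort sample are absent from the result.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("empty cohort")
    missing = [s for s in cohort if s not in matrix.columns]
    if missing:
        raise ValidationError(f"cohort samples absent from matrix: {missing[:5]}")
    mean = matrix[cohort].mean(axis=1, skipna=True)
    return mean.dropna()


@dataclass
class CnaSimilarity:
    """Three copy-number similarity summaries of one cell line vs a cohort."""

    cell_line: str
    corr_with_mean_profile: float
    per_tumour_correlations: pd.Series
    median_correlation: float
    max_single_tumour_correlation: float


def _pearson_pairwise_complete(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over indices where both values are finite; NaN if undefined."""
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return np.nan
    xv, yv = x[mask], y[mask]
    # exact constancy check: summed-float std of a constant vector can be ~1e-17
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def cna_similarity(
    cell_line_profile: pd.Series,
    tumour_matrix: pd.DataFrame,
    mean_profile: pd.Series,
    cell_line: str | None = None,
    min_shared_genes: int = 3,
) -> CnaSimilarity:
    """Correlate one cell line's gene-level profile with a tumour cohort.

    Each correlation uses pairwise-complete gene pairs (missing genes are
    dropped per comparison, not globally).  Undefined correlations — fewer
    than three complete pairs, or zero variance in either vector — propagate
    as missing and are excluded from the median, with a warning; they are
    never silently zero.
    """
    name = cell_line or (cell_line_profile.name if cell_line_profile.name else "cell_line")

    shared = cell_line_profile.index.intersection(mean_profile.index)
    x = cell_line_profile.reindex(shared).to_numpy(dtype=float)
    m = mean_profile.reindex(shared).to_numpy(dtype=float)
    if (np.isfinite(x) & np.isfinite(m)).sum() < min_shared_genes:
        raise ValidationError(
            f"cell line {name!r}: fewer than {min_shared_genes} complete shared genes"
        )
    corr_mean = _pearson_pairwise_complete(x, m)
    if np.isnan(corr_mean):
        warnings.warn(f"cell line {name!r}: undefined correlation with mean profile")

    shared_t = cell_line_profile.index.intersection(tumour_matrix.index)
    xv = cell_line_profile.reindex(shared_t).to_numpy(dtype=float)
    tm = tumour_matrix.reindex(shared_t)
    per_tumour = {}
    for tumour in tm.columns:
        r = _pearson_pairwise_complete(xv, tm[tumour].to_numpy(dtype=float))
        per_tumour[tumour] = r
    per_tumour = pd.Series(per_tumour, dtype=float)
    n_undef = int(per_tumour.isna().sum())
    if n_undef:
        warnings.warn(
            f"cell line {name!r}: {n_undef} undefined per-tumour correlation(s) excluded"
        )
    defined = per_tumour.dropna()
    if defined.empty:
        raise ValidationError(f"cell line {name!r}: no defined per-tumour correlation")
    return CnaSimilarity(
        cell_line=str(name),
        corr_with_mean_profile=corr_mean,
        per_tumour_correlations=per_tumour,
        median_correlation=float(defined.median()),
        max_single_tumour_correlation=float(defined.max()),
    )


def call_high_level_amplification(value: float, threshold: float = 1.0) -> bool:
    """True iff the gene-level log2 ratio strictly exceeds ``threshold``.

    The default cut of 1.0 applies to cell-line profiles; the inequality is
    strict, so a value exactly at the threshold is not called amplified.
    """
    if not np.isfinite(value):
        raise ValidationError(f"non-finite copy-number value: {value}")
    return bool(value > threshold)
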