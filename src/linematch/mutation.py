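"""Mutation metrics: functional filtering, coverage-corrected burden and
marker-gene status.

Mutation frequency is the ratio of likely-functional mutation counts to the
number of bases covered by sequencing, reported per megabase.  Likely
functional means every class except intron, UTR, flanking, intergenic,
silent and RNA; splice-site and in-frame indel classes are retained.  The
covered-bases denominator comes in two dialects: per-base (positions with
one or more reads) and per-exon (sum of exon length times coverage
fraction, accumulated in real arithmetic and rounded once at the end).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna import call_high_level_amplification
from .config import Panels
from .io import CoverageTrack, MutationCatalog, ValidationError

logger = logging.getLogger(__name__)

#: Classes excluded by the likely-functional filter.
EXCLUDED_CLASSES = frozenset({"intron", "utr5", "utr3", "flank", "igr", "silent", "rna"})


def filter_functional(catalog: MutationCatalog) -> MutationCatalog:
    """Drop records in non-functional classes; idempotent."""
    keep = ~catalog.records["classification"].isin(EXCLUDED_CLASSES)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_functional: removed %d non-functional record(s)", removed)
    return MutationCatalog(
        records=catalog.records[keep].reset_index(drop=True),
        samples=catalog.samples,
        functional_only=True,
    )


@dataclass
class MutationBurden:
    """Coverage-corrected functional mutation burden of one sample."""

    sample_id: str
    functional_mutation_count: int
    bases_covered: int
    frequency_per_mb: float


def bases_covered(track: CoverageTrack) -> int:
    """Number of callable bases in a coverage track.

    Per-base dialect: count of positions with read count >= 1.  Per-exon
    dialect: sum over exons of length x coverage fraction, summed as a real
    and rounded once to the nearest base.
    """
    if track.dialect == "per_base":
        assert track.per_base is not None
        total = sum(
            int((runs[:, 1] - runs[:, 0] + 1).sum()) for runs in track.per_base.values()
        )
        if total == 0:
            raise ValidationError(f"sample {track.sample_id!r}: empty coverage track")
        return total
    assert track.per_exon is not None
    if track.per_exon.empty:
        raise ValidationError(f"sample {track.sample_id!r}: empty coverage track")
    effective = float(
        (track.per_exon["exon_length"] * track.per_exon["coverage_fraction"]).sum()
    )
    return int(round(effective))


def mutation_frequency(
    catalog: MutationCatalog,
    track: CoverageTrack,
    allow_unfiltered: bool = False,
) -> MutationBurden:
    """Functional mutation frequency per Mb of covered sequence for one sample.

    ``catalog`` must already be functional-filtered (records in excluded
    classes make the call fail unless ``allow_unfiltered`` acknowledges it,
    in which case the filter is applied here).  Each record counts once;
    multiple mutations in the same gene are not collapsed.
    """
    if track.sample_id not in catalog.samples:
        raise ValidationError(
            f"sample mismatch: coverage for {track.sample_id!r} but catalog covers "
            f"{sorted(catalog.samples)[:5]}..."
        )
    has_excluded = catalog.records["classification"].isin(EXCLUDED_CLASSES).any()
    if has_excluded:
        if not allow_unfiltered:
            raise ValidationError(
                "catalog contains non-functional records; run filter_functional "
                "first or pass allow_unfiltered=True"
            )
        catalog = filter_functional(catalog)
    covered = bases_covered(track)
    count = int(len(catalog.for_sample(track.sample_id)))
    return MutationBurden(
        sample_id=track.sample_id,
        functional_mutation_count=count,
        bases_covered=covered,
        frequency_per_mb=count / covered * 1e6,
    )


@dataclass
class MarkerStatus:
    """Per-gene marker flags for one sample.

    ``mutation`` covers the HGSOC mutation panel, ``amplification`` the
    high-level amplification panel, ``mut_or_del`` genes flagged when mutated
    or deleted, and ``non_hgsoc`` the seven-gene panel counted by score
    component D.  A flag is ``None`` when the gene could not be assessed.
    """

    sample_id: str
    mutation: dict[str, bool | None]
    amplification: dict[str, bool | None]
    mut_or_del: dict[str, bool | None]
    non_hgsoc: dict[str, bool | None]

    def flags(self) -> dict[str, object]:
        out: dict[str, object] = {}
        for gene, v in self.mutation.items():
            out[f"mut_{gene}"] = v
        for gene, v in self.amplification.items():
            out[f"amp_{gene}"] = v
        for gene, v in self.mut_or_del.items():
            out[f"mutdel_{gene}"] = v
        for gene, v in self.non_hgsoc.items():
            out[f"nonhgsoc_{gene}"] = v
        return out


def marker_status(
    sample_id: str,
    catalog: MutationCatalog,
    gene_cna: pd.Series | None = None,
    panels: Panels | None = None,
    amp_threshold: float = 1.0,
    deletion_threshold: float = -1.0,
    gene_universe: set[str] | None = None,
) -> MarkerStatus:
    """Derive marker-panel flags for one sample.

    A mutation flag is true iff the sample has at least one functional
    mutation in the gene; amplification flags call a gene-level log2 ratio
    strictly above ``amp_threshold``; mut-or-del genes are additionally
    flagged when their gene-level value falls below ``deletion_threshold``.
    A panel gene absent from both the assayed gene universe and the CNA
    vector yields a warning and a missing flag, never a silent False.
    """
    panels = panels or Panels()
    functional = filter_functional(catalog) if not catalog.functional_only else catalog
    sample_rec = functional.for_sample(sample_id)
    mutated_genes = set(sample_rec["gene"].unique())

    universe = gene_universe if gene_universe is not None else catalog.genes()
    cna_genes = set(gene_cna.index) if gene_cna is not None else set()

    def assessable(gene: str) -> bool:
        return gene in universe or gene in cna_genes

    def mut_flag(gene: str) -> bool | None:
        if not assessable(gene):
            warnings.warn(f"sample {sample_id!r}: marker gene {gene!r} not assayed")
            return None
        return gene in mutated_genes

    def amp_flag(gene: str) -> bool | None:
        if gene_cna is None or gene not in cna_genes or not np.isfinite(gene_cna[gene]):
            warnings.warn(f"sample {sample_id!r}: no copy-number value for {gene!r}")
            return None
        return call_high_level_amplification(float(gene_cna[gene]), amp_threshold)

    def mutdel_flag(gene: str) -> bool | None:
        mut = mut_flag(gene)
        deleted = None
        if gene_cna is not None and gene in cna_genes and np.isfinite(gene_cna[gene]):
            deleted = bool(gene_cna[gene] < deletion_threshold)
        if mut is None and deleted is None:
            return None
        return bool(mut) or bool(deleted)

    return MarkerStatus(
        sample_id=sample_id,
        mutation={g: mut_flag(g) for g in panels.hgsoc_mutation},
        amplification={g: amp_flag(g) for g in panels.hgsoc_amplification},
        mut_or_del={g: mutdel_flag(g) for g in panels.hgsoc_mut_or_del},
        non_hgsoc={g: mut_flag(g) for g in panels.non_hgsoc},
    )
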