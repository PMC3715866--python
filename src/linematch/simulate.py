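"""Seeded synthetic tumour cohorts and cell-line panels with ground truth.

The generator emulates the statistical structure the analysis assumes for a
high-grade serous ovarian cancer (HGSOC) comparison:

* tumours with extensive copy-number alteration driven by recurrent gains
  and losses, near-universal TP53 mutation (default probability 0.95 among
  the non-flat subpopulation), and a small flat-profile TP53-wild-type
  subpopulation;
* a cell-line panel mixing three archetypes — HGSOC-like lines whose
  gene-level copy-number profile is the tumour cohort's mean profile plus
  noise (TP53 mutated, non-HGSOC panel clean), non-HGSOC lines (flat
  profile, TP53 wild type, 1-3 planted mutations in the seven-gene
  non-HGSOC panel), and hypermutators (flat profile, high mutation rate);
* mutation rates stated per Mb of *functional* mutations (the filter's
  output); total records are drawn at rate/functional_fraction with a fixed
  class mixture (70% missense, 10% silent, 10% frameshift/nonsense, 10%
  non-coding) so the functional filter has work to do;
* expression as a rank-one latent-tissue-factor model plus noise, with a
  constant batch offset added to a shared gene subset of every cell line,
  emulating the platform/dataset separation seen between cohorts.

All randomness flows through an explicit integer seed; identical
(spec, seed) pairs give bit-identical outputs.  Every generated artefact
passes the :mod:`linematch.io` validators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .config import NON_HGSOC_GENES
from .io import (
    CoverageTrack,
    ExpressionMatrix,
    MutationCatalog,
    SegmentedProfile,
    ValidationError,
)

#: Marker genes given their field names in the synthetic genome.
MARKER_GENE_NAMES = (
    "TP53",
    "BRCA1",
    "BRCA2",
    "RB1",
    "C11orf30",
    "CCNE1",
    "KRAS",
    "MYC",
    "ARID1A",
    "BRAF",
    "CTNNB1",
    "ERBB2",
    "PIK3CA",
    "PTEN",
)

#: Variant-class mixture for generated records.  Functional classes carry
#: 0.8 of the mass, so a functional rate lambda corresponds to a total
#: record rate lambda / 0.8.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "missense": 0.70,
    "nonsense": 0.05,
    "frameshift": 0.05,
    "silent": 0.10,
    "intron": 0.04,
    "utr3": 0.02,
    "utr5": 0.02,
    "flank": 0.01,
    "igr": 0.005,
    "rna": 0.005,
}

GENE_LENGTH = 20_000
GENE_SPACING = 100_000

from .mutation import EXCLUDED_CLASSES


def _functional_fraction(mixture: dict[str, float]) -> float:
    return 1.0 - sum(p for c, p in mixture.items() if c in EXCLUDED_CLASSES)


@dataclass(frozen=True)
class RecurrentEvent:
    """A recurrent copy-number event over a contiguous gene-index range.

    ``gene_start``/``gene_end`` are half-open global gene indices; the range
    must lie within one chromosome.  ``amplitude`` is the unsigned log2
    magnitude, signed by ``kind``.
    """

    gene_start: int
    gene_end: int
    kind: str  # "gain" | "loss"
    amplitude: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise ValidationError(f"event kind must be gain/loss, got {self.kind!r}")
        if not 0 <= self.prevalence <= 1:
            raise ValidationError("event prevalence must be in [0, 1]")
        if self.gene_end <= self.gene_start:
            raise ValidationError("event gene range is empty")
        if not np.isfinite(self.amplitude):
            raise ValidationError("event amplitude must be finite")

    @property
    def signed_amplitude(self) -> float:
        return self.amplitude if self.kind == "gain" else -self.amplitude


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic tumour cohort."""

    n_tumours: int = 100
    n_genes: int = 1000
    n_chromosomes: int = 22
    recurrent_events: tuple[RecurrentEvent, ...] | None = None  # None -> defaults
    noise_sd: float = 0.1
    tp53_mut_prob: float = 0.95
    flat_tp53wt_fraction: float = 0.05
    background_mut_rate: float = 1.6  # functional mutations per Mb
    covered_mb: float = 30.0
    n_exons: int = 300
    class_mixture: tuple[tuple[str, float], ...] = tuple(DEFAULT_CLASS_MIXTURE.items())
    expression_factor_mean: float = 2.0
    expression_factor_sd: float = 0.2
    expression_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tumours <= 0 or self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ValidationError("counts must be positive")
        for p in (self.tp53_mut_prob, self.flat_tp53wt_fraction):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.background_mut_rate < 0 or self.covered_mb <= 0:
            raise ValidationError("mutation rate must be >= 0 and covered_mb > 0")
        if self.n_genes < 10 * self.n_chromosomes:
            raise ValidationError("need at least 10 genes per chromosome")

    def mixture(self) -> dict[str, float]:
        return dict(self.class_mixture)


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for a synthetic cell-line panel (archetype mixture)."""

    n_hgsoc_like: int = 30
    n_non_hgsoc: int = 12
    n_hypermutator: int = 5
    lambda_background: float = 4.0  # functional mutations per Mb
    lambda_high: float = 15.0
    expression_batch_offset: float = 3.0
    covered_mb: float = 30.0
    cna_noise_sd: float = 0.1
    flat_noise_sd: float = 0.05
    panel_mut_min: int = 1
    panel_mut_max: int = 3
    offset_gene_fraction: float = 0.5
    n_runs: int = 200
    class_mixture: tuple[tuple[str, float], ...] = tuple(DEFAULT_CLASS_MIXTURE.items())
    expression_factor_mean: float = 2.0
    expression_factor_sd: float = 0.2
    expression_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_hgsoc_like, self.n_non_hgsoc, self.n_hypermutator) < 0:
            raise ValidationError("archetype counts must be >= 0")
        if self.n_hgsoc_like + self.n_non_hgsoc + self.n_hypermutator == 0:
            raise ValidationError("panel is empty")
        if self.lambda_high <= self.lambda_background:
            raise ValidationError("lambda_high must exceed lambda_background")
        if not 1 <= self.panel_mut_min <= self.panel_mut_max <= len(NON_HGSOC_GENES):
            raise ValidationError("panel mutation count range invalid")

    @property
    def size(self) -> int:
        return self.n_hgsoc_like + self.n_non_hgsoc + self.n_hypermutator

    def mixture(self) -> dict[str, float]:
        return dict(self.class_mixture)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def make_gene_models(n_genes: int, n_chromosomes: int = 22) -> pd.DataFrame:
    """Lay out ``n_genes`` equal-length genes over autosome-like chromosomes.

    Genes fill chromosomes in contiguous blocks; marker genes (TP53, the
    non-HGSOC panel, the amplification panel, ...) are placed at fixed
    positions in the final chromosomes, away from the default recurrent
    event regions.
    """
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    idx = np.arange(n_genes)
    chrom_idx = idx // per_chrom
    pos_idx = idx % per_chrom
    start = 1 + pos_idx * GENE_SPACING
    end = start + GENE_LENGTH - 1
    names = np.array([f"G{i:05d}" for i in idx], dtype=object)
    # markers spread over the tail of the gene list
    n_mark = len(MARKER_GENE_NAMES)
    tail = min(2 * per_chrom, n_genes)
    stride = max(1, tail // (n_mark + 1))
    for k, marker in enumerate(MARKER_GENE_NAMES):
        names[n_genes - 1 - k * stride] = marker
    return pd.DataFrame(
        {
            "gene": names,
            "chromosome": [str(c + 1) for c in chrom_idx],
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
        }
    )


def default_recurrent_events(n_genes: int, n_chromosomes: int = 22) -> tuple[RecurrentEvent, ...]:
    """Recurrent events (alternating gains/losses) on the first sixteen
    chromosomes, each covering the middle two thirds of its chromosome.

    Sized so a cohort's median fraction genome altered lands near the ~46%
    characteristic of heavily copy-number-driven tumours; the last two
    chromosomes stay event-free (marker genes live there).
    """
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    events = []
    for c in range(min(16, n_chromosomes - 2)):
        lo = c * per_chrom + per_chrom // 6
        hi = c * per_chrom + (5 * per_chrom) // 6
        events.append(
            RecurrentEvent(
                gene_start=lo,
                gene_end=hi,
                kind="gain" if c % 2 == 0 else "loss",
                amplitude=0.9,
                prevalence=0.9,
            )
        )
    return tuple(events)


def _chromosome_lengths(gene_models: pd.DataFrame) -> dict[str, int]:
    return {
        str(chrom): int(grp["end"].max() + GENE_SPACING)
        for chrom, grp in gene_models.groupby("chromosome", sort=False)
    }


def _event_intervals(
    events: tuple[RecurrentEvent, ...], gene_models: pd.DataFrame
) -> list[tuple[str, int, int]]:
    """Genomic (chromosome, start, end) footprint of each event."""
    out = []
    for ev in events:
        rows = gene_models.iloc[ev.gene_start : ev.gene_end]
        chroms = rows["chromosome"].unique()
        if len(chroms) != 1:
            raise ValidationError("an event's gene range must lie within one chromosome")
        out.append((str(chroms[0]), int(rows["start"].min()), int(rows["end"].max())))
    return out


def _segments_for_sample(
    rng: np.random.Generator,
    gene_models: pd.DataFrame,
    chrom_lengths: dict[str, int],
    active: list[tuple[tuple[str, int, int], float]],
    noise_sd: float,
) -> pd.DataFrame:
    """Realise one sample's segments: baselines split by active events."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for (chrom, s, e), amp in active:
        by_chrom.setdefault(chrom, []).append((s, e, amp))
    rows = []
    for chrom in sorted(chrom_lengths, key=lambda c: int(c)):
        length = chrom_lengths[chrom]
        cursor = 1
        for s, e, amp in sorted(by_chrom.get(chrom, [])):
            if s > cursor:
                rows.append((chrom, cursor, s - 1, rng.normal(0.0, noise_sd)))
            rows.append((chrom, s, e, amp + rng.normal(0.0, noise_sd)))
            cursor = e + 1
        if cursor < length:
            rows.append((chrom, cursor, length, rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=lio.SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# mutation record machinery
# ---------------------------------------------------------------------------


def _draw_mutations(
    rng: np.random.Generator,
    sample_ids: list[str],
    counts: np.ndarray,
    allowed_gene_idx: np.ndarray,
    gene_names: np.ndarray,
    mixture: dict[str, float],
) -> pd.DataFrame:
    """Draw mutation records: genes uniform over allowed genes, classes from
    the mixture.  (Genes are equal-length, so length-proportional assignment
    is uniform.)"""
    total = int(counts.sum())
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    gene_pick = allowed_gene_idx[rng.integers(0, len(allowed_gene_idx), total)]
    class_pick = rng.choice(classes, size=total, p=probs)
    sample_col = np.repeat(np.asarray(sample_ids, dtype=object), counts)
    return pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene": gene_names[gene_pick],
            "classification": class_pick,
            "protein_change": "",
        }
    )


def _plant_tp53(
    rng: np.random.Generator,
    records: pd.DataFrame,
    sample_ids: list[str],
    tp53_mutated: np.ndarray,
) -> pd.DataFrame:
    """Guarantee exactly the planted TP53 status.

    Mutated samples get at least one functional TP53 record by converting
    their first functional record's gene (count-preserving) or, if they have
    none, appending a missense record.  Wild-type samples have any TP53 hit
    reassigned to a non-TP53 background gene.
    """
    records = records.copy()
    functional = ~records["classification"].isin(EXCLUDED_CLASSES)
    status = dict(zip(sample_ids, tp53_mutated))

    # wild-type samples: move TP53 hits elsewhere
    wt_hits = records.index[
        (records["gene"] == "TP53")
        & records["sample_id"].map(lambda s: not status[s])
    ]
    if len(wt_hits):
        records.loc[wt_hits, "gene"] = "G00000"

    has_tp53 = set(
        records.loc[functional & (records["gene"] == "TP53"), "sample_id"].unique()
    )
    to_add = []
    for sample, mutated in status.items():
        if not mutated or sample in has_tp53:
            continue
        own = records.index[(records["sample_id"] == sample) & functional]
        if len(own):
            records.loc[own[0], "gene"] = "TP53"
        else:
            to_add.append((sample, "TP53", "missense", ""))
    if to_add:
        records = pd.concat(
            [records, pd.DataFrame(to_add, columns=records.columns)], ignore_index=True
        )
    return records.reset_index(drop=True)


# ---------------------------------------------------------------------------
# coverage machinery
# ---------------------------------------------------------------------------


def _per_exon_track(
    rng: np.random.Generator, sample_id: str, covered_mb: float, n_exons: int
) -> CoverageTrack:
    """Exon lengths and fractions whose effective sum is ``covered_mb`` Mb."""
    target = covered_mb * 1e6
    props = rng.dirichlet(np.full(n_exons, 5.0))
    fracs = rng.uniform(0.7, 1.0, n_exons)
    lengths = np.maximum(1, np.round(target * props / fracs)).astype(np.int64)
    effective = float((lengths * fracs).sum())
    adjust = int(round((target - effective) / fracs[0]))
    lengths[0] = max(1, lengths[0] + adjust)
    return CoverageTrack(
        sample_id=sample_id,
        dialect="per_exon",
        per_exon=pd.DataFrame({"exon_length": lengths, "coverage_fraction": fracs}),
    )


def _per_base_track(
    rng: np.random.Generator,
    sample_id: str,
    covered_mb: float,
    n_runs: int,
    n_chromosomes: int,
) -> CoverageTrack:
    """Covered runs totalling exactly ``covered_mb`` Mb of positions."""
    target = int(round(covered_mb * 1e6))
    props = rng.dirichlet(np.full(n_runs, 5.0))
    lengths = np.maximum(1, np.floor(target * props)).astype(np.int64)
    lengths[0] += target - int(lengths.sum())
    runs: dict[str, list[list[int]]] = {}
    cursors = {str(c + 1): 1 for c in range(n_chromosomes)}
    for r, length in enumerate(lengths):
        chrom = str(r % n_chromosomes + 1)
        start = cursors[chrom]
        runs.setdefault(chrom, []).append([start, start + int(length) - 1])
        cursors[chrom] = start + int(length) + 1000
    return CoverageTrack(
        sample_id=sample_id,
        dialect="per_base",
        per_base={c: np.asarray(v, dtype=np.int64) for c, v in runs.items()},
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class TumourCohort:
    spec: CohortSpec
    seed: int
    gene_models: pd.DataFrame
    profiles: list[SegmentedProfile]
    mutations: MutationCatalog
    coverage: list[CoverageTrack]
    expression: ExpressionMatrix
    truth: pd.DataFrame
    expression_loadings: pd.Series


def generate_tumour_cohort(spec: CohortSpec, seed: int) -> TumourCohort:
    """Realise a tumour cohort from a :class:`CohortSpec` and a seed."""
    rng = np.random.default_rng(seed)
    gene_models = make_gene_models(spec.n_genes, spec.n_chromosomes)
    gene_names = gene_models["gene"].to_numpy()
    events = (
        spec.recurrent_events
        if spec.recurrent_events is not None
        else default_recurrent_events(spec.n_genes, spec.n_chromosomes)
    )
    intervals = _event_intervals(tuple(events), gene_models)
    chrom_lengths = _chromosome_lengths(gene_models)

    n = spec.n_tumours
    sample_ids = [f"TUM{i:04d}" for i in range(n)]
    flat = rng.random(n) < spec.flat_tp53wt_fraction
    tp53 = np.where(flat, False, rng.random(n) < spec.tp53_mut_prob)
    draws = rng.random((n, len(events))) < np.array([e.prevalence for e in events])
    draws[flat] = False

    profiles = []
    for i, sid in enumerate(sample_ids):
        active = [
            (intervals[k], events[k].signed_amplitude)
            for k in range(len(events))
            if draws[i, k]
        ]
        seg = _segments_for_sample(rng, gene_models, chrom_lengths, active, spec.noise_sd)
        profiles.append(SegmentedProfile(sample_id=sid, segments=seg))

    mixture = spec.mixture()
    f_frac = _functional_fraction(mixture)
    lam_total = spec.background_mut_rate * spec.covered_mb / f_frac
    counts = rng.poisson(lam_total, n)
    allowed = np.arange(spec.n_genes)
    records = _draw_mutations(rng, sample_ids, counts, allowed, gene_names, mixture)
    records = _plant_tp53(rng, records, sample_ids, tp53)
    catalog = MutationCatalog(records=records, samples=tuple(sample_ids))

    coverage = [
        _per_exon_track(rng, sid, spec.covered_mb, spec.n_exons) for sid in sample_ids
    ]

    u = rng.normal(0.0, 1.0, spec.n_genes)
    f = rng.normal(spec.expression_factor_mean, spec.expression_factor_sd, n)
    expr = u[:, None] * f[None, :] + rng.normal(
        0.0, spec.expression_noise_sd, (spec.n_genes, n)
    )
    expression = ExpressionMatrix.from_frame(
        pd.DataFrame(expr, index=gene_names, columns=sample_ids), "tumours"
    )

    functional = ~records["classification"].isin(EXCLUDED_CLASSES)
    func_counts = (
        records[functional].groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "flat_wt": flat,
            "tp53_mutated": tp53,
            "functional_count": func_counts.to_numpy(),
        }
    )
    for k in range(len(events)):
        truth[f"event_{k}"] = draws[:, k]

    return TumourCohort(
        spec=spec,
        seed=seed,
        gene_models=gene_models,
        profiles=profiles,
        mutations=catalog,
        coverage=coverage,
        expression=expression,
        truth=truth,
        expression_loadings=pd.Series(u, index=gene_names),
    )


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------


@dataclass
class CellLinePanel:
    spec: PanelSpec
    seed: int
    gene_models: pd.DataFrame
    profiles: list[SegmentedProfile]
    mutations: MutationCatalog
    coverage: list[CoverageTrack]
    expression: ExpressionMatrix
    truth: pd.DataFrame


def generate_cell_line_panel(
    spec: PanelSpec,
    tumour_mean_profile: pd.Series,
    gene_models: pd.DataFrame,
    seed: int,
    tumour_expression_loadings: pd.Series | None = None,
) -> CellLinePanel:
    """Realise a cell-line panel of the three archetypes.

    ``tumour_mean_profile`` is the cohort's gene-level mean copy-number
    vector (HGSOC-like lines are built from it); ``gene_models`` fixes the
    genomic coordinates.  When the tumour cohort's expression loadings are
    supplied, HGSOC-like lines share the tumours' latent tissue factor, so
    expression correlation mirrors archetype.
    """
    rng = np.random.default_rng(seed)
    n = spec.size
    archetypes = (
        ["hgsoc_like"] * spec.n_hgsoc_like
        + ["non_hgsoc"] * spec.n_non_hgsoc
        + ["hypermutator"] * spec.n_hypermutator
    )
    sample_ids = [f"LINE{i:02d}" for i in range(n)]
    gene_names = gene_models["gene"].to_numpy()
    n_genes = len(gene_names)
    chrom_lengths = _chromosome_lengths(gene_models)
    mean_vec = tumour_mean_profile.reindex(gene_names).fillna(0.0).to_numpy()

    profiles = []
    for i, sid in enumerate(sample_ids):
        if archetypes[i] == "hgsoc_like":
            seg = pd.DataFrame(
                {
                    "chromosome": gene_models["chromosome"],
                    "start": gene_models["start"],
                    "end": gene_models["end"],
                    "seg_mean": mean_vec + rng.normal(0.0, spec.cna_noise_sd, n_genes),
                }
            )
        else:
            chroms = sorted(chrom_lengths, key=lambda c: int(c))
            seg = pd.DataFrame(
                {
                    "chromosome": chroms,
                    "start": 1,
                    "end": [chrom_lengths[c] for c in chroms],
                    "seg_mean": rng.normal(0.0, spec.flat_noise_sd, len(chroms)),
                }
            )
        profiles.append(SegmentedProfile(sample_id=sid, segments=seg))

    # mutations: background excludes all planted-status genes
    mixture = spec.mixture()
    f_frac = _functional_fraction(mixture)
    lam = np.where(
        np.asarray(archetypes) == "hypermutator", spec.lambda_high, spec.lambda_background
    )
    counts = rng.poisson(lam * spec.covered_mb / f_frac)
    special = set(NON_HGSOC_GENES) | {"TP53"}
    allowed = np.flatnonzero(~np.isin(gene_names, list(special)))
    records = _draw_mutations(rng, sample_ids, counts, allowed, gene_names, mixture)

    planted_panel: list[str] = []
    extra = []
    for i, sid in enumerate(sample_ids):
        if archetypes[i] == "hgsoc_like":
            extra.append((sid, "TP53", "missense", ""))
            planted_panel.append("")
        elif archetypes[i] == "non_hgsoc":
            k = int(rng.integers(spec.panel_mut_min, spec.panel_mut_max + 1))
            genes = rng.choice(np.asarray(NON_HGSOC_GENES, dtype=object), k, replace=False)
            extra.extend((sid, g, "missense", "") for g in genes)
            planted_panel.append(",".join(sorted(genes)))
        else:
            planted_panel.append("")
    if extra:
        records = pd.concat(
            [records, pd.DataFrame(extra, columns=records.columns)], ignore_index=True
        )
    catalog = MutationCatalog(records=records, samples=tuple(sample_ids))

    coverage = [
        _per_base_track(rng, sid, spec.covered_mb, spec.n_runs, len(chrom_lengths))
        for sid in sample_ids
    ]

    if tumour_expression_loadings is not None:
        u = tumour_expression_loadings.reindex(gene_names).fillna(0.0).to_numpy()
    else:
        u = rng.normal(0.0, 1.0, n_genes)
    w = rng.normal(0.0, 1.0, n_genes)
    f = rng.normal(spec.expression_factor_mean, spec.expression_factor_sd, n)
    is_hgsoc = np.asarray(archetypes) == "hgsoc_like"
    loadings = np.where(is_hgsoc[None, :], u[:, None], w[:, None])
    expr = loadings * f[None, :] + rng.normal(
        0.0, spec.expression_noise_sd, (n_genes, n)
    )
    n_offset = int(np.floor(n_genes * spec.offset_gene_fraction))
    expr[:n_offset, :] += spec.expression_batch_offset
    expression = ExpressionMatrix.from_frame(
        pd.DataFrame(expr, index=gene_names, columns=sample_ids), "cell_lines"
    )

    functional = ~records["classification"].isin(EXCLUDED_CLASSES)
    func_counts = (
        records[functional].groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "archetype": archetypes,
            "tp53_mutated": is_hgsoc,
            "planted_panel_genes": planted_panel,
            "functional_count": func_counts.to_numpy(),
        }
    )

    return CellLinePanel(
        spec=spec,
        seed=seed,
        gene_models=gene_models,
        profiles=profiles,
        mutations=catalog,
        coverage=coverage,
        expression=expression,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialisation of a full synthetic study
# ---------------------------------------------------------------------------


def write_cohort_inputs(cohort: TumourCohort, out_dir: str | Path) -> dict[str, str]:
    """Write all tumour-side inputs in their standard dialects; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_dir = out / "tumour_coverage"
    cov_dir.mkdir(exist_ok=True)
    paths = {
        "tumour_seg": str(out / "tumour_segments.seg"),
        "tumour_mutations": str(out / "tumour_mutations.maf.tsv"),
        "tumour_coverage_dir": str(cov_dir),
        "tumour_expression": str(out / "tumour_expression.tsv"),
        "gene_models": str(out / "gene_models.tsv"),
    }
    lio.write_seg(cohort.profiles, paths["tumour_seg"])
    lio.write_mutations(cohort.mutations, paths["tumour_mutations"])
    for track in cohort.coverage:
        lio.write_coverage(track, cov_dir / f"{track.sample_id}.tsv")
    lio.write_expression(cohort.expression, paths["tumour_expression"])
    lio.write_gene_models(cohort.gene_models, paths["gene_models"])
    cohort.truth.to_csv(out / "tumour_truth.tsv", sep="\t", index=False)
    return paths


def write_panel_inputs(panel: CellLinePanel, out_dir: str | Path) -> dict[str, str]:
    """Write all cell-line-side inputs; per-base coverage goes out as wig."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov_dir = out / "cell_coverage"
    cov_dir.mkdir(exist_ok=True)
    paths = {
        "cell_seg": str(out / "cell_segments.seg"),
        "cell_mutations": str(out / "cell_mutations.maf.tsv"),
        "cell_coverage_dir": str(cov_dir),
        "cell_expression": str(out / "cell_expression.tsv"),
    }
    lio.write_seg(panel.profiles, paths["cell_seg"])
    lio.write_mutations(panel.mutations, paths["cell_mutations"])
    for track in panel.coverage:
        lio.write_coverage(track, cov_dir / f"{track.sample_id}.wig")
    lio.write_expression(panel.expression, paths["cell_expression"])
    panel.truth.to_csv(out / "cell_truth.tsv", sep="\t", index=False)
    return paths
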