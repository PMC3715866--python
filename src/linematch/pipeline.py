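"""End-to-end orchestration: read inputs, run every analysis stage, and write
the result tables plus a run manifest.

Stages communicate through TSV files in the run's output directory so each
subcommand is independently testable; the manifest records the configuration
hash, seed and package version, and identical configuration plus inputs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .cna import cna_similarity, fraction_genome_altered, map_segments_to_genes, mean_cna_profile
from .config import RunConfig
from .expression import expression_rank, kendall_concordance
from .io import ValidationError
from .mutation import filter_functional, marker_status, mutation_frequency
from .suitability import assemble_components, classify_hypermutated, rank_and_tier

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Paths of the artefacts a full run produced."""

    out_dir: Path
    ranking_table: Path
    components_table: Path
    burden_table: Path
    similarity_table: Path
    expression_ranking: Path
    concordance_report: Path
    scatter_tsv: Path
    manifest: Path


def _read_coverage_dir(directory: str | Path, dialect: str) -> dict[str, lio.CoverageTrack]:
    tracks = {}
    for path in sorted(Path(directory).iterdir()):
        if path.suffix not in (".tsv", ".wig"):
            continue
        track = lio.read_coverage(path, dialect=dialect)
        tracks[track.sample_id] = track
    if not tracks:
        raise ValidationError(f"no coverage files found in {directory}")
    return tracks


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute read -> map -> FGA/burden -> similarity -> score -> rank, then
    the expression ranking and the rank-concordance test between the two
    orderings.  Any stage error aborts with the stage name and sample
    context."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        tumour_profiles = lio.read_seg(config.tumour_seg)
        cell_profiles = lio.read_seg(config.cell_seg)
        gene_models = lio.read_gene_models(config.gene_models)
        tumour_catalog = lio.read_mutations(config.tumour_mutations)
        cell_catalog = lio.read_mutations(config.cell_mutations)
        tumour_cov = _read_coverage_dir(config.tumour_coverage_dir, "per_exon")
        cell_cov = _read_coverage_dir(config.cell_coverage_dir, "per_base")
        tumour_expr = lio.read_expression(config.tumour_expression, "tumours")
        cell_expr = lio.read_expression(config.cell_expression, "cell_lines")

        current = stage("gene-level copy-number mapping")
        tumour_cna = map_segments_to_genes(tumour_profiles, gene_models)
        cell_cna = map_segments_to_genes(cell_profiles, gene_models)
        mean_profile = mean_cna_profile(tumour_cna, list(tumour_cna.columns))
        logger.info(
            "mapped %d genes x %d tumours, %d cell lines",
            len(gene_models), tumour_cna.shape[1], cell_cna.shape[1],
        )

        current = stage("FGA and mutation burden")
        thr = config.thresholds
        tumour_fga = {
            p.sample_id: fraction_genome_altered(p, thr.fga_tumour) for p in tumour_profiles
        }
        cell_fga = {
            p.sample_id: fraction_genome_altered(p, thr.fga_cell_line) for p in cell_profiles
        }
        cell_functional = filter_functional(cell_catalog)
        tumour_functional = filter_functional(tumour_catalog)
        cell_burdens = [
            mutation_frequency(cell_functional, cell_cov[p.sample_id])
            for p in cell_profiles
        ]
        tumour_burdens = [
            mutation_frequency(tumour_functional, tumour_cov[p.sample_id])
            for p in tumour_profiles
        ]

        current = stage("copy-number similarity")
        similarities = {}
        for p in cell_profiles:
            similarities[p.sample_id] = cna_similarity(
                cell_cna[p.sample_id], tumour_cna, mean_profile, cell_line=p.sample_id
            )

        current = stage("hypermutator classification and components")
        hyper = classify_hypermutated(cell_burdens, cell_fga, config.hypermutator)
        universe = set(gene_models["gene"])
        markers = {}
        components = []
        for p in cell_profiles:
            sid = p.sample_id
            markers[sid] = marker_status(
                sid,
                cell_functional,
                gene_cna=cell_cna[sid],
                panels=config.panels,
                amp_threshold=thr.amplification,
                deletion_threshold=thr.deletion,
                gene_universe=universe,
            )
            components.append(
                assemble_components(
                    sid, similarities[sid], markers[sid], bool(hyper[sid]),
                    panel=config.panels.non_hgsoc,
                )
            )

        current = stage("scoring and ranking")
        ranking = rank_and_tier(components, config.weights, config.tiers)

        current = stage("expression ranking")
        # plain profile correlations over shared genes; see docs/methods.md on
        # why per-gene standardisation is not applied before ranking
        expr_rank = expression_rank(cell_expr, tumour_expr)

        current = stage("rank concordance")
        concordance = kendall_concordance(ranking.order(), list(expr_rank["sample"]))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    # --- write artefacts ---------------------------------------------------
    paths = PipelineResult(
        out_dir=out,
        ranking_table=out / "ranking.tsv",
        components_table=out / "components.tsv",
        burden_table=out / "burden.tsv",
        similarity_table=out / "similarity.tsv",
        expression_ranking=out / "expression_ranking.tsv",
        concordance_report=out / "concordance.json",
        scatter_tsv=out / "scatter.tsv",
        manifest=out / "manifest.json",
    )
    lio.write_ranking_table(ranking, paths.ranking_table, markers=markers)
    ranking.to_frame().drop(columns=["tier", "tie_break_note"]).to_csv(
        paths.components_table, sep="\t", index=False
    )
    burden_rows = pd.DataFrame(
        [
            {
                "sample": b.sample_id,
                "cohort": cohort,
                "functional_mutation_count": b.functional_mutation_count,
                "bases_covered": b.bases_covered,
                "frequency_per_mb": b.frequency_per_mb,
                "fga": (tumour_fga if cohort == "tumour" else cell_fga)[b.sample_id],
            }
            for cohort, burdens in (("tumour", tumour_burdens), ("cell_line", cell_burdens))
            for b in burdens
        ]
    )
    burden_rows.to_csv(paths.burden_table, sep="\t", index=False)
    sim_rows = pd.DataFrame(
        [
            {
                "sample": s.cell_line,
                "corr_with_mean_profile": s.corr_with_mean_profile,
                "median_correlation": s.median_correlation,
                "max_single_tumour_correlation": s.max_single_tumour_correlation,
            }
            for s in similarities.values()
        ]
    ).sort_values("sample")
    sim_rows.to_csv(paths.similarity_table, sep="\t", index=False)
    expr_rank.to_csv(paths.expression_ranking, sep="\t", index=False)
    paths.concordance_report.write_text(
        json.dumps(
            {
                "tau": concordance.tau,
                "p_value": concordance.p_value,
                "method": concordance.method,
                "n": concordance.n,
            },
            indent=2,
        )
        + "\n"
    )
    report_scatter(
        cell_burdens, cell_fga, hyper, paths.scatter_tsv, out / "scatter.png"
    )

    config_dict = config.to_dict()
    manifest = {
        "package": "linematch",
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_tumours": len(tumour_profiles),
        "n_cell_lines": len(cell_profiles),
    }
    paths.manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def report_scatter(burdens, fgas, hyper_flags, tsv_path, png_path=None):
    """Mutation frequency vs FGA scatter with hypermutators marked.

    The plotted data is also emitted as TSV so the figure is testable
    numerically.  Sample sets must align.
    """
    freq = {b.sample_id: b.frequency_per_mb for b in burdens}
    if not freq:
        raise ValidationError("no burdens to plot")
    if set(freq) != set(fgas) or set(freq) != set(hyper_flags.keys() if hasattr(hyper_flags, "keys") else hyper_flags.index):
        raise ValidationError("burden/FGA/hypermutator sample sets do not align")
    tab = pd.DataFrame(
        {
            "sample": sorted(freq),
            "frequency_per_mb": [freq[s] for s in sorted(freq)],
            "fga": [fgas[s] for s in sorted(freq)],
            "hypermutated": [bool(hyper_flags[s]) for s in sorted(freq)],
        }
    )
    tab.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        normal = tab[~tab["hypermutated"]]
        hyper = tab[tab["hypermutated"]]
        ax.scatter(normal["frequency_per_mb"], normal["fga"], s=18, label="panel")
        ax.scatter(
            hyper["frequency_per_mb"], hyper["fga"], s=30, marker="x", color="crimson",
            label="hypermutated",
        )
        ax.set_xlabel("functional mutations per Mb")
        ax.set_ylabel("fraction genome altered")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return tab
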