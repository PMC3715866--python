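"""Configuration objects for thresholds, score weights, panels and runs.

Defaults follow the published analysis settings for comparing a high-CNA
tumour cohort with a cell-line panel: the fraction-genome-altered threshold
is 0.2 for tumour profiles and 0.3 for cell lines (cell lines are purer, so
their copy-number signal is less attenuated), high-level amplification is a
log2 ratio strictly above 1.0, and the expression analyses use the top 5,000
genes by interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Genes whose mutation marks the HGSOC-typical genotype.
HGSOC_MUTATION_GENES = ("TP53", "BRCA1", "BRCA2")
#: Genes whose high-level amplification marks the HGSOC-typical genotype.
HGSOC_AMPLIFICATION_GENES = ("C11orf30", "CCNE1", "KRAS", "MYC")
#: Genes flagged when mutated or homozygously deleted.
HGSOC_MUT_OR_DEL_GENES = ("RB1",)
#: The seven genes recurrently mutated only in non-HGSOC ovarian-cancer
#: subtypes; the count of mutated panel genes is score component D.
NON_HGSOC_GENES = ("ARID1A", "BRAF", "CTNNB1", "ERBB2", "KRAS", "PIK3CA", "PTEN")


@dataclass(frozen=True)
class Panels:
    """Marker gene panels; all configurable."""

    hgsoc_mutation: tuple[str, ...] = HGSOC_MUTATION_GENES
    hgsoc_amplification: tuple[str, ...] = HGSOC_AMPLIFICATION_GENES
    hgsoc_mut_or_del: tuple[str, ...] = HGSOC_MUT_OR_DEL_GENES
    non_hgsoc: tuple[str, ...] = NON_HGSOC_GENES


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the affine suitability score S = wA*A + wB*B - wC*C - wD*D.

    The published equation is rendered only as a figure; these defaults make
    each component's dynamic range comparable (A spans about one unit, the
    binary terms half a unit each, D/4 at most 1.75) and are fully
    configurable.  All weights must be positive; the signs are fixed by the
    definition of S.
    """

    w_a: float = 1.0
    w_b: float = 0.5
    w_c: float = 0.5
    w_d: float = 0.25

    def __post_init__(self) -> None:
        for name in ("w_a", "w_b", "w_c", "w_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"score weight {name} must be positive")


@dataclass(frozen=True)
class HypermutatorParams:
    """Thresholds defining the hypermutator outlier archetype.

    A sample is hypermutated when its functional mutation frequency exceeds
    ``freq_threshold`` (per Mb of covered sequence) while its fraction genome
    altered stays below ``fga_threshold`` — many mutations, few copy-number
    changes.
    """

    freq_threshold: float = 10.0
    fga_threshold: float = 0.25


@dataclass(frozen=True)
class TierConfig:
    """Good/moderate/poor grouping of the ranked panel.

    ``mode="counts"`` takes the top ``n_good`` lines as good and the bottom
    ``n_poor`` as poor; ``mode="cutpoints"`` uses score cut points instead
    (good: S >= good_min; poor: S < poor_max).
    """

    mode: str = "counts"
    n_good: int = 12
    n_poor: int = 12
    good_min: float | None = None
    poor_max: float | None = None


@dataclass(frozen=True)
class Thresholds:
    """Copy-number thresholds, per dataset role."""

    fga_tumour: float = 0.2
    fga_cell_line: float = 0.3
    amplification: float = 1.0
    deletion: float = -1.0


@dataclass
class RunConfig:
    """Everything a full pipeline run needs: input paths plus parameters."""

    out_dir: str
    seed: int = 0
    # input paths
    tumour_seg: str = ""
    cell_seg: str = ""
    tumour_mutations: str = ""
    cell_mutations: str = ""
    tumour_coverage_dir: str = ""
    cell_coverage_dir: str = ""
    gene_models: str = ""
    tumour_expression: str = ""
    cell_expression: str = ""
    # parameters
    thresholds: Thresholds = field(default_factory=Thresholds)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    hypermutator: HypermutatorParams = field(default_factory=HypermutatorParams)
    tiers: TierConfig = field(default_factory=TierConfig)
    panels: Panels = field(default_factory=Panels)
    n_top_genes: int = 5000
    linkage_all: str = "ward"
    linkage_combined: str = "complete"

    def validate_paths(self) -> None:
        for name in (
            "tumour_seg",
            "cell_seg",
            "tumour_mutations",
            "cell_mutations",
            "tumour_coverage_dir",
            "cell_coverage_dir",
            "gene_models",
            "tumour_expression",
            "cell_expression",
        ):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"run config: {name} path missing or absent: {p!r}")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("panels",):
            d[key] = {k: list(v) for k, v in d[key].items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "weights" in raw:
            raw["weights"] = ScoreWeights(**raw["weights"])
        if "hypermutator" in raw:
            raw["hypermutator"] = HypermutatorParams(**raw["hypermutator"])
        if "tiers" in raw:
            tiers = dict(raw["tiers"])
            raw["tiers"] = TierConfig(**tiers)
        if "panels" in raw:
            raw["panels"] = Panels(**{k: tuple(v) for k, v in raw["panels"].items()})
        return cls(**raw)
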