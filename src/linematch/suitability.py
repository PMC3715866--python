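"""Suitability scoring: hypermutator classification, score assembly, and the
good/moderate/poor grouping of a cell-line panel.

The suitability score of a cell line is the affine combination

    S = w_A * A + w_B * B - w_C * C - w_D * D

where A is the Pearson correlation of the line's gene-level copy-number
profile with the tumour cohort's mean profile, B indicates a TP53 mutation,
C indicates a hypermutator genotype (high mutation frequency with few
copy-number changes), and D counts mutated genes among the seven-gene
non-HGSOC panel.  HGSOC-typical features raise S; features typical of other
ovarian-cancer subtypes lower it.  The ordering distinguishes better from
poorer models but is not meant as a finely graduated ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cna import CnaSimilarity
from .config import HypermutatorParams, ScoreWeights, TierConfig, NON_HGSOC_GENES
from .io import ValidationError
from .mutation import MarkerStatus, MutationBurden


def classify_hypermutated(
    burdens: Iterable[MutationBurden],
    fga: Mapping[str, float],
    params: HypermutatorParams | None = None,
) -> pd.Series:
    """Flag samples with many mutations but few copy-number changes.

    True iff frequency_per_mb > ``params.freq_threshold`` and fraction genome
    altered < ``params.fga_threshold``.  Burdens and FGA values must cover
    the same samples.
    """
    params = params or HypermutatorParams()
    freq = pd.Series({b.sample_id: b.frequency_per_mb for b in burdens}, dtype=float)
    fga_s = pd.Series(dict(fga), dtype=float)
    missing_f = set(freq.index) - set(fga_s.index)
    missing_b = set(fga_s.index) - set(freq.index)
    if missing_f or missing_b:
        raise ValidationError(
            f"burden/FGA sample mismatch: no FGA for {sorted(missing_f)[:5]}, "
            f"no burden for {sorted(missing_b)[:5]}"
        )
    fga_s = fga_s.reindex(freq.index)
    return (freq > params.freq_threshold) & (fga_s < params.fga_threshold)


@dataclass
class SuitabilityComponents:
    """The (A, B, C, D) tuple and score S of one cell line."""

    cell_line: str
    A: float
    B: int
    C: int
    D: int
    S: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.A <= 1.0 + 1e-12:
            raise ValidationError(f"{self.cell_line}: A={self.A} outside [-1, 1]")
        if self.B not in (0, 1) or self.C not in (0, 1):
            raise ValidationError(f"{self.cell_line}: B and C must be 0/1")
        if self.D < 0:
            raise ValidationError(f"{self.cell_line}: D must be non-negative")


def assemble_components(
    cell_line: str,
    similarity: CnaSimilarity,
    markers: MarkerStatus,
    hypermutated: bool,
    panel: Sequence[str] = NON_HGSOC_GENES,
) -> SuitabilityComponents:
    """Collect (A, B, C, D) for one cell line from upstream results.

    A missing TP53 or panel flag raises — absence of information is never
    treated as absence of mutation.
    """
    if similarity.cell_line != cell_line or markers.sample_id != cell_line:
        raise ValidationError(
            f"inputs refer to different samples: {similarity.cell_line!r}, "
            f"{markers.sample_id!r}, {cell_line!r}"
        )
    tp53 = markers.mutation.get("TP53")
    if tp53 is None:
        raise ValidationError(f"{cell_line}: TP53 mutation status missing")
    flags = []
    for gene in panel:
        flag = markers.non_hgsoc.get(gene)
        if flag is None:
            raise ValidationError(f"{cell_line}: marker flag for panel gene {gene!r} missing")
        flags.append(bool(flag))
    return SuitabilityComponents(
        cell_line=cell_line,
        A=float(similarity.corr_with_mean_profile),
        B=int(bool(tp53)),
        C=int(bool(hypermutated)),
        D=int(sum(flags)),
    )


def suitability_score(
    components: SuitabilityComponents, weights: ScoreWeights | None = None
) -> float:
    """Evaluate S = w_A*A + w_B*B - w_C*C - w_D*D with the configured weights."""
    w = weights or ScoreWeights()
    return float(w.w_a * components.A + w.w_b * components.B - w.w_c * components.C - w.w_d * components.D)


@dataclass
class SuitabilityRanking:
    """Ordered panel with good/moderate/poor tiers.

    ``entries`` is sorted by S descending (ties broken by A descending, then
    sample id); ``tiers`` and ``tie_break_notes`` are parallel lists.  Tiers
    form contiguous blocks of the sorted order.
    """

    entries: list[SuitabilityComponents]
    tiers: list[str]
    tie_break_notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [e.cell_line for e in self.entries],
                "A": [e.A for e in self.entries],
                "B": [e.B for e in self.entries],
                "C": [e.C for e in self.entries],
                "D": [e.D for e in self.entries],
                "S": [e.S for e in self.entries],
                "tier": self.tiers,
                "tie_break_note": self.tie_break_notes,
            }
        )

    def order(self) -> list[str]:
        return [e.cell_line for e in self.entries]


def rank_and_tier(
    components: Iterable[SuitabilityComponents],
    weights: ScoreWeights | None = None,
    tiers: TierConfig | None = None,
) -> SuitabilityRanking:
    """Score, sort and tier a panel.

    Entries are ordered by S descending; exact S ties fall back to A
    descending, then lexicographic sample id, with the rule recorded in the
    entry's tie-break note.  Tiers come either from top/bottom counts
    (default: top 12 good, bottom 12 poor) or from score cut points.
    """
    comps = list(components)
    if not comps:
        raise ValidationError("empty component collection")
    w = weights or ScoreWeights()
    cfg = tiers or TierConfig()
    for c in comps:
        c.S = suitability_score(c, w)
    comps.sort(key=lambda c: (-c.S, -c.A, c.cell_line))

    notes = []
    s_values = [c.S for c in comps]
    for i, c in enumerate(comps):
        tied = (i > 0 and s_values[i - 1] == c.S) or (
            i + 1 < len(comps) and s_values[i + 1] == c.S
        )
        notes.append("S tie; ordered by A desc, then sample id" if tied else "")

    n = len(comps)
    if cfg.mode == "counts":
        n_good = min(cfg.n_good, n)
        n_poor = min(cfg.n_poor, n - n_good)
        tier_labels = (
            ["good"] * n_good + ["moderate"] * (n - n_good - n_poor) + ["poor"] * n_poor
        )
    elif cfg.mode == "cutpoints":
        if cfg.good_min is None or cfg.poor_max is None:
            raise ValidationError("cutpoint tiering needs good_min and poor_max")
        tier_labels = [
            "good" if c.S >= cfg.good_min else ("poor" if c.S < cfg.poor_max else "moderate")
            for c in comps
        ]
    else:
        raise ValidationError(f"unknown tier mode {cfg.mode!r}")

    return SuitabilityRanking(entries=comps, tiers=tier_labels, tie_break_notes=notes)
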