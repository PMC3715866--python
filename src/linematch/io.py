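"""Readers, writers and domain containers for the tabular formats the pipeline touches.

Formats handled:

* SEG-style TSV (``sample``, ``chromosome``, ``loc.start``, ``loc.end``,
  ``seg.mean``) for segmented DNA copy-number profiles.  Coordinates are
  **1-based, fully closed** intervals, the convention of SEG tables exported
  by cBioPortal-style portals; a segment of length 1 has ``end == start + 0``
  is disallowed (``end > start`` is required) and segment length is
  ``end - start + 1``.
* MAF-style TSV (``sample``, ``gene``, ``classification``) for mutation
  catalogues, with a configurable mapping from common MAF spellings
  (``Missense_Mutation``, ``3'UTR``, ...) to a controlled vocabulary.
* Sequencing coverage in two dialects: text wiggle (fixedStep/variableStep)
  with per-base read counts, and a per-exon table of exon length plus a
  coverage fraction in [0, 1].
* Gene-by-sample expression matrices and BED-style gene model tables as TSV.

Sex chromosomes are dropped on read by default; the copy-number analysis is
restricted to autosomes 1-22.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = ("X", "Y", "MT", "M")

#: Controlled vocabulary for variant classifications.
CLASSIFICATION_VOCABULARY = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "in_frame_indel",
        "nonstop",
        "translation_start",
        "silent",
        "intron",
        "utr5",
        "utr3",
        "flank",
        "igr",
        "rna",
    }
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["chromosome", "start", "end", "seg_mean"]


@dataclass
class SegmentedProfile:
    """One sample's segmented copy-number profile (log2 copy ratios).

    ``segments`` is a frame with columns ``chromosome`` (label, "1".."22"),
    ``start``/``end`` (1-based closed, bp) and ``seg_mean`` (log2 ratio),
    sorted by chromosome then start.  Segments on the same chromosome must
    not overlap.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise FormatError(f"segment table missing column(s): {missing}")
        seg = seg[SEGMENT_COLUMNS].copy()
        seg["chromosome"] = seg["chromosome"].astype(str)
        seg["start"] = seg["start"].astype(np.int64)
        seg["end"] = seg["end"].astype(np.int64)
        seg["seg_mean"] = seg["seg_mean"].astype(float)
        bad = seg["end"] <= seg["start"]
        if bad.any():
            row = seg.index[bad][0]
            raise ValidationError(
                f"sample {self.sample_id!r}: segment end <= start at row {row} "
                f"({seg.loc[row, 'chromosome']}:{seg.loc[row, 'start']}-{seg.loc[row, 'end']})"
            )
        seg = seg.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in seg.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]  # closed intervals
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                raise ValidationError(
                    f"sample {self.sample_id!r}: overlapping segments on chromosome "
                    f"{chrom}: [{starts[i]}-{ends[i]}] and [{starts[i + 1]}-{ends[i + 1]}]"
                )
        self.segments = seg

    @property
    def lengths(self) -> np.ndarray:
        """Segment lengths in bp (closed-interval convention)."""
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy()

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic footprint: symbol plus a 1-based closed interval."""

    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene!r}: end <= start")


@dataclass
class MutationCatalog:
    """Per-sample mutation records with validated classifications.

    ``records`` has columns ``sample_id``, ``gene``, ``classification``,
    ``protein_change``; ``samples`` is the set of samples assayed (a sample
    may legitimately have zero records).  ``functional_only`` is set by
    :func:`linematch.mutation.filter_functional`.
    """

    records: pd.DataFrame
    samples: tuple[str, ...] = ()
    functional_only: bool = False

    def __post_init__(self) -> None:
        rec = self.records.copy()
        for col in ("sample_id", "gene", "classification"):
            if col not in rec.columns:
                raise FormatError(f"mutation table missing column {col!r}")
        if "protein_change" not in rec.columns:
            rec["protein_change"] = ""
        rec = rec[["sample_id", "gene", "classification", "protein_change"]]
        unknown = set(rec["classification"].unique()) - CLASSIFICATION_VOCABULARY
        if unknown:
            raise ValidationError(
                f"unknown variant classification(s): {sorted(unknown)}"
            )
        self.records = rec.reset_index(drop=True)
        if not self.samples:
            self.samples = tuple(pd.unique(rec["sample_id"]))

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]

    def counts_by_sample(self) -> pd.Series:
        counts = self.records.groupby("sample_id").size()
        return counts.reindex(list(self.samples), fill_value=0)

    def genes(self) -> set[str]:
        return set(self.records["gene"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CoverageTrack:
    """Callable-bases information for one sample, in one of two dialects.

    ``per_base`` holds, per chromosome, an ``(n, 2)`` integer array of merged
    closed intervals of positions with read count >= 1 (a run-length encoding
    of the covered-position set).  ``per_exon`` is a frame with columns
    ``exon_length`` (bp, > 0) and ``coverage_fraction`` (in [0, 1]).
    Exactly one dialect is populated.
    """

    sample_id: str
    dialect: str  # "per_base" | "per_exon"
    per_base: dict[str, np.ndarray] | None = None
    per_exon: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.dialect not in ("per_base", "per_exon"):
            raise ValidationError(f"unknown coverage dialect {self.dialect!r}")
        if (self.per_base is None) == (self.per_exon is None):
            raise ValidationError("exactly one coverage dialect must be populated")
        if self.dialect == "per_base":
            if self.per_base is None:
                raise ValidationError("per_base dialect requires per_base intervals")
            clean: dict[str, np.ndarray] = {}
            for chrom, runs in self.per_base.items():
                arr = np.asarray(runs, dtype=np.int64).reshape(-1, 2)
                if len(arr) and (arr[:, 1] < arr[:, 0]).any():
                    raise ValidationError(
                        f"sample {self.sample_id!r}: covered run end < start on {chrom}"
                    )
                clean[str(chrom)] = _merge_runs(arr)
            self.per_base = clean
        else:
            if self.per_exon is None:
                raise ValidationError("per_exon dialect requires an exon table")
            tab = self.per_exon.copy()
            for col in ("exon_length", "coverage_fraction"):
                if col not in tab.columns:
                    raise FormatError(f"per-exon coverage missing column {col!r}")
            tab["exon_length"] = tab["exon_length"].astype(np.int64)
            tab["coverage_fraction"] = tab["coverage_fraction"].astype(float)
            if (tab["exon_length"] <= 0).any():
                raise ValidationError(f"sample {self.sample_id!r}: exon_length must be > 0")
            frac = tab["coverage_fraction"]
            if ((frac < 0) | (frac > 1)).any():
                bad = frac[(frac < 0) | (frac > 1)].iloc[0]
                raise ValidationError(
                    f"sample {self.sample_id!r}: coverage_fraction {bad} outside [0, 1]"
                )
            self.per_exon = tab[["exon_length", "coverage_fraction"]].reset_index(drop=True)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a dataset/platform label.

    ``values`` is a frame indexed by gene symbol with one column per sample.
    ``sample_datasets`` maps each sample to its dataset label; a combined
    matrix carries one label per source dataset.
    """

    values: pd.DataFrame
    sample_datasets: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers")
        self.sample_datasets = self.sample_datasets.reindex(self.values.columns)
        if self.sample_datasets.isna().any():
            missing = self.sample_datasets.index[self.sample_datasets.isna()].tolist()
            raise ValidationError(f"samples without a dataset label: {missing[:5]}")

    @classmethod
    def from_frame(cls, values: pd.DataFrame, dataset_label: str) -> "ExpressionMatrix":
        labels = pd.Series(dataset_label, index=values.columns)
        return cls(values=values, sample_datasets=labels)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def dataset_label(self) -> str:
        labels = self.sample_datasets.unique()
        if len(labels) != 1:
            raise ValidationError("matrix combines several datasets; no single label")
        return str(labels[0])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def normalize_chromosome(label: object) -> str:
    """Normalise a chromosome label: ``"chr1" -> "1"``, ``"chrx" -> "X"``.

    Idempotent; numeric labels keep their integer spelling.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        return s.upper()
    try:
        return str(int(s))
    except ValueError:
        return s


def _merge_runs(arr: np.ndarray) -> np.ndarray:
    """Merge closed integer intervals that overlap or touch."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0], kind="mergesort")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _resolve_columns(
    columns: Sequence[str], aliases: Mapping[str, set[str]], what: str
) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    out = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                out[canon] = lower[name]
                break
        else:
            raise FormatError(f"{what}: missing required column {canon!r}")
    return out


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_ALIASES = {
    "sample": {"sample", "sample_id", "id", "sample_name", "tumor_sample_barcode"},
    "chromosome": {"chromosome", "chrom", "chr"},
    "start": {"start", "loc.start", "loc_start", "start_position"},
    "end": {"end", "loc.end", "loc_end", "end_position"},
    "seg_mean": {"seg.mean", "seg_mean", "segment_mean", "mean"},
}


def read_seg(path: str | Path, drop_sex_chromosomes: bool = True) -> list[SegmentedProfile]:
    """Read a SEG-style TSV into one :class:`SegmentedProfile` per sample.

    Chromosome labels are normalised ("chr1" -> "1"); sex chromosomes are
    dropped by default.  A num-probes column, if present, is ignored.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    cols = _resolve_columns(tab.columns, _SEG_ALIASES, f"SEG file {path}")
    tab = tab.rename(columns={v: k for k, v in cols.items()})
    tab["chromosome"] = tab["chromosome"].map(normalize_chromosome)
    if drop_sex_chromosomes:
        keep = tab["chromosome"].isin(AUTOSOMES)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("read_seg: dropped %d sex/other-chromosome rows", dropped)
        tab = tab[keep]
    profiles = []
    for sample, grp in tab.groupby("sample", sort=True):
        profiles.append(
            SegmentedProfile(
                sample_id=str(sample),
                segments=grp[SEGMENT_COLUMNS].reset_index(drop=True),
            )
        )
    return profiles


def write_seg(profiles: Iterable[SegmentedProfile], path: str | Path) -> None:
    """Write profiles as a SEG-style TSV (full float precision)."""
    frames = []
    for prof in profiles:
        seg = prof.segments.copy()
        seg.insert(0, "sample", prof.sample_id)
        frames.append(seg)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutations (MAF-style)
# ---------------------------------------------------------------------------

_MAF_ALIASES = {
    "sample": {"sample", "sample_id", "tumor_sample_barcode"},
    "gene": {"gene", "hugo_symbol", "gene_symbol"},
    "classification": {"classification", "variant_classification"},
}


def default_classification_map() -> dict[str, str]:
    """The packaged MAF-spelling -> vocabulary mapping (editable YAML)."""
    text = resources.files("linematch.data").joinpath("maf_classes.yaml").read_text()
    mapping = yaml.safe_load(text)
    return {str(k): str(v) for k, v in mapping.items()}


def read_mutations(
    path: str | Path,
    classification_map: Mapping[str, str] | str | Path | None = None,
    samples: Sequence[str] | None = None,
) -> MutationCatalog:
    """Read a MAF-style TSV into a :class:`MutationCatalog`.

    ``classification_map`` translates input spellings to the controlled
    vocabulary; by default the packaged mapping is used, extended with the
    identity on vocabulary terms.  Unmapped labels raise, listing the
    offenders — they are never coerced.
    """
    if classification_map is None:
        cmap = default_classification_map()
    elif isinstance(classification_map, (str, Path)):
        cmap = {str(k): str(v) for k, v in yaml.safe_load(Path(classification_map).read_text()).items()}
    else:
        cmap = dict(classification_map)
    for term in CLASSIFICATION_VOCABULARY:
        cmap.setdefault(term, term)

    tab = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(tab.columns, _MAF_ALIASES, f"mutation file {path}")
    tab = tab.rename(columns={v: k for k, v in cols.items()})
    unmapped = sorted(set(tab["classification"].unique()) - set(cmap))
    if unmapped:
        raise ValidationError(f"unmapped variant classification label(s): {unmapped}")
    protein = None
    for cand in ("protein_change", "Protein_Change", "HGVSp_Short"):
        if cand in tab.columns:
            protein = tab[cand]
            break
    rec = pd.DataFrame(
        {
            "sample_id": tab["sample"],
            "gene": tab["gene"],
            "classification": tab["classification"].map(cmap),
            "protein_change": protein if protein is not None else "",
        }
    )
    return MutationCatalog(records=rec, samples=tuple(samples) if samples else ())


def write_mutations(catalog: MutationCatalog, path: str | Path) -> None:
    catalog.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(r"(\w+)=(\S+)")


def read_coverage(
    path: str | Path, dialect: str, sample_id: str | None = None
) -> CoverageTrack:
    """Read a coverage file into a :class:`CoverageTrack`.

    ``dialect="per_base"`` expects a text wiggle track of per-base read
    counts (fixedStep or variableStep, span supported); positions with a
    count >= 1 are retained.  ``dialect="per_exon"`` expects a TSV of exon
    length and coverage fraction, retained verbatim.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    if dialect == "per_base":
        runs = _parse_wig(path)
        return CoverageTrack(sample_id=sid, dialect="per_base", per_base=runs)
    if dialect == "per_exon":
        tab = pd.read_csv(path, sep="\t")
        cols = _resolve_columns(
            tab.columns,
            {
                "exon_length": {"exon_length", "length"},
                "coverage_fraction": {"coverage_fraction", "coverage", "fraction"},
            },
            f"per-exon coverage file {path}",
        )
        tab = tab.rename(columns={v: k for k, v in cols.items()})
        return CoverageTrack(sample_id=sid, dialect="per_exon", per_exon=tab)
    raise ValidationError(f"unknown coverage dialect {dialect!r}")


def _parse_wig(path: Path) -> dict[str, np.ndarray]:
    runs: dict[str, list[list[int]]] = {}
    mode = None  # ("fixed", chrom, next_pos, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(_STEP_RE.findall(line))
                mode = [
                    "fixed",
                    normalize_chromosome(kv["chrom"]),
                    int(kv["start"]),
                    int(kv.get("step", 1)),
                    int(kv.get("span", 1)),
                ]
                continue
            if line.startswith("variableStep"):
                kv = dict(_STEP_RE.findall(line))
                mode = ["variable", normalize_chromosome(kv["chrom"]), int(kv.get("span", 1))]
                continue
            if mode is None:
                raise FormatError(f"wig file {path}: data line before a step declaration")
            if mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                value = float(line)
                if value >= 1:
                    runs.setdefault(chrom, []).append([pos, pos + span - 1])
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                fields = line.split()
                pos, value = int(fields[0]), float(fields[1])
                if value >= 1:
                    runs.setdefault(chrom, []).append([pos, pos + span - 1])
    return {c: np.asarray(r, dtype=np.int64) for c, r in runs.items()}


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track (wig for per_base, TSV for per_exon)."""
    if track.dialect == "per_base":
        assert track.per_base is not None
        with open(path, "w") as fh:
            for chrom in sorted(track.per_base):
                for start, end in track.per_base[chrom]:
                    length = int(end - start + 1)
                    fh.write(f"fixedStep chrom={chrom} start={int(start)} step={length} span={length}\n1\n")
    else:
        assert track.per_exon is not None
        track.per_exon.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a BED-style TSV (gene, chromosome, start, end) of gene models.

    Returns a validated frame with one row per gene symbol, chromosome labels
    normalised, 1-based closed coordinates.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    cols = _resolve_columns(
        tab.columns,
        {
            "gene": {"gene", "symbol", "gene_symbol", "name"},
            "chromosome": {"chromosome", "chrom", "chr"},
            "start": {"start"},
            "end": {"end"},
        },
        f"gene model file {path}",
    )
    tab = tab.rename(columns={v: k for k, v in cols.items()})
    return validate_gene_models(tab)


def validate_gene_models(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab[["gene", "chromosome", "start", "end"]].copy()
    tab["chromosome"] = tab["chromosome"].map(normalize_chromosome)
    tab["start"] = tab["start"].astype(np.int64)
    tab["end"] = tab["end"].astype(np.int64)
    if tab["gene"].duplicated().any():
        dups = tab.loc[tab["gene"].duplicated(), "gene"].unique().tolist()
        raise ValidationError(f"duplicate gene model(s): {dups[:5]}")
    if (tab["end"] <= tab["start"]).any():
        bad = tab.loc[tab["end"] <= tab["start"], "gene"].iloc[0]
        raise ValidationError(f"gene {bad!r}: end <= start")
    return tab.reset_index(drop=True)


def write_gene_models(tab: pd.DataFrame, path: str | Path) -> None:
    validate_gene_models(tab).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, dataset_label: str) -> ExpressionMatrix:
    """Read a genes-by-samples expression TSV (first column ``gene``)."""
    tab = pd.read_csv(path, sep="\t")
    first = tab.columns[0]
    tab = tab.set_index(first)
    tab.index.name = "gene"
    tab.index = tab.index.astype(str)
    return ExpressionMatrix.from_frame(tab.astype(float), dataset_label)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# suitability ranking table
# ---------------------------------------------------------------------------


def write_ranking_table(ranking, path: str | Path, markers: Mapping[str, object] | None = None) -> None:
    """Serialise a :class:`~linematch.suitability.SuitabilityRanking` as TSV.

    Columns: sample, A, B, C, D, S, tier, tie_break_note, then one column per
    marker flag when per-sample :class:`~linematch.mutation.MarkerStatus`
    objects are supplied.  Row order equals ranking order.
    """
    frame = ranking.to_frame()
    if frame.empty:
        raise ValidationError("empty ranking")
    if markers is not None:
        flag_rows = []
        for sample in frame["sample"]:
            status = markers[sample]
            flag_rows.append(status.flags())
        flags = pd.DataFrame(flag_rows, index=frame.index)
        frame = pd.concat([frame, flags], axis=1)
    frame.to_csv(path, sep="\t", index=False)


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    """Read back a ranking table written by :func:`write_ranking_table`."""
    return pd.read_csv(path, sep="\t")
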