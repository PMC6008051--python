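"""Domain types, file readers/writers, and dataset validation.

The pipeline's universal input is an :class:`ExpressionDataset`: a
transcripts × samples matrix of unique-read counts, per-sample metadata
(tissue, muscle class, species, sex, replicate) and per-transcript
annotation (gene symbol, chromosome with mitochondrial flag, length,
exon structure).

Genomic coordinates are 0-based half-open everywhere internally.  Input
junction files declare their dialect (``zero_half_open`` or
``one_inclusive``) and are converted exactly once on read; the dialect
of a record set is recorded so a second conversion is an error rather
than a silent off-by-one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MUSCLE_CLASSES = ("skeletal", "cardiac", "smooth")
SEXES = ("male", "female", "unknown")
COORD_DIALECTS = ("zero_half_open", "one_inclusive")

METADATA_COLUMNS = ["tissue", "muscle_class", "species", "sex", "replicate"]
ANNOTATION_COLUMNS = ["gene_symbol", "chrom", "is_mitochondrial", "length_bp", "strand", "exons"]


class DataModelError(ValueError):
    """Raised when an input violates a dataset invariant."""


@dataclass(frozen=True)
class JunctionRecord:
    """One intron observation from spliced alignments.

    ``intron_start`` is 0-based inclusive, ``intron_end`` 0-based
    exclusive (the intron occupies [start, end)).
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    read_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise DataModelError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                "intron_end must exceed intron_start"
            )
        if self.read_count < 0:
            raise DataModelError("read_count must be non-negative")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass
class JunctionSet:
    """Junction records plus the dialect they were normalized from."""

    records: list[JunctionRecord]
    dialect: str = "zero_half_open"

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class OrthologTable:
    """One-to-one ortholog pairing between two species' transcript IDs.

    Many-to-many rows are dropped at construction and counted in
    ``n_ambiguous_dropped``.
    """

    pairs: tuple[tuple[str, str], ...]
    n_ambiguous_dropped: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologTable":
        uniq = list(dict.fromkeys((str(a), str(b)) for a, b in pairs))
        from collections import Counter

        ca = Counter(a for a, _ in uniq)
        cb = Counter(b for _, b in uniq)
        kept = [(a, b) for a, b in uniq if ca[a] == 1 and cb[b] == 1]
        return cls(pairs=tuple(kept), n_ambiguous_dropped=len(uniq) - len(kept))

    def as_mapping(self) -> dict[str, str]:
        return dict(self.pairs)


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols (case-folded to upper case)."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], provenance: str = "") -> "GeneList":
        members = frozenset(s.strip().upper() for s in symbols if s.strip())
        if not members:
            raise DataModelError(f"gene list {name!r} is empty")
        return cls(name=name, members=members, provenance=provenance)

    @classmethod
    def from_file(cls, name: str, path: str | Path, provenance: str = "") -> "GeneList":
        lines = Path(path).read_text().splitlines()
        return cls.from_symbols(name, lines, provenance=provenance or str(path))

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members

    def __len__(self) -> int:
        return len(self.members)


def _parse_exons(spec: str) -> tuple[tuple[int, int], ...]:
    """Parse "start-end,start-end" into sorted half-open intervals."""
    if not spec or spec in (".", "nan"):
        return ()
    out = []
    for part in str(spec).split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _format_exons(exons: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons) if exons else "."


def validate_annotation_row(tid: str, row: pd.Series) -> None:
    if row["length_bp"] < 1:
        raise DataModelError(f"transcript {tid}: length_bp must be >= 1")
    if row["strand"] not in ("+", "-"):
        raise DataModelError(f"transcript {tid}: strand must be + or -")
    exons = row["exons"]
    if exons:
        prev_end = None
        total = 0
        for s, e in exons:
            if e <= s:
                raise DataModelError(f"transcript {tid}: empty/inverted exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise DataModelError(f"transcript {tid}: exons overlap or are unsorted")
            prev_end = e
            total += e - s
        if total != row["length_bp"]:
            raise DataModelError(
                f"transcript {tid}: exon lengths sum to {total}, expected length_bp={row['length_bp']}"
            )


@dataclass
class ExpressionDataset:
    """Count matrix + sample metadata + transcript annotation.

    counts:     DataFrame [transcripts × samples], non-negative integers.
    samples:    DataFrame indexed by sample_id with columns
                tissue, muscle_class, species, sex, replicate.
    transcripts: DataFrame indexed by transcript_id with columns
                gene_symbol, chrom, is_mitochondrial, length_bp, strand, exons.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    transcripts: pd.DataFrame
    dropped_transcripts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        if self.samples.index.duplicated().any():
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise DataModelError(f"duplicate sample_id(s): {dups}")
        if self.transcripts.index.duplicated().any():
            dups = self.transcripts.index[self.transcripts.index.duplicated()].tolist()
            raise DataModelError(f"duplicate transcript_id(s): {dups}")
        if list(self.counts.columns) != list(self.samples.index):
            raise DataModelError("counts columns do not align with sample metadata index")
        if list(self.counts.index) != list(self.transcripts.index):
            raise DataModelError("counts rows do not align with transcript annotation index")

        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise DataModelError(
                    f"non-integer count at row {self.counts.index[bad[0]]!r}, "
                    f"column {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise DataModelError(
                f"negative count at row {self.counts.index[bad[0]]!r}, "
                f"column {self.counts.columns[bad[1]]!r}"
            )

        bad_class = set(self.samples["muscle_class"]) - set(MUSCLE_CLASSES)
        if bad_class:
            raise DataModelError(f"unknown muscle_class values: {sorted(bad_class)}")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise DataModelError(f"unknown sex values: {sorted(bad_sex)}")
        if (self.samples["replicate"].astype(int) < 1).any():
            raise DataModelError("replicate numbers must be positive")

        for tid, row in self.transcripts.iterrows():
            validate_annotation_row(tid, row)

    # -- convenience ------------------------------------------------
    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.samples["tissue"]))

    def samples_of_tissue(self, tissue: str) -> list[str]:
        hit = self.samples.index[self.samples["tissue"] == tissue]
        if len(hit) == 0:
            raise DataModelError(f"unknown tissue {tissue!r}")
        return list(hit)

    def tissue_class_map(self) -> dict[str, str]:
        return dict(zip(self.samples["tissue"], self.samples["muscle_class"]))

    def require_replicated(self, min_replicates: int = 2) -> None:
        """Inferential operations need >= 2 replicates per tissue."""
        sizes = self.samples.groupby("tissue").size()
        low = sizes[sizes < min_replicates]
        if len(low):
            raise DataModelError(
                f"tissues with fewer than {min_replicates} replicates: {dict(low)}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
) -> ExpressionDataset:
    """Read and validate the three standard TSVs into a dataset.

    Transcripts present in the counts matrix but absent from the
    annotation are dropped with a logged count (they are recorded on
    ``dataset.dropped_transcripts``).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="transcript_id")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id", dtype={"replicate": int})
    ann = pd.read_csv(
        annotation_path,
        sep="\t",
        index_col="transcript_id",
        dtype={"is_mito": int, "length_bp": int},
    )
    ann = ann.rename(columns={"is_mito": "is_mitochondrial"})
    ann["is_mitochondrial"] = ann["is_mitochondrial"].astype(bool)
    ann["exons"] = [_parse_exons(x) for x in ann.get("exons", pd.Series("." , index=ann.index))]

    missing_meta = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise DataModelError(f"metadata missing columns: {missing_meta}")

    dropped = [t for t in counts.index if t not in ann.index]
    if dropped:
        logger.warning("%d transcripts in counts absent from annotation; dropped", len(dropped))
        counts = counts.drop(index=dropped)
    ann = ann.loc[counts.index]
    meta = meta.loc[counts.columns]

    return ExpressionDataset(
        counts=counts, samples=meta, transcripts=ann, dropped_transcripts=dropped
    )


def read_junctions(path: str | Path, coordinate_dialect: str) -> JunctionSet:
    """Read a junction TSV and normalize to 0-based half-open introns.

    ``one_inclusive`` input (1-based, both ends inclusive) has 1
    subtracted from the start; the end is already the exclusive 0-based
    coordinate. Rows with zero reads are retained — no filtering happens
    at read time.
    """
    if coordinate_dialect not in COORD_DIALECTS:
        raise DataModelError(
            f"unknown coordinate dialect {coordinate_dialect!r}; expected one of {COORD_DIALECTS}"
        )
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise DataModelError(f"junction file missing columns: {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = "pooled"

    offset = 1 if coordinate_dialect == "one_inclusive" else 0
    records = [
        JunctionRecord(
            chrom=str(r.chrom),
            intron_start=int(r.start) - offset,
            intron_end=int(r.end),
            strand=str(r.strand),
            read_count=int(r.reads),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples()
    ]
    return JunctionSet(records=records, dialect="zero_half_open")


def convert_dialect(junctions: JunctionSet, coordinate_dialect: str) -> JunctionSet:
    """Explicit conversion guard: converting an already-normalized set is an error."""
    if junctions.dialect == "zero_half_open":
        raise DataModelError(
            "junction set is already in normalized 0-based half-open coordinates; "
            "a second conversion would silently shift introns"
        )
    raise DataModelError(f"cannot convert from dialect {junctions.dialect!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(result: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table as deterministic, sorted, round-trippable TSV."""
    if format != "tsv":
        raise DataModelError(f"unsupported format {format!r}")
    df = result.sort_index()
    df.to_csv(path, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_dataset(
    dataset: ExpressionDataset,
    counts_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write a dataset back to the three standard TSVs."""
    c = dataset.counts.copy()
    c.index.name = "transcript_id"
    c.to_csv(counts_path, sep="\t")
    m = dataset.samples.copy()
    m.index.name = "sample_id"
    m.to_csv(metadata_path, sep="\t")
    a = dataset.transcripts.copy()
    a.index.name = "transcript_id"
    a["is_mito"] = a.pop("is_mitochondrial").astype(int)
    a["exons"] = [_format_exons(x) for x in a["exons"]]
    a = a[["gene_symbol", "chrom", "is_mito", "length_bp", "strand", "exons"]]
    a.to_csv(annotation_path, sep="\t")


def export_newick(tree, path: str | Path) -> None:
    """Write a dendrogram (similarity_structure.Dendrogram) as newick."""
    Path(path).write_text(tree.to_newick() + "\n")


def export_bed(junctions: Iterable, path: str | Path) -> None:
    """Write junction records/calls as BED6; score = min(read_count, 1000).

    Accepts JunctionRecord-likes (``read_count``) or aggregated calls
    (``total_reads``).
    """
    lines = []
    for i, j in enumerate(junctions):
        reads = getattr(j, "total_reads", None)
        if reads is None:
            reads = j.read_count
        start = getattr(j, "intron_start")
        end = getattr(j, "intron_end")
        name = f"junction_{i + 1}"
        lines.append(
            f"{j.chrom}\t{start}\t{end}\t{name}\t{min(int(reads), 1000)}\t{j.strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
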