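"""Novel splice-junction discovery and event classification.

Known introns are the gaps between consecutive exons of every annotated
transcript. Observed junctions absent from that set are aggregated
across samples, ranked by total read support, and classified:

* ``exon_skipping`` — both intron ends sit on annotated exon boundaries
  (donor on an exon end, acceptor on a downstream exon start) with at
  least one annotated exon strictly inside the intron;
* ``novel_exon_or_site`` — one or both ends off any annotated boundary
  (a cryptic splice site or a previously undescribed exon);
* ``unresolved`` — boundary-consistent but with no skipped exon, or on
  a chromosome absent from the annotation.

Matching is strand-aware by default; a strand-agnostic fallback exists
because junction dialects from different aligners disagree on strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .data_model import DataModelError, JunctionRecord, JunctionSet

EXON_SKIPPING = "exon_skipping"
NOVEL_EXON = "novel_exon_or_site"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class NovelJunctionCall:
    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    total_reads: int
    n_samples_detected: int
    classification: str

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


def known_intron_set(annotation: pd.DataFrame) -> set[tuple[str, int, int, str]]:
    """Every gap between consecutive exons, as (chrom, start, end, strand)."""
    out: set[tuple[str, int, int, str]] = set()
    for tid, row in annotation.iterrows():
        exons = row["exons"]
        if len(exons) < 2:
            continue
        prev_end = None
        for s, e in exons:
            if prev_end is not None:
                if s <= prev_end:
                    raise DataModelError(f"transcript {tid}: unordered exons")
                out.add((row["chrom"], prev_end, s, row["strand"]))
            prev_end = e
    return out


class _AnnotationIndex:
    """Exon boundaries and exon intervals grouped by (chrom, strand)."""

    def __init__(self, annotation: pd.DataFrame):
        self.ends = defaultdict(set)       # donor-side boundaries (exon ends)
        self.starts = defaultdict(set)     # acceptor-side boundaries (exon starts)
        self.exons = defaultdict(list)
        self.chroms = set()
        for _, row in annotation.iterrows():
            key = (row["chrom"], row["strand"])
            self.chroms.add(row["chrom"])
            for s, e in row["exons"]:
                self.starts[key].add(s)
                self.ends[key].add(e)
                self.exons[key].append((s, e))

    def keys_for(self, chrom: str, strand: str, strand_agnostic: bool):
        if strand_agnostic:
            return [(chrom, "+"), (chrom, "-")]
        return [(chrom, strand)]


def classify_event(
    call,
    annotation: pd.DataFrame | _AnnotationIndex,
    strand_agnostic: bool = False,
) -> str:
    """Classify one junction against the annotation (see module docstring)."""
    idx = annotation if isinstance(annotation, _AnnotationIndex) else _AnnotationIndex(annotation)
    if call.chrom not in idx.chroms:
        return UNRESOLVED

    keys = idx.keys_for(call.chrom, call.strand, strand_agnostic)
    donor_hit = any(call.intron_start in idx.ends[k] for k in keys)
    acceptor_hit = any(call.intron_end in idx.starts[k] for k in keys)

    if donor_hit and acceptor_hit:
        inside = any(
            s > call.intron_start and e < call.intron_end
            for k in keys
            for s, e in idx.exons[k]
        )
        return EXON_SKIPPING if inside else UNRESOLVED
    return NOVEL_EXON


def find_novel_junctions(
    records: JunctionSet | list[JunctionRecord],
    known_set: set[tuple[str, int, int, str]],
    annotation: pd.DataFrame | None = None,
    min_reads: int = 1,
    strand_agnostic: bool = False,
) -> list[NovelJunctionCall]:
    """Aggregate, drop known introns, rank by support, classify.

    Reads are summed per junction across samples before ranking (the
    per-sample detection count is kept for curation filters). Sorted by
    total reads descending, ties by (chrom, start). ``min_reads``
    defaults to 1; for manual curation a floor of ≥5 reads is a sensible
    recommendation.
    """
    agg: dict[tuple, list[int]] = {}
    for rec in records:
        if rec.key in known_set:
            continue
        tot = agg.setdefault(rec.key, [0, 0])
        tot[0] += rec.read_count
        tot[1] += 1 if rec.read_count > 0 else 0

    idx = _AnnotationIndex(annotation) if annotation is not None else None
    calls = []
    for (chrom, start, end, strand), (total, n_det) in agg.items():
        if total < min_reads:
            continue
        stub = JunctionRecord(chrom=chrom, intron_start=start, intron_end=end,
                              strand=strand, read_count=total, sample_id="pooled")
        cls = classify_event(stub, idx, strand_agnostic) if idx is not None else UNRESOLVED
        calls.append(
            NovelJunctionCall(
                chrom=chrom, intron_start=start, intron_end=end, strand=strand,
                total_reads=total, n_samples_detected=n_det, classification=cls,
            )
        )
    calls.sort(key=lambda c: (-c.total_reads, c.chrom, c.intron_start))
    return calls


def calls_to_frame(calls: list[NovelJunctionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(chrom=c.chrom, intron_start=c.intron_start, intron_end=c.intron_end,
                 strand=c.strand, total_reads=c.total_reads,
                 n_samples_detected=c.n_samples_detected, classification=c.classification)
            for c in calls
        ]
    )
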