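"""Transcript and gene models for the annotation panel.

At the transcript level (the default) every annotated isoform overlapping
the region is drawn, colored by its gene.  At the "gene" level each gene is
collapsed into a single meta-transcript containing the union of all exons
across its isoforms, which simplifies dense loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import AnnotationDatabase, ClipViewError, GenomicRegion

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered disjoint exons plus a display row."""

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: list[Interval]
    row: int = 0

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ClipViewError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def label(self) -> str:
        return self.transcript_id


@dataclass
class GeneModel:
    """A collapsed meta-transcript: the exon union of all of a gene's isoforms."""

    gene_id: str
    gene_name: str
    strand: str
    meta_exons: list[Interval]
    row: int = 0

    @property
    def exons(self) -> list[Interval]:
        return self.meta_exons

    @property
    def start(self) -> int:
        return self.meta_exons[0][0]

    @property
    def end(self) -> int:
        return self.meta_exons[-1][1]

    @property
    def transcript_id(self) -> str:  # uniform drawing interface
        return self.gene_id

    @property
    def label(self) -> str:
        return self.gene_name or self.gene_id


def transcripts_in_region(db: AnnotationDatabase,
                          region: GenomicRegion) -> list[TranscriptModel]:
    """All transcripts whose span overlaps the region by at least 1 nt.

    A transcript overlapping only through an intron is still returned — the
    span, not the exons, decides membership.  Exons keep their full genomic
    coordinates; clipping to the window happens at draw time.
    """
    models = []
    for t in db.transcripts_overlapping(region):
        exons = db.exons_of(t.id)
        if not exons:
            continue
        models.append(
            TranscriptModel(
                transcript_id=t.attributes.get("transcript_id", [t.id])[0],
                gene_id=t.attributes.get("gene_id", [""])[0],
                gene_name=t.attributes.get("gene_name", [""])[0],
                strand=t.strand,
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.start, m.transcript_id))
    return models


def union_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals into a sorted disjoint set."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def collapse_to_metagene(transcripts: Sequence[TranscriptModel]) -> GeneModel:
    """Collapse one gene's isoforms into a meta-transcript of all its exons."""
    if not transcripts:
        raise ClipViewError("cannot collapse an empty transcript set")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ClipViewError(
            f"collapse_to_metagene got transcripts from several genes: "
            f"{sorted(gene_ids)}"
        )
    first = transcripts[0]
    exons = [iv for t in transcripts for iv in t.exons]
    return GeneModel(
        gene_id=first.gene_id,
        gene_name=first.gene_name,
        strand=first.strand,
        meta_exons=union_intervals(exons),
    )


def collapse_by_gene(transcripts: Sequence[TranscriptModel]) -> list[GeneModel]:
    """One meta-transcript per gene, ordered deterministically by gene_id."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [collapse_to_metagene(by_gene[g]) for g in sorted(by_gene)]


def layout_transcripts(models: Sequence, padding: int = 50) -> list:
    """Assign non-colliding display rows with a greedy first-fit sweep.

    Models are sorted by start; each takes the lowest row whose previous
    occupant ends at least ``padding`` nt before it starts.  Deterministic
    for a fixed input, and same-row models never overlap horizontally.
    """
    ordered = sorted(models, key=lambda m: (m.start, m.end, m.transcript_id))
    row_ends: list[int] = []
    for m in ordered:
        for row, last_end in enumerate(row_ends):
            if m.start >= last_end + padding:
                m.row = row
                row_ends[row] = m.end
                break
        else:
            m.row = len(row_ends)
            row_ends.append(m.end)
    return ordered
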