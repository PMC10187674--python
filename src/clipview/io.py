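"""Readers for the genomic file formats consumed by clipview.

Crosslink tracks arrive as BED or BedGraph files in which each record is a
genomic position and the score is the number of crosslink events detected
there.  BedGraph files carry no strand column, so the common iCLIP dialect
encodes strand in the sign of the score: positive scores are plus-strand
crosslinks, negative scores minus-strand.  Auxiliary interval tracks are
BED6/BED9, orthogonal coverage is bigWig, and the reference annotation is a
GENCODE/Ensembl-style GTF indexed into a persistent sqlite database.

Coordinate conventions: BED, BedGraph and bigWig are 0-based half-open and
consumed as such; GTF is 1-based inclusive and converted on load; user
coordinate queries are 1-based inclusive (genome-browser convention) and
converted.  All internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import numpy as np
import pyBigWig

logger = logging.getLogger("clipview")

#: suffix appended to the GTF path for the persistent annotation index
ANNOTATION_CACHE_SUFFIX = ".clipview.sqlite"


class ClipViewError(Exception):
    """Fatal input or configuration error; the CLI reports it and exits 1."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicRegion:
    """A strand-aware query window that every track is clipped to.

    ``start``/``end`` are 0-based half-open.  ``strand`` is '+', '-' or '.'
    (unstranded, used only for raw coordinate queries without a strand).
    ``label`` is the plot title text.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ClipViewError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ClipViewError(f"invalid strand {self.strand!r}")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.chrom}:{self.start + 1}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrosslinkSite:
    """A single-nucleotide crosslink position with a non-negative count."""

    chrom: str
    pos: int
    strand: str
    count: float


@dataclass
class CrosslinkLibrary:
    """One experiment's crosslink sites plus its whole-file library size.

    ``library_size`` is the total crosslink count summed over the entire
    file — every chromosome and both strands, not just a viewed region —
    because library-size normalization must reflect sequencing depth.
    """

    name: str
    sites: list[CrosslinkSite]
    library_size: float
    source_path: Optional[str] = None


@dataclass
class AuxiliaryFeature:
    """An interval from an auxiliary BED track (peaks, repeats, ...)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."
    color: Optional[str] = None  # hex color, set only from BED9 itemRgb


@dataclass
class CoverageProfile:
    """Per-position signal from a bigWig, plotted without further processing."""

    name: str
    values: np.ndarray
    group: Optional[str] = None


# ---------------------------------------------------------------------------
# Crosslink tracks (BED / BedGraph)
# ---------------------------------------------------------------------------


def _parse_lines(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_crosslinks(path: str, name: Optional[str] = None) -> CrosslinkLibrary:
    """Read a crosslink track from BED or BedGraph into a CrosslinkLibrary.

    BedGraph (4 columns): the sign of the score sets the strand and its
    magnitude the count; intervals wider than one nucleotide are expanded to
    one site per covered base, each carrying the full per-position score
    (BedGraph semantics: the value applies to every base of the interval).
    BED6+: column 6 sets the strand and column 5 the count.  BED5 without a
    strand column is treated as plus-strand with a warning.  Duplicate
    (position, strand) records are summed with a warning.
    """
    if not os.path.exists(path):
        raise ClipViewError(f"crosslink file not found: {path}")
    if name is None:
        name = track_name_from_path(path)

    counts: dict[tuple[str, int, str], float] = {}
    duplicates = 0
    warned_unstranded = False
    total = 0.0

    for lineno, fields in _parse_lines(path):
        try:
            chrom = fields[0]
            start = int(fields[1])
            end = int(fields[2])
            if len(fields) == 4:
                # BedGraph: signed score encodes strand
                score = float(fields[3])
                strand = "-" if score < 0 else "+"
                count = abs(score)
            elif len(fields) >= 6:
                count = abs(float(fields[4]))
                strand = fields[5]
                if strand not in {"+", "-"}:
                    raise ValueError(f"invalid strand {strand!r}")
            elif len(fields) == 5:
                count = abs(float(fields[4]))
                strand = "+"
                if not warned_unstranded:
                    logger.warning(
                        "%s: no strand column; treating all records as + strand",
                        path,
                    )
                    warned_unstranded = True
            else:
                raise ValueError(f"expected 4-9 columns, got {len(fields)}")
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval [{start}, {end})")
        except (ValueError, IndexError) as exc:
            raise ClipViewError(f"{path}: malformed line {lineno}: {exc}") from exc

        for pos in range(start, end):
            key = (chrom, pos, strand)
            if key in counts:
                duplicates += 1
                counts[key] += count
            else:
                counts[key] = count
            total += count

    if duplicates:
        logger.warning(
            "%s: %d duplicate position records; counts were summed", path, duplicates
        )

    sites = [
        CrosslinkSite(chrom, pos, strand, c)
        for (chrom, pos, strand), c in sorted(counts.items())
    ]
    logger.info("%s: library size %g crosslinks (%d sites)", name, total, len(sites))
    return CrosslinkLibrary(name=name, sites=sites, library_size=total,
                            source_path=str(path))


def write_crosslinks_bedgraph(lib: CrosslinkLibrary, path: str) -> None:
    """Write a library as a signed BedGraph (iCLIP dialect).

    Minus-strand counts are written with negative scores, so reading the
    file back with :func:`read_crosslinks` reproduces the library exactly.
    """
    with open(path, "w") as fh:
        for s in sorted(lib.sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            score = -s.count if s.strand == "-" else s.count
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{score:g}\n")


def track_name_from_path(path: str) -> str:
    """Experiment label derived from the file basename, extension stripped."""
    stem = Path(path).name
    for ext in (".gz", ".bedgraph", ".bedGraph", ".bg", ".bed", ".bw", ".bigwig",
                ".bigWig"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    return stem


# ---------------------------------------------------------------------------
# Auxiliary tracks (BED6 / BED9)
# ---------------------------------------------------------------------------


def _rgb_to_hex(item_rgb: str) -> str:
    parts = item_rgb.split(",")
    if len(parts) != 3:
        raise ValueError(f"itemRgb {item_rgb!r} is not 'r,g,b'")
    r, g, b = (int(p) for p in parts)
    return f"#{r:02x}{g:02x}{b:02x}"


def read_auxiliary(path: str) -> list[AuxiliaryFeature]:
    """Read an auxiliary BED6/BED9 interval track.

    BED9 records carry their itemRgb into the feature color; BED6 features
    are left uncolored and take the track default at draw time.
    """
    if not os.path.exists(path):
        raise ClipViewError(f"auxiliary file not found: {path}")
    features = []
    for lineno, fields in _parse_lines(path):
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            color = _rgb_to_hex(fields[8]) if len(fields) >= 9 else None
            if end <= start:
                raise ValueError(f"invalid interval [{start}, {end})")
        except (ValueError, IndexError) as exc:
            raise ClipViewError(f"{path}: malformed line {lineno}: {exc}") from exc
        features.append(AuxiliaryFeature(chrom, start, end, name, strand, color))
    return features


# ---------------------------------------------------------------------------
# Coverage tracks (bigWig)
# ---------------------------------------------------------------------------


def read_coverage(path: str, region: GenomicRegion,
                  name: Optional[str] = None) -> CoverageProfile:
    """Read dense per-position coverage over the region from a bigWig.

    Values are taken as stored — no normalization or smoothing is applied.
    Missing intervals read as 0.  A region chromosome absent from the file
    yields an all-zero profile and a prominent warning (chromosome-name
    dialects such as 'chr1' vs '1' are never aliased automatically).
    """
    if name is None:
        name = track_name_from_path(path)
    try:
        bw = pyBigWig.open(path)
    except RuntimeError as exc:
        raise ClipViewError(f"{path}: not a readable bigWig: {exc}") from exc
    if bw is None or not bw.isBigWig():
        raise ClipViewError(f"{path}: not a bigWig file")
    try:
        chroms = bw.chroms()
        values = np.zeros(len(region), dtype=float)
        if region.chrom not in chroms:
            logger.warning(
                "%s: chromosome %r not in bigWig (has: %s); returning zeros — "
                "check chromosome-name spelling ('chr1' vs '1')",
                path, region.chrom, ", ".join(sorted(chroms)[:5]),
            )
            return CoverageProfile(name=name, values=values)
        chrom_len = chroms[region.chrom]
        lo = max(0, region.start)
        hi = min(region.end, chrom_len)
        if lo < hi:
            vals = np.array(bw.values(region.chrom, lo, hi), dtype=float)
            vals[np.isnan(vals)] = 0.0
            values[lo - region.start: hi - region.start] = vals
        return CoverageProfile(name=name, values=values)
    finally:
        bw.close()


# ---------------------------------------------------------------------------
# Annotation (GTF -> persistent sqlite index)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationDatabase:
    """A queryable annotation index built from a GTF.

    Wraps a gffutils sqlite database persisted next to the GTF so repeat
    runs skip the parse step.  All coordinates returned by query helpers
    are converted to the internal 0-based half-open convention.
    """

    source_path: str
    cache_path: str
    db: gffutils.FeatureDB = field(repr=False)

    # -- summary -----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.db.count_features_of_type("gene")

    @property
    def n_transcripts(self) -> int:
        return self.db.count_features_of_type("transcript")

    # -- gene lookup -------------------------------------------------------
    def _gene_attr(self, feature, key: str) -> Optional[str]:
        vals = feature.attributes.get(key)
        return vals[0] if vals else None

    def find_gene(self, query: str):
        """Return the unique gene feature whose gene_id or gene_name matches.

        Raises on no match or on an ambiguous gene name shared by several
        gene ids.
        """
        try:
            feature = self.db[query]
            if feature.featuretype == "gene":
                return feature
        except gffutils.FeatureNotFoundError:
            pass
        matches = [
            g for g in self.db.features_of_type("gene")
            if self._gene_attr(g, "gene_name") == query
            or self._gene_attr(g, "gene_id") == query
        ]
        if not matches:
            raise ClipViewError(
                f"gene {query!r} not found in annotation {self.source_path}"
            )
        if len(matches) > 1:
            ids = ", ".join(self._gene_attr(g, "gene_id") or g.id for g in matches)
            raise ClipViewError(
                f"gene name {query!r} is ambiguous in {self.source_path}; "
                f"candidate gene ids: {ids}"
            )
        return matches[0]

    def transcripts_overlapping(self, region: GenomicRegion):
        """GTF transcript features whose span overlaps the region by >= 1 nt."""
        return list(
            self.db.region(
                region=(region.chrom, region.start + 1, region.end),
                featuretype="transcript",
            )
        )

    def exons_of(self, transcript_id: str) -> list[tuple[int, int]]:
        """Ordered exon intervals of a transcript, 0-based half-open."""
        return [
            (e.start - 1, e.end)
            for e in self.db.children(
                transcript_id, featuretype="exon", order_by="start"
            )
        ]


def load_annotation(gtf_path: str,
                    cache_path: Optional[str] = None) -> AnnotationDatabase:
    """Load a GTF annotation, building or reusing a persistent sqlite index.

    The first run parses the GTF and saves the index next to it (or at
    ``cache_path``); later runs on the same, unmodified GTF reuse the index
    and skip parsing.  A cache older than the GTF is rebuilt with a notice.
    """
    if not os.path.exists(gtf_path):
        raise ClipViewError(f"annotation GTF not found: {gtf_path}")
    if cache_path is None:
        cache_path = str(gtf_path) + ANNOTATION_CACHE_SUFFIX

    rebuild = True
    if os.path.exists(cache_path):
        if os.path.getmtime(gtf_path) > os.path.getmtime(cache_path):
            logger.info("annotation cache %s is older than the GTF; rebuilding",
                        cache_path)
        else:
            rebuild = False

    if rebuild:
        logger.info("building annotation database from %s (first run on this GTF)",
                    gtf_path)
        try:
            db = gffutils.create_db(
                str(gtf_path),
                dbfn=cache_path,
                force=True,
                keep_order=True,
                disable_infer_genes=True,
                disable_infer_transcripts=True,
                merge_strategy="create_unique",
            )
        except Exception as exc:  # gffutils raises bare ValueError/sqlite errors
            raise ClipViewError(f"failed to parse GTF {gtf_path}: {exc}") from exc
        _validate_gtf_attributes(db, gtf_path)
    else:
        logger.info("annotation cache hit: reusing %s (GTF parse skipped)",
                    cache_path)
        db = gffutils.FeatureDB(cache_path)

    return AnnotationDatabase(source_path=str(gtf_path), cache_path=cache_path, db=db)


def _validate_gtf_attributes(db: gffutils.FeatureDB, gtf_path: str) -> None:
    for g in db.features_of_type("gene"):
        if "gene_id" not in g.attributes:
            raise ClipViewError(
                f"{gtf_path}: gene feature missing gene_id attribute: {g}"
            )
    for t in db.features_of_type("transcript"):
        if "transcript_id" not in t.attributes:
            raise ClipViewError(
                f"{gtf_path}: transcript feature missing transcript_id: {t}"
            )


# ---------------------------------------------------------------------------
# Region resolution
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)[-:](?P<end>[\d,]+)"
                       r"(?::(?P<strand>[+-]))?$")


def resolve_region(db: Optional[AnnotationDatabase], query: str) -> GenomicRegion:
    """Resolve a region query — coordinates, gene name, or gene id.

    Coordinate queries ('chrom:start-end' or 'chrom:start:end:strand') are
    1-based inclusive, as typed into a genome browser, and converted to the
    internal 0-based half-open convention; they are unstranded unless a
    strand suffix is given.  Gene queries return the gene's full span and
    strand, with the gene symbol as the plot label.
    """
    m = _COORD_RE.match(query.strip())
    if m:
        start = int(m.group("start").replace(",", "")) - 1
        end = int(m.group("end").replace(",", ""))
        if start < 0 or start >= end:
            raise ClipViewError(f"invalid coordinate region {query!r}: start >= end")
        return GenomicRegion(
            chrom=m.group("chrom"), start=start, end=end,
            strand=m.group("strand") or ".", label=query.strip(),
        )
    if db is None:
        raise ClipViewError(
            f"region {query!r} is not a coordinate string and no annotation "
            "is loaded to resolve it as a gene"
        )
    gene = db.find_gene(query.strip())
    name = gene.attributes.get("gene_name", [None])[0] or query.strip()
    return GenomicRegion(
        chrom=gene.seqid, start=gene.start - 1, end=gene.end,
        strand=gene.strand if gene.strand in "+-" else ".", label=name,
    )
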