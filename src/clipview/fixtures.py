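"""Synthetic test dataset generator.

Emits a small, fully synthetic dataset in every format the tool consumes —
signed BedGraph crosslink tracks, an auxiliary BED9 feature, bigWig coverage
tracks and a GTF — so the whole pipeline can be exercised without any
downloads.  The dataset emulates a classic RBP-competition scene: two
replicate tracks of "RBP-A" share a binding peak over an alternative exon,
two "RBP-B" replicates peak at a shifted position, and knockdown coverage
groups show an expression step over the alternative exon relative to
control.  All files are synthetic stand-ins; none derive from real data.

Crosslink counts are drawn per position as Poisson samples around a
Gaussian-bump mean (background + peak), which makes replicate concordance
after normalization and smoothing a stable, testable property.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pyBigWig

from .io import ClipViewError


@dataclass
class PeakSpec:
    """A Gaussian crosslink peak: mean count = height * exp(-d^2 / 2 sd^2)."""

    center: int
    sd: float
    height: float


@dataclass
class FixtureSpec:
    """Parameters of the synthetic dataset; same seed => identical bytes."""

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000
    # gene body over which crosslink background is laid down (0-based)
    gene_start: int = 1_100
    gene_end: int = 3_100
    # the shared binding site (under the auxiliary feature / highlight box)
    shared_peak: PeakSpec = field(default_factory=lambda: PeakSpec(1_800, 25.0, 30.0))
    # the condition-dependent, shifted binding site of the second RBP
    shifted_peak: PeakSpec = field(default_factory=lambda: PeakSpec(2_050, 25.0, 20.0))
    n_replicates: int = 2
    background_rate: float = 0.2      # crosslinks/nt over the gene body
    minus_strand_rate: float = 0.05   # sparse antisense signal (sign convention)
    # off-region signal so library size != region total
    offsite_span: tuple[int, int] = (5_000, 5_500)
    offsite_rate: float = 0.8
    # coverage model (arbitrary bigWig units)
    exon_coverage: float = 5.0
    knockdown_step: float = 25.0      # extra coverage over the alt exon in KD
    # alternative exon under the shared peak (0-based half-open)
    alt_exon: tuple[int, int] = (1_770, 1_830)


# transcript skeleton of the multi-isoform gene (0-based half-open exons)
def _gene_models(spec: FixtureSpec):
    constitutive = [(1_100, 1_300), (2_400, 2_600), (2_900, 3_100)]
    with_alt = sorted(constitutive + [spec.alt_exon])
    return {
        "FIXG000001": {
            "gene_name": "CD55-like",
            "strand": "+",
            "transcripts": {
                "FIXT000001": constitutive,
                "FIXT000002": with_alt,
            },
        },
        "FIXG000002": {
            "gene_name": "NBR-like",
            "strand": "-",
            "transcripts": {
                "FIXT000003": [(4_000, 4_200), (4_600, 4_800)],
            },
        },
    }


def _write_gtf(spec: FixtureSpec, path: Path) -> None:
    lines = []
    for gene_id, g in _gene_models(spec).items():
        exons = [iv for t in g["transcripts"].values() for iv in t]
        g_start, g_end = min(s for s, _ in exons), max(e for _, e in exons)
        attrs = f'gene_id "{gene_id}"; gene_name "{g["gene_name"]}";'
        lines.append(
            f"{spec.chrom}\tfixture\tgene\t{g_start + 1}\t{g_end}\t.\t"
            f"{g['strand']}\t.\t{attrs}"
        )
        for tx_id, tx_exons in g["transcripts"].items():
            t_attrs = f'{attrs} transcript_id "{tx_id}";'
            t_start = min(s for s, _ in tx_exons)
            t_end = max(e for _, e in tx_exons)
            lines.append(
                f"{spec.chrom}\tfixture\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                f"{g['strand']}\t.\t{t_attrs}"
            )
            for i, (s, e) in enumerate(sorted(tx_exons), start=1):
                lines.append(
                    f"{spec.chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t"
                    f"{g['strand']}\t.\t{t_attrs} exon_number {i};"
                )
    path.write_text("\n".join(lines) + "\n")


def _peak_means(spec: FixtureSpec, peak: PeakSpec) -> np.ndarray:
    pos = np.arange(spec.gene_start, spec.gene_end)
    mu = np.full(pos.size, spec.background_rate)
    mu += peak.height * np.exp(-0.5 * ((pos - peak.center) / peak.sd) ** 2)
    return mu


def _write_xlink_bedgraph(spec: FixtureSpec, peak: PeakSpec, path: Path,
                          rng: np.random.Generator) -> None:
    records: list[tuple[int, float]] = []
    plus = rng.poisson(_peak_means(spec, peak))
    for offset, c in enumerate(plus):
        if c > 0:
            records.append((spec.gene_start + offset, float(c)))
    minus = rng.poisson(spec.minus_strand_rate, spec.gene_end - spec.gene_start)
    for offset, c in enumerate(minus):
        if c > 0:
            records.append((spec.gene_start + offset, -float(c)))
    off_s, off_e = spec.offsite_span
    offsite = rng.poisson(spec.offsite_rate, off_e - off_s)
    for offset, c in enumerate(offsite):
        if c > 0:
            records.append((off_s + offset, float(c)))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for pos, score in records:
            fh.write(f"{spec.chrom}\t{pos}\t{pos + 1}\t{score:g}\n")


def _write_aux_bed9(spec: FixtureSpec, path: Path) -> None:
    s, e = spec.alt_exon
    path.write_text(
        f"{spec.chrom}\t{s}\t{e}\tshared_binding_site\t0\t+\t{s}\t{e}\t255,0,0\n"
    )


def _write_coverage_bigwig(spec: FixtureSpec, path: Path, knockdown: bool,
                           scale: float) -> None:
    gene = _gene_models(spec)["FIXG000001"]
    exons = gene["transcripts"]["FIXT000001"]
    entries = [(s, e, spec.exon_coverage * scale) for s, e in exons]
    if knockdown:
        s, e = spec.alt_exon
        entries.append((s, e, (spec.exon_coverage + spec.knockdown_step) * scale))
    entries.sort()
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(spec.chrom, spec.chrom_length)])
        bw.addEntries(
            [spec.chrom] * len(entries),
            [s for s, _, _ in entries],
            ends=[e for _, e, _ in entries],
            values=[float(v) for _, _, v in entries],
        )
    finally:
        bw.close()


def make_fixture(spec: FixtureSpec, out_dir: str) -> dict:
    """Write the full synthetic dataset; returns a manifest of files by flag.

    The manifest maps CLI flags to the generated paths and suggested values
    (groups, region, highlight) and is also written to ``manifest.tsv`` in
    ``out_dir``.  Generation is fully deterministic in ``spec.seed``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ClipViewError(f"fixture output dir not writable: {out}: {exc}")

    manifest: dict = {
        "xlinks": [], "groups": [], "auxiliary": [], "coverage": [],
        "coverage_groups": [],
    }

    track_idx = 0
    for rbp, peak in (("RBP-A", spec.shared_peak), ("RBP-B", spec.shifted_peak)):
        for rep in range(1, spec.n_replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, track_idx]))
            path = out / f"{rbp}_rep{rep}.bedgraph"
            _write_xlink_bedgraph(spec, peak, path, rng)
            manifest["xlinks"].append(str(path))
            manifest["groups"].append(rbp)
            track_idx += 1

    aux_path = out / "binding_sites.bed"
    _write_aux_bed9(spec, aux_path)
    manifest["auxiliary"].append(str(aux_path))

    cov_idx = 0
    for group, knockdown in (("CTRL", False), ("KD1", True), ("KD2", True)):
        for rep in range(1, spec.n_replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 1000 + cov_idx]))
            scale = float(rng.uniform(0.9, 1.1))
            path = out / f"rnaseq_{group}_rep{rep}.bw"
            _write_coverage_bigwig(spec, path, knockdown, scale)
            manifest["coverage"].append(str(path))
            manifest["coverage_groups"].append(group)
            cov_idx += 1

    gtf_path = out / "annotation.gtf"
    _write_gtf(spec, gtf_path)
    manifest["gtf"] = str(gtf_path)
    manifest["region"] = "CD55-like"
    s, e = spec.alt_exon
    manifest["highlight"] = f"{s + 1}:{e}"  # 1-based inclusive, CLI syntax

    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("file\tflag\tgroup\n")
        for p, g in zip(manifest["xlinks"], manifest["groups"]):
            fh.write(f"{os.path.basename(p)}\t--xlinks\t{g}\n")
        fh.write(f"{os.path.basename(aux_path)}\t--auxiliary\t.\n")
        for p, g in zip(manifest["coverage"], manifest["coverage_groups"]):
            fh.write(f"{os.path.basename(p)}\t--coverage\t{g}\n")
        fh.write(f"{os.path.basename(gtf_path)}\t--gtf\t.\n")
    manifest["manifest"] = str(manifest_path)
    return manifest
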