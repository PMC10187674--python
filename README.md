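# clipview

Comparative visualization of nucleotide-resolution CLIP data from the
command line.

CLIP technologies (iCLIP, eCLIP, PAR-CLIP, ...) map the exact nucleotides at
which an RNA-binding protein (RBP) crosslinks to RNA. Comparing such tracks
across experiments, conditions or RBPs in a genome browser is misleading for
two reasons: libraries differ in sequencing depth, and single-nucleotide
counts are too noisy to compare by eye. `clipview` reads crosslink tracks
(BED/BedGraph, with the common iCLIP convention that the sign of a BedGraph
score encodes the strand), normalizes and smooths them, and composes a
publication-quality multi-panel figure for one genomic region of interest —
optionally alongside auxiliary interval tracks (BED6/BED9), orthogonal
coverage tracks (bigWig, drawn as stored), and a transcript annotation panel
built from a GTF.

## Normalization and smoothing

For a track with per-position counts *x<sub>i</sub>* and whole-file total
*N* (computed over the entire file, not just the viewed region), the
available normalizations are:

- **libsize** (default): crosslinks per million, *x<sub>i</sub>* / *N* x 10^6;
- **maxpeak**: *x<sub>i</sub>* / max<sub>region</sub>(*x*), pooled over each
  group of tracks, so each group's signal spans [0, 1];
- **libsize_maxpeak**: library-size normalization first, then max-peak —
  recommended when relative differences between groups must be read off the
  axis, since raw max-peak scaling conflates signal with library depth;
- **custom**: division by user-supplied per-experiment size factors;
- **none**: raw counts.

After normalization the signal is smoothed with either a centered rolling
mean (default, window 100 nt) or a Gaussian kernel regression
(Nadaraya–Watson, sigma = window/4, truncated at ±window/2). The y-axis
label follows the chosen normalization automatically.

## Worked example

The package ships a generator that writes a small synthetic dataset in every
consumed format — four crosslink BedGraphs (two replicates each of "RBP-A",
which binds a shared site over an alternative exon, and "RBP-B", which binds
a shifted site), a BED9 feature marking the shared site, six bigWig coverage
tracks in three groups (CTRL and two knockdowns with an expression step over
the alternative exon), and a two-gene, three-isoform GTF:

```python
from clipview import FixtureSpec, make_fixture
make_fixture(FixtureSpec(seed=1), "demo")
```

One command then draws the full four-panel figure:

```sh
cd demo
clipview \
  -x RBP-A_rep1.bedgraph,RBP-A_rep2.bedgraph,RBP-B_rep1.bedgraph,RBP-B_rep2.bedgraph \
  --groups RBP-A,RBP-A,RBP-B,RBP-B \
  -a binding_sites.bed \
  -c rnaseq_CTRL_rep1.bw,rnaseq_CTRL_rep2.bw,rnaseq_KD1_rep1.bw,rnaseq_KD1_rep2.bw,rnaseq_KD2_rep1.bw,rnaseq_KD2_rep2.bw \
  --coverage_groups CTRL,CTRL,KD1,KD1,KD2,KD2 \
  -g annotation.gtf -r CD55-like --highlight 1771:1830 \
  -n libsize -s rollmean -w 50 -o cd55like.png
```

which logs:

```
INFO: normalization: libsize; smoothing: rollmean (window 50 nt)
INFO: building annotation database from annotation.gtf (first run on this GTF)
INFO: region resolved: chr1:1101-3100 (+) 'CD55-like'
INFO: RBP-A_rep1: library size 2759 crosslinks (830 sites)
INFO: RBP-A_rep2: library size 2879 crosslinks (902 sites)
INFO: RBP-B_rep1: library size 2170 crosslinks (882 sites)
INFO: RBP-B_rep2: library size 2067 crosslinks (856 sites)
INFO: rollmean window adjusted to 51 so it can be centered
...
INFO: wrote cd55like.png
```

The library sizes are each track's whole-file crosslink totals — the
denominators of the crosslinks-per-million calculation — and the region line
shows how the gene query `CD55-like` resolved against the annotation (the
gene symbol becomes the plot title). In the output figure the two RBP-A
replicates peak at ~9,000 crosslinks per million inside the gray highlight
box over the alternative exon, the RBP-B replicates peak ~250 nt downstream,
the coverage panel shows the knockdown-specific expression step over the
same exon, and the annotation panel shows that exactly one of the two
CD55-like isoforms contains it. A second run on the same GTF logs
`annotation cache hit` and skips the parse step.

Region queries may also be coordinates (`-r chr1:1101-3100`, 1-based,
optionally `:strand`). `--help` lists every flag with its default; other
frequently used flags are `--scale_y` (independent y-scale per group),
`--annotation gene` (collapsed meta-transcripts), `--ratios a:b:c:d` and
`--size "W x H"`.

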