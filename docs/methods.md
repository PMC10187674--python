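# Methods

## Signal model

A crosslink track is a set of single-nucleotide events: each record of a BED
or BedGraph file contributes a position, a strand, and a non-negative count
of crosslinks detected there. BedGraph carries no strand column, so the
widely used iCLIP dialect is assumed: the sign of the score encodes the
strand (+ score = plus strand) and its magnitude the count. BedGraph
intervals wider than one nucleotide are expanded to one site per covered
base, each carrying the full per-position score — BedGraph semantics state
the value applies to every base of the interval, and expansion preserves the
per-nucleotide resolution the rest of the pipeline assumes. Records at a
duplicated (position, strand) are summed with a warning; zero-count records
are kept (they contribute nothing). BED input uses column 5 as the count and
column 6 as the strand; a 5-column BED without a strand column is treated as
plus-strand with a warning.

The library size of a track is the sum of counts over the *entire file* —
all chromosomes, both strands — never a region-restricted total, because it
stands in for sequencing depth.

## Coordinate conventions

BED, BedGraph and bigWig are consumed as 0-based half-open. GTF is 1-based
inclusive and converted on load. User-facing coordinates (the `--region`
query and `--highlight` bounds) are 1-based inclusive, the genome-browser
convention, and converted at the boundary. All internal arithmetic is
0-based half-open; for every parsed interval, internal `end − start` equals
the source line's width. Chromosome-name dialects ("chr1" vs "1") are never
aliased: a mismatch between the region and a track yields an empty profile
plus a warning naming both spellings, on the grounds that silent aliasing
hides genuine input errors.

## Normalization

Five modes, selected with `--normalization`:

| mode | definition | y-axis label |
|---|---|---|
| `none` | raw counts | Crosslinks |
| `libsize` (default) | x / N × 10⁶, N the whole-file total | Crosslinks per million |
| `maxpeak` | x / max over the region, pooled per group | Fraction of maximum |
| `libsize_maxpeak` | libsize first, then maxpeak | Fraction of maximum |
| `custom` | x / user size factor (one per track) | Crosslinks (custom scaled) |

The max-peak divisor is the single maximum pooled across all tracks of a
group within the viewed region, so grouped replicates share one scale and
each group's maximum is exactly 1; ungrouped tracks are singleton groups.
An all-zero group is left unchanged with a warning rather than dividing by
zero. The composed mode applies library-size normalization strictly before
the max-peak division.

Max-peak normalization alone can mislead: two replicates with similar CPM
signal but different library depths appear to differ two-fold after raw
max-peak scaling. When relative differences between groups are the point,
`libsize_maxpeak` keeps the profile shapes of the CPM view while placing all
groups on a common [0, 1] axis.

## Smoothing

Smoothing runs after normalization (for the linear modes the order is
immaterial mathematically; it is fixed and tested anyway so that the
nonlinear max-peak mode normalizes pre-smoothing values, and so that
documented behavior matches implementation). Two methods:

- **Rolling mean** (default): the window is centered on each position.
  Positions whose window extends past the region edge use the truncated
  window (a partial mean), so the output has a value at every position and
  no length change — a plot needs a value everywhere, and truncated means
  avoid the bias of zero-padding. Even windows are bumped to the next odd
  integer with a notice so "centered" is well defined; a window longer than
  the region is clamped with a warning.
- **Gaussian kernel regression** (Nadaraya–Watson): kernel standard
  deviation `window/4`, truncated at `±window/2`, with edge renormalization
  (weights always sum to 1 over the available positions). The sigma rule is
  a package choice — it makes `--smoothing_window` comparable between the
  two methods, with the Gaussian window covering ±2 sigma.

The default window is 100 nt. Sensible windows depend on the RBP's binding
footprint and the region size; the worked example uses 50 nt over a 2 kb
region. Both smoothers are verified element-wise against independent
double-loop implementations to 1e-9 in the test suite.

Unstranded coordinate regions are handled by extracting each strand
separately and overlaying both profiles per track, minus-strand dashed; a
stranded region (including every gene query) uses only matching-strand
sites.

## Annotation

The GTF is indexed into a sqlite database (via gffutils) stored next to the
GTF with suffix `.clipview.sqlite` (overridable with `--cache`); later runs
reuse it unless the GTF's mtime is newer, in which case the index is rebuilt
with a notice. Gene queries accept a gene_id or gene_name; an ambiguous name
aborts with the candidate ids rather than guessing.

The annotation panel draws, at `transcript` level (default), every isoform
whose *span* overlaps the region — a transcript overlapping only through an
intron is still shown, since its exons provide context at the window edges —
colored by gene with a deterministic palette keyed on sorted gene_id. At
`gene` level each gene collapses to a meta-transcript whose exons are the
interval union of all isoform exons. Stacking uses greedy first-fit: models
sorted by start each take the lowest row free at their start minus a 50 nt
padding gap, which is deterministic and collision-free. Exons are filled
boxes, introns a thin line with strand-direction arrowheads; CDS/UTR are not
distinguished. Models are clipped to the window for drawing, with a small
edge marker when a model continues beyond it. No cap is applied to the
number of isoforms drawn.

## Figure composition

Panels in order: crosslink (always), auxiliary, coverage, annotation; all
share the x-axis in region coordinates and are present only when their
inputs were given (an empty auxiliary file still draws its panel). Default
height ratios are 40:10:25:25, with the annotation share growing by 5 units
per stacked row beyond four; `--ratios` overrides them verbatim and absent
panels always get 0. Default page size is 10 × 8 inches, PNG at 300 dpi.
`--scale_y` splits the crosslink panel into one facet per group, each
autoscaled to its own maximum, preserving order-of-magnitude differences
between groups while exposing peak morphology. Smoothed signal is drawn as
lines; with `--smoothing none` per-nucleotide bars are drawn instead, since
unsmoothed single-nucleotide lines are illegible. The highlight box is a
light gray span behind the data in the crosslink, auxiliary and coverage
panels. Coverage tracks are overlaid lines sharing the group color, never
averaged.

Output format (PDF or PNG) follows the filename extension. Rendering is
pinned to the Agg backend; PDF metadata that varies run-to-run
(CreationDate) is stripped, so identical inputs give byte-identical output
files. The figure is written to a temporary file and moved into place on
success, so a failed run leaves no partial output.

## Synthetic dataset

`clipview.fixtures.make_fixture` writes a fully synthetic dataset that
emulates the structure of a two-RBP competition experiment over an
alternative exon: two replicate tracks per RBP drawn as per-position Poisson
counts around a Gaussian-bump mean (background 0.2 crosslinks/nt over the
2 kb gene body; shared peak at 1,800 with sd 25 nt and height 30; shifted
peak at 2,050 with height 20), plus sparse antisense signal (rate 0.05) to
exercise the sign convention and an off-region block so that library size
and region total differ. Coverage bigWigs place constitutive-exon coverage
of 5 in all groups and add a 25-unit step over the alternative exon in the
knockdown groups, with a ±10% deterministic per-replicate scale. The GTF
holds one plus-strand gene with two isoforms (one containing the alternative
exon) and a second minus-strand gene. Generation is byte-deterministic in
the seed.

These parameters make replicate concordance stable: after CPM and a 50 nt
rolling mean, replicate Pearson correlation exceeds 0.9 by a wide margin.
What the fixtures do *not* emulate: real crosslink-site sequence biases
(e.g. uridine preference), overdispersion beyond Poisson, multi-chromosome
annotations, and realistic transcript complexity — so passing tests
demonstrate the pipeline's arithmetic and plumbing, not robustness to every
property of real CLIP libraries.

## Numerical and degenerate-input choices

- Library size ≤ 0 is fatal only when libsize normalization is requested.
- Max-peak on an all-zero group: unchanged, warning.
- Custom factors must be positive and cover every track, else fatal naming
  the track.
- `--highlight` fully outside the region is fatal; a partial overlap is
  clipped.
- Smoothing window 1 is the identity for both methods.
- Test problem sizes: brute-force smoother comparisons use 100 random
  profiles of length ≤ 500; max-peak range checks use 100 random groups;
  the end-to-end runs use the 2 kb synthetic gene.

## Known limitations

- BAM/CRAM, remote URLs, tabix and liftover are out of scope; inputs are
  local BED/BedGraph/bigWig/GTF only.
- No peak calling and no differential-binding statistics: the processing
  exists to make visual comparisons valid, not to test hypotheses.
- The Gaussian smoother's bandwidth rule is this package's own documented
  choice; other tools' "gaussian" modes may differ numerically.
- Exact byte-identity of rendered files is guaranteed only within one
  matplotlib version on one platform; the figure object model (panel
  geometry, line data) is deterministic regardless.
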