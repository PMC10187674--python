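"""Multi-panel figure assembly.

The figure stacks up to four panels sharing one x-axis in region
coordinates: crosslink signal (always), auxiliary intervals, orthogonal
coverage, and the annotation track.  Tracks are grouped and colored, an
optional gray highlight box is drawn behind the signal panels, and the
result is exported to PDF or PNG according to the output filename
extension.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless, deterministic rendering

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.lines import Line2D
from matplotlib.patches import Patch

from .annotation import layout_transcripts
from .io import AuxiliaryFeature, ClipViewError, CoverageProfile, GenomicRegion, \
    track_name_from_path
from .signal import SignalProfile

logger = logging.getLogger("clipview")

#: fixed ordered palette for automatic group coloring (colorblind-safe-ish)
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

#: default panel height ratios crosslink:auxiliary:coverage:annotation
DEFAULT_RATIOS = (40.0, 10.0, 25.0, 25.0)

HIGHLIGHT_COLOR = "0.85"
SUPPORTED_FORMATS = (".pdf", ".png")


# ---------------------------------------------------------------------------
# Styling
# ---------------------------------------------------------------------------


@dataclass
class GroupStyle:
    """Resolved track names, their groups, and per-group colors."""

    names: list[str]
    group_of: dict[str, str]
    color_of: dict[str, str]

    def group(self, name: str) -> str:
        return self.group_of.get(name, name)

    def color(self, name: str) -> str:
        return self.color_of[self.group(name)]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: list[str] = []
        for n in self.names:
            g = self.group_of[n]
            if g not in seen:
                seen.append(g)
        return seen


def assign_styles(tracks: Sequence[str],
                  groups: Optional[Sequence[str]] = None,
                  colors: Optional[Sequence[str]] = None) -> GroupStyle:
    """Resolve names, groups and colors for a set of tracks.

    Track names are derived from file basenames with the extension stripped.
    Unspecified groups default to the track's own name; colors are assigned
    to groups in first-appearance order from a fixed palette, so re-runs
    with identical inputs give identical styles.
    """
    names = [track_name_from_path(t) for t in tracks]
    if groups is not None and len(groups) != len(names):
        raise ClipViewError(
            f"got {len(groups)} group labels for {len(names)} tracks"
        )
    group_of = {
        n: (groups[i] if groups is not None else n) for i, n in enumerate(names)
    }
    ordered_groups: list[str] = []
    for n in names:
        if group_of[n] not in ordered_groups:
            ordered_groups.append(group_of[n])
    if colors is not None:
        if len(colors) < len(ordered_groups):
            raise ClipViewError(
                f"{len(colors)} colors supplied for {len(ordered_groups)} groups"
            )
        color_of = {g: colors[i] for i, g in enumerate(ordered_groups)}
    else:
        color_of = {
            g: PALETTE[i % len(PALETTE)] for i, g in enumerate(ordered_groups)
        }
    return GroupStyle(names=names, group_of=group_of, color_of=color_of)


# ---------------------------------------------------------------------------
# Figure specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HighlightBox:
    """A shaded sub-interval drawn behind the signal panels (0-based)."""

    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ClipViewError(
                f"highlight start {self.start} must be < end {self.end}"
            )


@dataclass
class FigureSpec:
    """Everything the renderer needs beyond the data itself."""

    region: GenomicRegion
    output: Optional[str] = None
    style: Optional[GroupStyle] = None
    coverage_style: Optional[GroupStyle] = None
    highlight: Optional[HighlightBox] = None
    scale_y: bool = False          # independent y-scale facet per group
    ratios: Optional[tuple[float, float, float, float]] = None
    size: tuple[float, float] = (10.0, 8.0)
    dpi: int = 300
    bars: bool = False             # per-nucleotide bars (unsmoothed display)


def compute_panel_ratios(has_auxiliary: bool, has_coverage: bool,
                         has_annotation: bool,
                         n_annotation_rows: int = 1,
                         user: Optional[Sequence[float]] = None,
                         ) -> tuple[float, float, float, float]:
    """Height ratios (crosslink, auxiliary, coverage, annotation).

    Absent panels get ratio 0.  By default the crosslink panel takes the
    largest share and the annotation share grows with the number of stacked
    transcript rows (5 extra units per row beyond four).  User ratios
    override the defaults entirely for the panels that are present.
    """
    present = (True, has_auxiliary, has_coverage, has_annotation)
    if user is not None:
        if len(user) != 4:
            raise ClipViewError(f"expected 4 panel ratios, got {len(user)}")
        for label, r, p in zip(
            ("crosslink", "auxiliary", "coverage", "annotation"), user, present
        ):
            if p and r <= 0:
                raise ClipViewError(
                    f"panel ratio for the {label} panel must be positive, got {r}"
                )
        return tuple(r if p else 0.0 for r, p in zip(user, present))
    ratios = list(DEFAULT_RATIOS)
    ratios[3] += 5.0 * max(0, n_annotation_rows - 4)
    return tuple(r if p else 0.0 for r, p in zip(ratios, present))


# ---------------------------------------------------------------------------
# Panel renderers
# ---------------------------------------------------------------------------


def _draw_highlight(ax, highlight: Optional[HighlightBox]):
    if highlight is not None:
        ax.axvspan(highlight.start, highlight.end, color=HIGHLIGHT_COLOR, zorder=0)


def _draw_profiles(ax, profiles: Sequence[SignalProfile], style: GroupStyle,
                   bars: bool):
    x0 = None
    for p in profiles:
        color = style.color(p.name)
        x = np.arange(p.values.size)
        if x0 is None:
            x0 = x
        if bars:
            ax.bar(x + 0.5, p.values, width=1.0, color=color, alpha=0.6,
                   linewidth=0, zorder=2)
        else:
            ls = "--" if p.strand == "-" else "-"
            ax.plot(x + 0.5, p.values, color=color, lw=1.0, ls=ls, zorder=2)


def _legend_handles(style: GroupStyle, groups: Sequence[str]):
    return [Line2D([], [], color=style.color_of[g], lw=2, label=g) for g in groups]


def _draw_auxiliary(ax, features: Sequence[AuxiliaryFeature],
                    region: GenomicRegion, default_color: str = "0.4"):
    row = 0
    for f in features:
        if f.chrom != region.chrom or f.end <= region.start or f.start >= region.end:
            continue
        s = max(f.start, region.start) - region.start
        e = min(f.end, region.end) - region.start
        ax.broken_barh([(s, e - s)], (row, 0.8),
                       facecolors=f.color or default_color, zorder=2)
        ax.text(s, row + 0.9, f.name, fontsize=6, va="bottom", clip_on=True)
        row += 1
    ax.set_ylim(-0.2, max(row, 1) + 0.6)
    ax.set_yticks([])


def _gene_palette(models) -> dict[str, str]:
    gene_ids = sorted({m.gene_id for m in models})
    return {g: PALETTE[i % len(PALETTE)] for i, g in enumerate(gene_ids)}


def _draw_annotation(ax, models, region: GenomicRegion):
    models = layout_transcripts(models)
    colors = _gene_palette(models)
    length = len(region)
    for m in models:
        y = m.row * 1.5
        color = colors[m.gene_id]
        s = max(m.start, region.start) - region.start
        e = min(m.end, region.end) - region.start
        if e <= s:
            continue
        # intron backbone with strand arrows
        ax.plot([s, e], [y + 0.4, y + 0.4], color=color, lw=0.8, zorder=1)
        marker = ">" if m.strand == "+" else "<"
        arrow_x = np.linspace(s, e, 5)[1:-1]
        ax.plot(arrow_x, np.full(arrow_x.size, y + 0.4), linestyle="none",
                marker=marker, markersize=3, color=color, zorder=1)
        for ex_s, ex_e in m.exons:
            cs = max(ex_s, region.start) - region.start
            ce = min(ex_e, region.end) - region.start
            if ce > cs:
                ax.broken_barh([(cs, ce - cs)], (y, 0.8), facecolors=color,
                               zorder=2)
        # cut-edge cue when the model extends past the window
        if m.start < region.start:
            ax.plot([0], [y + 0.4], marker="<", color="0.2", markersize=4)
        if m.end > region.end:
            ax.plot([length], [y + 0.4], marker=">", color="0.2", markersize=4)
        ax.text(min(max(s, 0), length * 0.98), y + 0.95, m.label, fontsize=6,
                va="bottom", clip_on=True)
    n_rows = max((m.row for m in models), default=0) + 1
    ax.set_ylim(-0.3, n_rows * 1.5 + 0.5)
    ax.invert_yaxis()
    ax.set_yticks([])
    return models


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def compose_figure(profiles: Sequence[SignalProfile],
                   aux_features: Optional[Sequence[AuxiliaryFeature]],
                   coverage_profiles: Optional[Sequence[CoverageProfile]],
                   annotation_models: Optional[Sequence],
                   spec: FigureSpec):
    """Assemble the multi-panel figure; returns the matplotlib Figure.

    ``aux_features``/``coverage_profiles``/``annotation_models`` of None omit
    the panel; empty sequences draw an empty panel.  When ``spec.output`` is
    set the figure is also written there, in the format implied by the
    extension.
    """
    region = spec.region
    style = spec.style
    if style is None:
        style = assign_styles([p.name for p in profiles],
                              groups=[p.group or p.name for p in profiles])
    cov_style = spec.coverage_style
    if coverage_profiles is not None and cov_style is None:
        cov_style = assign_styles(
            [c.name for c in coverage_profiles],
            groups=[c.group or c.name for c in coverage_profiles])

    has_aux = aux_features is not None
    has_cov = coverage_profiles is not None
    has_annot = annotation_models is not None

    if has_annot and annotation_models:
        annotation_models = layout_transcripts(list(annotation_models))
        n_rows = max(m.row for m in annotation_models) + 1
    else:
        n_rows = 1

    ratios = compute_panel_ratios(has_aux, has_cov, has_annot, n_rows,
                                  user=spec.ratios)

    xlink_groups = style.groups if profiles else []
    n_xlink_axes = max(len(xlink_groups), 1) if spec.scale_y else 1
    heights = [ratios[0] / n_xlink_axes] * n_xlink_axes
    panel_axes: dict[str, int] = {}
    for key, idx in (("auxiliary", 1), ("coverage", 2), ("annotation", 3)):
        if ratios[idx] > 0:
            panel_axes[key] = len(heights)
            heights.append(ratios[idx])

    fig, axes = plt.subplots(
        len(heights), 1, sharex=True, figsize=spec.size,
        gridspec_kw={"height_ratios": heights, "hspace": 0.25}, squeeze=False,
    )
    axes = axes[:, 0]

    hl = None
    if spec.highlight is not None:
        hl = HighlightBox(spec.highlight.start - region.start,
                          spec.highlight.end - region.start)

    # -- crosslink panel(s) -------------------------------------------------
    units = profiles[0].units_label if profiles else ""
    if spec.scale_y and xlink_groups:
        for i, g in enumerate(xlink_groups):
            ax = axes[i]
            _draw_highlight(ax, hl)
            _draw_profiles(ax, [p for p in profiles if style.group(p.name) == g],
                           style, spec.bars)
            ax.set_ylabel(units, fontsize=7)
            ax.text(1.0, 1.0, g, transform=ax.transAxes, ha="right", va="top",
                    fontsize=7, color=style.color_of[g])
        legend_ax = axes[0]
    else:
        ax = axes[0]
        _draw_highlight(ax, hl)
        _draw_profiles(ax, profiles, style, spec.bars)
        ax.set_ylabel(units, fontsize=8)
        legend_ax = ax
    if xlink_groups:
        legend_ax.legend(handles=_legend_handles(style, xlink_groups),
                         loc="upper right", fontsize=6, frameon=False)

    # -- auxiliary panel ----------------------------------------------------
    if "auxiliary" in panel_axes:
        ax = axes[panel_axes["auxiliary"]]
        _draw_highlight(ax, hl)
        _draw_auxiliary(ax, aux_features or [], region)
        ax.set_ylabel("features", fontsize=7)

    # -- coverage panel -----------------------------------------------------
    if "coverage" in panel_axes:
        ax = axes[panel_axes["coverage"]]
        _draw_highlight(ax, hl)
        for c in coverage_profiles or []:
            ax.plot(np.arange(c.values.size) + 0.5, c.values,
                    color=cov_style.color(c.name), lw=0.8, zorder=2)
        if coverage_profiles:
            ax.legend(handles=_legend_handles(cov_style, cov_style.groups),
                      loc="upper right", fontsize=6, frameon=False)
        ax.set_ylabel("coverage", fontsize=7)

    # -- annotation panel ---------------------------------------------------
    if "annotation" in panel_axes:
        ax = axes[panel_axes["annotation"]]
        if annotation_models:
            _draw_annotation(ax, annotation_models, region)
        else:
            ax.set_yticks([])
        ax.set_ylabel("annotation", fontsize=7)

    # -- shared x axis in region coordinates --------------------------------
    for ax in axes:
        ax.set_xlim(0, len(region))
    bottom = axes[-1]
    n_ticks = 5
    tick_pos = np.linspace(0, len(region), n_ticks)
    bottom.set_xticks(tick_pos)
    bottom.set_xticklabels(
        [f"{int(region.start + t):,}" for t in tick_pos], fontsize=7
    )
    bottom.set_xlabel(f"{region.chrom} position", fontsize=8)
    fig.suptitle(region.label)

    if spec.output is not None:
        save_figure(fig, spec.output, dpi=spec.dpi)
    return fig


def save_figure(fig, path: str, dpi: int = 300) -> None:
    """Write the figure as PDF or PNG according to the filename extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_FORMATS:
        raise ClipViewError(
            f"unsupported output extension {ext!r}; "
            f"choose one of {', '.join(SUPPORTED_FORMATS)}"
        )
    if ext == ".pdf":
        # strip volatile metadata so identical runs give identical bytes
        fig.savefig(path, format="pdf",
                    metadata={"CreationDate": None, "Producer": None,
                              "Creator": None})
    else:
        fig.savefig(path, format="png", dpi=dpi)
    logger.debug("rendered figure to %s", path)
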