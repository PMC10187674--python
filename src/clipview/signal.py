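"""Normalization and smoothing of per-position crosslink signal.

Before CLIP experiments can be compared visually, two processing steps are
needed.  First, counts must be made comparable across libraries of different
sequencing depth: the tool offers library-size (crosslinks per million),
max-peak (scale the viewed region to [0, 1] per group), their composition
(library size first, then max peak), user-supplied size factors, or no
normalization.  Second, nucleotide-resolution crosslink counts are noisy at
single positions, so the signal is smoothed with a centered rolling mean or
a Gaussian kernel regression over a configurable window.

The pipeline order is fixed: densify over the region, normalize, smooth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import ClipViewError, CrosslinkLibrary, GenomicRegion

logger = logging.getLogger("clipview")

NORMALIZATION_MODES = ("none", "libsize", "maxpeak", "libsize_maxpeak", "custom")
SMOOTHING_METHODS = ("none", "rollmean", "gaussian")

#: y-axis label implied by each normalization mode
UNITS_BY_MODE = {
    "none": "Crosslinks",
    "libsize": "Crosslinks per million",
    "maxpeak": "Fraction of maximum",
    "libsize_maxpeak": "Fraction of maximum",
    "custom": "Crosslinks (custom scaled)",
}

DEFAULT_NORMALIZATION = "libsize"
DEFAULT_SMOOTHING = "rollmean"
DEFAULT_SMOOTHING_WINDOW = 100


@dataclass
class SignalProfile:
    """Dense per-position signal over a region for one experiment.

    ``values`` has one entry per nucleotide of the region.  ``strand``
    records which strand's crosslinks the profile holds, which matters only
    for unstranded coordinate regions where both strands are drawn.
    """

    name: str
    values: np.ndarray
    group: Optional[str] = None
    units_label: str = UNITS_BY_MODE["none"]
    strand: str = "+"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class NormalizationSpec:
    mode: str = DEFAULT_NORMALIZATION
    size_factors: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.mode not in NORMALIZATION_MODES:
            raise ClipViewError(
                f"unknown normalization {self.mode!r}; "
                f"choose from {', '.join(NORMALIZATION_MODES)}"
            )
        if self.mode == "custom" and not self.size_factors:
            raise ClipViewError(
                "normalization mode 'custom' requires size factors "
                "(one per crosslink track)"
            )


@dataclass(frozen=True)
class SmoothingSpec:
    method: str = DEFAULT_SMOOTHING
    window: int = DEFAULT_SMOOTHING_WINDOW

    def __post_init__(self):
        if self.method not in SMOOTHING_METHODS:
            raise ClipViewError(
                f"unknown smoothing {self.method!r}; "
                f"choose from {', '.join(SMOOTHING_METHODS)}"
            )
        if self.window < 1:
            raise ClipViewError(f"smoothing window must be >= 1, got {self.window}")


# ---------------------------------------------------------------------------
# Densification
# ---------------------------------------------------------------------------


def extract_region_signal(lib: CrosslinkLibrary, region: GenomicRegion,
                          strand: Optional[str] = None) -> SignalProfile:
    """Densify a library's crosslink counts over the region.

    Positions without a crosslink are 0.  When the region (or the explicit
    ``strand`` override) is stranded, only sites on that strand contribute;
    an unstranded region includes both strands.
    """
    wanted = strand if strand is not None else region.strand
    values = np.zeros(len(region), dtype=float)
    hit = False
    for s in lib.sites:
        if s.chrom != region.chrom:
            continue
        if wanted in "+-" and s.strand != wanted:
            continue
        if region.start <= s.pos < region.end:
            values[s.pos - region.start] += s.count
            hit = True
    if not hit:
        chroms = {s.chrom for s in lib.sites}
        extra = ""
        if region.chrom not in chroms and chroms:
            extra = (f" — chromosome spelling mismatch? region has "
                     f"{region.chrom!r}, track has {sorted(chroms)[:3]}")
        logger.warning("%s: no crosslinks in %s%s", lib.name, region.label, extra)
    return SignalProfile(name=lib.name, values=values,
                         strand=wanted if wanted in "+-" else "+")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_libsize(profile: SignalProfile, library_size: float) -> SignalProfile:
    """Crosslinks-per-million: value / whole-library total x 1,000,000."""
    if library_size <= 0:
        raise ClipViewError(
            f"{profile.name}: library size must be > 0 for libsize "
            f"normalization (got {library_size})"
        )
    return replace(profile, values=profile.values / library_size * 1_000_000,
                   units_label=UNITS_BY_MODE["libsize"])


def normalize_maxpeak(profiles: Sequence[SignalProfile]) -> list[SignalProfile]:
    """Divide a group of profiles by the single group-wide maximum.

    The maximum is pooled over all tracks of the group within the region, so
    grouped replicates share one scale and the group's maximum becomes
    exactly 1.  An all-zero group is returned unchanged with a warning.
    """
    if not profiles:
        return []
    peak = max(float(p.values.max()) if p.values.size else 0.0 for p in profiles)
    if peak <= 0:
        logger.warning(
            "max-peak normalization skipped for group %r: no signal in region",
            profiles[0].group,
        )
        return [replace(p) for p in profiles]
    return [
        replace(p, values=p.values / peak, units_label=UNITS_BY_MODE["maxpeak"])
        for p in profiles
    ]


def normalize_custom(profile: SignalProfile, size_factor: float) -> SignalProfile:
    """Divide by a user-supplied per-experiment size factor."""
    if size_factor is None or size_factor <= 0:
        raise ClipViewError(
            f"{profile.name}: custom normalization needs a positive size "
            f"factor (got {size_factor})"
        )
    return replace(profile, values=profile.values / size_factor,
                   units_label=UNITS_BY_MODE["custom"])


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def _effective_window(window: int, n: int, method: str) -> int:
    """Odd-adjusted window clamped to the profile length."""
    w = int(window)
    if w < 1:
        raise ClipViewError(f"smoothing window must be >= 1, got {window}")
    if w > n:
        logger.warning(
            "%s window %d exceeds region length %d; clamping", method, w, n
        )
        w = n
    if w % 2 == 0:
        w = w - 1 if w >= n else w + 1
        w = max(w, 1)
        logger.info("%s window adjusted to %d so it can be centered", method, w)
    return w


def smooth_rollmean(profile: SignalProfile, window: int) -> SignalProfile:
    """Centered rolling mean.

    Positions whose window extends past the region edge use the truncated
    window (a partial mean), so the output has a value everywhere and keeps
    the input length.  Window 1 is the identity.
    """
    n = profile.values.size
    w = _effective_window(window, n, "rollmean")
    if w == 1:
        return replace(profile)
    kernel = np.ones(w)
    sums = np.convolve(profile.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return replace(profile, values=sums / counts)


def smooth_gaussian(profile: SignalProfile, window: int) -> SignalProfile:
    """Gaussian kernel regression (Nadaraya–Watson) over the region.

    The kernel standard deviation is window/4 and the kernel is truncated at
    +/- window/2; weights are renormalized at the edges so the output length
    equals the input length.
    """
    n = profile.values.size
    w = _effective_window(window, n, "gaussian")
    if w == 1:
        return replace(profile)
    half = (w - 1) // 2
    sigma = w / 4.0
    offsets = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    num = np.convolve(profile.values, kernel, mode="same")
    den = np.convolve(np.ones(n), kernel, mode="same")
    return replace(profile, values=num / den)


_SMOOTHERS = {"rollmean": smooth_rollmean, "gaussian": smooth_gaussian}


def smooth(profile: SignalProfile, spec: SmoothingSpec) -> SignalProfile:
    if spec.method == "none":
        return replace(profile)
    return _SMOOTHERS[spec.method](profile, spec.window)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def process_libraries(
    libs: Sequence[CrosslinkLibrary],
    region: GenomicRegion,
    norm: NormalizationSpec = NormalizationSpec(),
    smoothing: SmoothingSpec = SmoothingSpec(),
    groups: Optional[Mapping[str, str]] = None,
    strand: Optional[str] = None,
) -> list[SignalProfile]:
    """Run the full signal pipeline for a set of crosslink tracks.

    The order is fixed: densify over the region, then normalize — library
    size (or custom factors) first, then, for the maxpeak modes, division by
    the pooled per-group maximum — and smooth last.  ``groups`` maps track
    name to group label; ungrouped tracks are singleton groups.
    """
    groups = dict(groups or {})
    profiles = []
    for lib in libs:
        p = extract_region_signal(lib, region, strand=strand)
        p.group = groups.get(lib.name, lib.name)
        if norm.mode in ("libsize", "libsize_maxpeak"):
            p = normalize_libsize(p, lib.library_size)
        elif norm.mode == "custom":
            factor = (norm.size_factors or {}).get(lib.name)
            p = normalize_custom(p, factor)
        profiles.append(p)

    if norm.mode in ("maxpeak", "libsize_maxpeak"):
        by_group: dict[str, list[int]] = {}
        for i, p in enumerate(profiles):
            by_group.setdefault(p.group, []).append(i)
        for idxs in by_group.values():
            scaled = normalize_maxpeak([profiles[i] for i in idxs])
            for i, p in zip(idxs, scaled):
                profiles[i] = p

    return [smooth(p, smoothing) for p in profiles]


def process_track(
    lib: CrosslinkLibrary,
    region: GenomicRegion,
    norm: NormalizationSpec = NormalizationSpec(),
    smoothing: SmoothingSpec = SmoothingSpec(),
    strand: Optional[str] = None,
) -> SignalProfile:
    """Single-track convenience wrapper: the track is its own maxpeak group."""
    return process_libraries([lib], region, norm, smoothing, strand=strand)[0]
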