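"""Normalization and smoothing, checked against brute-force oracles."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from clipview.io import ClipViewError, CrosslinkLibrary, CrosslinkSite, GenomicRegion
from clipview.signal import (
    NormalizationSpec,
    SignalProfile,
    SmoothingSpec,
    extract_region_signal,
    normalize_custom,
    normalize_libsize,
    normalize_maxpeak,
    process_libraries,
    process_track,
    smooth_gaussian,
    smooth_rollmean,
)


def make_lib(sites, name="t"):
    return CrosslinkLibrary(name, sites, sum(s.count for s in sites))


def profile(values, **kw):
    return SignalProfile(name=kw.pop("name", "t"), values=np.asarray(values, float),
                         **kw)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def brute_extract(sites, region):
    out = np.zeros(region.end - region.start)
    for pos in range(region.start, region.end):
        for s in sites:
            if (s.chrom == region.chrom and s.pos == pos
                    and (region.strand == "." or s.strand == region.strand)):
                out[pos - region.start] += s.count
    return out


def brute_rollmean(values, window):
    n = len(values)
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.mean(values[lo:hi])
    return out


def brute_gaussian(values, window):
    n = len(values)
    half = (window - 1) // 2
    sigma = window / 4.0
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(max(0, i - half), min(n, i + half + 1)):
            w = np.exp(-0.5 * ((j - i) / sigma) ** 2)
            num += w * values[j]
            den += w
        out[i] = num / den
    return out


# ---------------------------------------------------------------------------
# Densification
# ---------------------------------------------------------------------------


class TestExtractRegionSignal:
    def test_direct_placement(self):
        lib = make_lib([CrosslinkSite("chr1", 102, "+", 3),
                        CrosslinkSite("chr1", 104, "+", 5)])
        region = GenomicRegion("chr1", 100, 106, "+", "r")
        np.testing.assert_array_equal(
            extract_region_signal(lib, region).values, [0, 0, 3, 0, 5, 0])

    def test_opposite_strand_filtered_out(self):
        lib = make_lib([CrosslinkSite("chr1", 102, "+", 3)])
        region = GenomicRegion("chr1", 100, 106, "-", "r")
        assert not extract_region_signal(lib, region).values.any()

    def test_matches_naive_lookup_on_random_sites(self, rng):
        region = GenomicRegion("chr1", 50, 250, "+", "r")
        sites = [
            CrosslinkSite("chr1", int(p), str(s), float(c))
            for p, s, c in zip(rng.integers(0, 300, 120),
                               rng.choice(["+", "-"], 120),
                               rng.integers(1, 9, 120))
        ]
        np.testing.assert_array_equal(
            extract_region_signal(make_lib(sites), region).values,
            brute_extract(sites, region))

    def test_empty_overlap_warns(self, caplog):
        lib = make_lib([CrosslinkSite("chrX", 10, "+", 1)])
        region = GenomicRegion("chr1", 0, 50, "+", "r")
        with caplog.at_level(logging.WARNING, logger="clipview"):
            vals = extract_region_signal(lib, region).values
        assert not vals.any()
        assert any("no crosslinks" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class TestNormalizeLibsize:
    def test_cpm_identity_at_million(self):
        p = normalize_libsize(profile([5.0]), 1_000_000)
        assert p.values[0] == 5.0

    def test_single_crosslink_library_scores_one_million(self):
        p = normalize_libsize(profile([1.0]), 1.0)
        assert p.values[0] == 1_000_000
        assert p.units_label == "Crosslinks per million"

    def test_zero_profile_stays_zero(self):
        assert not normalize_libsize(profile([0, 0, 0]), 10).values.any()

    def test_nonpositive_library_size_fatal(self):
        with pytest.raises(ClipViewError, match="library size"):
            normalize_libsize(profile([1.0]), 0)

    def test_whole_library_cpm_sums_to_one_million(self, rng):
        counts = rng.integers(0, 20, 500).astype(float)
        total = counts.sum()
        p = normalize_libsize(profile(counts), total)
        assert p.values.sum() == pytest.approx(1_000_000, rel=1e-12)


class TestNormalizeMaxpeak:
    def test_single_track_group(self):
        (p,) = normalize_maxpeak([profile([2, 4, 8])])
        np.testing.assert_array_equal(p.values, [0.25, 0.5, 1.0])
        assert p.units_label == "Fraction of maximum"

    def test_group_shares_pooled_maximum(self):
        a, b = normalize_maxpeak([profile([0, 8, 0], name="a"),
                                  profile([4, 2, 0], name="b")])
        assert a.values.max() == 1.0
        assert b.values.max() == 0.5

    def test_all_zero_group_unchanged_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="clipview"):
            (p,) = normalize_maxpeak([profile([0, 0])])
        assert not p.values.any()
        assert any("max-peak" in r.message for r in caplog.records)

    def test_range_zero_to_one_on_random_groups(self, rng):
        for _ in range(50):
            group = [profile(rng.integers(0, 100, 80).astype(float))
                     for _ in range(rng.integers(1, 4))]
            if not any(p.values.any() for p in group):
                continue
            out = normalize_maxpeak(group)
            pooled = np.concatenate([p.values for p in out])
            assert pooled.max() == 1.0
            assert pooled.min() >= 0.0


class TestNormalizeCustom:
    @pytest.mark.parametrize("factor,expected", [(2.0, [1, 2]), (1.0, [2, 4])])
    def test_division_by_factor(self, factor, expected):
        np.testing.assert_array_equal(
            normalize_custom(profile([2, 4]), factor).values, expected)

    def test_zero_factor_fatal_names_track(self):
        with pytest.raises(ClipViewError, match="mytrack"):
            normalize_custom(profile([1], name="mytrack"), 0)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


class TestRollmean:
    def test_centered_window_interior(self):
        p = smooth_rollmean(profile([0, 0, 3, 0, 0]), 3)
        np.testing.assert_allclose(p.values[1:4], [1, 1, 1])

    def test_window_one_is_identity(self, rng):
        v = rng.uniform(0, 5, 30)
        np.testing.assert_array_equal(smooth_rollmean(profile(v), 1).values, v)

    def test_constant_profile_invariant(self):
        for w in (1, 3, 7, 15):
            np.testing.assert_allclose(
                smooth_rollmean(profile([4.0] * 20), w).values, 4.0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            w = min(int(rng.integers(1, 40)) | 1, n - (1 - n % 2))  # odd, <= n
            v = rng.uniform(0, 10, n)
            np.testing.assert_allclose(
                smooth_rollmean(profile(v), w).values, brute_rollmean(v, w),
                atol=1e-9)

    def test_even_window_bumped_to_odd(self, rng):
        v = rng.uniform(0, 10, 50)
        np.testing.assert_allclose(smooth_rollmean(profile(v), 10).values,
                                   smooth_rollmean(profile(v), 11).values)

    def test_oversized_window_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="clipview"):
            p = smooth_rollmean(profile([1, 2, 3]), 99)
        assert p.values.size == 3
        assert any("clamping" in r.message for r in caplog.records)

    def test_mean_preserved_exactly_on_circular_padding(self, rng):
        v = rng.uniform(0, 10, 64)
        w = 9
        half = (w - 1) // 2
        padded = np.concatenate([v[-half:], v, v[:half]])
        sm = smooth_rollmean(profile(padded), w).values[half:-half]
        assert sm.mean() == pytest.approx(v.mean(), rel=1e-12)


class TestGaussian:
    def test_constant_profile_invariant(self):
        np.testing.assert_allclose(
            smooth_gaussian(profile([2.5] * 31), 11).values, 2.5)

    def test_impulse_response_symmetric_peaked_at_center(self):
        v = np.zeros(21)
        v[10] = 1.0
        out = smooth_gaussian(profile(v), 9).values
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)
        assert out.argmax() == 10

    def test_matches_brute_force_nadaraya_watson(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            w = min(int(rng.integers(1, 40)) | 1, n - (1 - n % 2))  # odd, <= n
            v = rng.uniform(0, 10, n)
            np.testing.assert_allclose(
                smooth_gaussian(profile(v), w).values, brute_gaussian(v, w),
                atol=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    values=hnp.arrays(np.float64, st.integers(5, 120),
                      elements=st.floats(0, 1e6)),
    window=st.integers(1, 31).filter(lambda w: w % 2 == 1),
    scale=st.floats(1e-3, 1e3),
)
def test_smoothers_commute_with_scalar_multiplication(values, window, scale):
    for smoother in (smooth_rollmean, smooth_gaussian):
        a = smoother(profile(values * scale), window).values
        b = smoother(profile(values), window).values * scale
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-6)


# ---------------------------------------------------------------------------
# Pipeline order
# ---------------------------------------------------------------------------


def random_libs(rng, n_tracks=3, span=(100, 400)):
    libs = []
    for i in range(n_tracks):
        sites = [CrosslinkSite("chr1", int(p), "+", float(c))
                 for p, c in zip(rng.integers(*span, 150),
                                 rng.integers(1, 30, 150))]
        libs.append(make_lib(sites, name=f"t{i}"))
    return libs


class TestPipeline:
    def test_identity_pipeline_returns_raw_counts(self, rng):
        region = GenomicRegion("chr1", 100, 400, "+", "r")
        (lib,) = random_libs(rng, 1)
        p = process_track(lib, region, NormalizationSpec("none"),
                          SmoothingSpec("none"))
        np.testing.assert_array_equal(p.values,
                                      extract_region_signal(lib, region).values)
        assert p.units_label == "Crosslinks"

    def test_libsize_before_maxpeak(self, rng):
        """libsize_maxpeak equals maxpeak applied to CPM profiles, and the
        normalized group maximum is 1 before smoothing."""
        region = GenomicRegion("chr1", 100, 400, "+", "r")
        libs = random_libs(rng)
        groups = {"t0": "G", "t1": "G", "t2": "G"}
        combined = process_libraries(
            libs, region, NormalizationSpec("libsize_maxpeak"),
            SmoothingSpec("none"), groups)
        cpm = [normalize_libsize(extract_region_signal(l, region), l.library_size)
               for l in libs]
        sequential = normalize_maxpeak(cpm)
        for got, want in zip(combined, sequential):
            np.testing.assert_allclose(got.values, want.values, rtol=1e-12)
        assert max(p.values.max() for p in combined) == 1.0

    def test_normalize_first_order_is_material(self, rng):
        """Smoothing before maxpeak would give a different result; the
        pipeline normalizes first, as documented."""
        region = GenomicRegion("chr1", 100, 400, "+", "r")
        (lib,) = random_libs(rng, 1)
        norm, sm = NormalizationSpec("maxpeak"), SmoothingSpec("rollmean", 21)
        pipeline = process_track(lib, region, norm, sm)
        normalize_first = smooth_rollmean(
            normalize_maxpeak([extract_region_signal(lib, region)])[0], 21)
        smooth_first = normalize_maxpeak(
            [smooth_rollmean(extract_region_signal(lib, region), 21)])[0]
        np.testing.assert_allclose(pipeline.values, normalize_first.values,
                                   rtol=1e-12)
        assert not np.allclose(pipeline.values, smooth_first.values)

    def test_libsize_commutes_with_smoothing_but_runs_first(self, rng):
        # CPM is linear, so the order cannot change the numbers ...
        region = GenomicRegion("chr1", 100, 400, "+", "r")
        (lib,) = random_libs(rng, 1)
        p = process_track(lib, region, NormalizationSpec("libsize"),
                          SmoothingSpec("rollmean", 11))
        other_order = normalize_libsize(
            smooth_rollmean(extract_region_signal(lib, region), 11),
            lib.library_size)
        np.testing.assert_allclose(p.values, other_order.values, rtol=1e-9)

    def test_custom_mode_requires_factor_for_every_track(self, rng):
        region = GenomicRegion("chr1", 100, 400, "+", "r")
        libs = random_libs(rng, 2)
        norm = NormalizationSpec("custom", {"t0": 2.0})  # t1 missing
        with pytest.raises(ClipViewError, match="t1"):
            process_libraries(libs, region, norm, SmoothingSpec("none"))

    def test_custom_spec_without_factors_fatal(self):
        with pytest.raises(ClipViewError, match="custom"):
            NormalizationSpec("custom")

    def test_unknown_mode_fatal(self):
        with pytest.raises(ClipViewError, match="sizelib"):
            NormalizationSpec("sizelib")
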