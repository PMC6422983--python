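"""Fragmentation map construction: the filter -> trim -> count -> smooth
chain, peak calling and the interception test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoamp import FragmentRecord
from nucleoamp.fragmap import (
    CoverageTrack,
    NucleosomeMap,
    call_nucleosome_peaks,
    filter_by_length,
    fragments_from_pairs,
    interception_test,
    position_overlap_counts,
    square_pulse_smooth,
    trim_to_dyad_window,
)
from conftest import make_amplicon, random_fragments


class TestPairs:
    def test_outer_span_definition(self):
        frs, dropped = fragments_from_pairs([(("chr1", 100, 201), ("chr1", 150, 251))])
        assert frs == [FragmentRecord("chr1", 100, 251)]
        assert frs[0].length == 151
        assert sum(dropped.values()) == 0

    def test_cross_contig_pairs_dropped_not_fatal(self):
        frs, dropped = fragments_from_pairs([(("chr1", 0, 100), ("chr2", 0, 100))])
        assert frs == [] and dropped["cross_contig"] == 1

    def test_matches_minmax_oracle_on_random_pairs(self, rng):
        pairs = []
        for _ in range(1000):
            s1, s2 = rng.integers(0, 5000, 2)
            pairs.append((("c", int(s1), int(s1) + 100), ("c", int(s2), int(s2) + 100)))
        frs, _ = fragments_from_pairs(pairs)
        expected = [
            (min(p[0][1], p[1][1]), max(p[0][2], p[1][2])) for p in pairs
        ]
        assert [(f.start, f.end) for f in frs] == expected


class TestLengthFilter:
    def test_inclusive_boundaries(self):
        frs = [FragmentRecord("c", 0, l) for l in (79, 80, 250, 251)]
        kept = filter_by_length(frs)
        assert [f.length for f in kept] == [80, 250]

    def test_empty_input(self):
        assert filter_by_length([]) == []

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length([], 100, 80)

    def test_survivor_count_matches_normal_cdf(self, rng):
        """Count surviving the 80-250 filter agrees with the discretized
        normal interval mass within 3 SE at n = 20,000."""
        from scipy.stats import norm

        n = 20_000
        lengths = np.maximum(np.rint(rng.normal(167, 20, n)), 1).astype(int)
        frs = [FragmentRecord("c", 0, int(l)) for l in lengths]
        kept = len(filter_by_length(frs))
        p = norm.cdf(250.5, 167, 20) - norm.cdf(79.5, 167, 20)
        se = np.sqrt(n * p * (1 - p))
        assert abs(kept - n * p) < 3 * se


class TestTrim:
    def test_midpoint_window(self):
        (out,) = trim_to_dyad_window([FragmentRecord("c", 100, 268)], 40)
        assert (out.start, out.end) == (164, 204)

    def test_window_length_fragment_unchanged(self):
        (out,) = trim_to_dyad_window([FragmentRecord("c", 60, 100)], 40)
        assert (out.start, out.end) == (60, 100)

    def test_all_outputs_have_window_length_and_same_dyads(self, rng):
        frs = random_fragments(rng, 500, lo=100, hi=4000)
        frs = [f for f in frs if f.length >= 40]
        out = trim_to_dyad_window(frs, 40)
        assert len(out) == len(frs)
        assert all(f.length == 40 for f in out)
        assert [f.midpoint for f in out] == [f.midpoint for f in frs]

    def test_short_fragment_is_an_error_listing_offenders(self):
        with pytest.raises(ValueError, match=r"\[0,10\)"):
            trim_to_dyad_window([FragmentRecord("c", 0, 10)], 40)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            trim_to_dyad_window([], 21)


class TestOverlapCounts:
    def test_single_fragment_by_definition(self):
        track = position_overlap_counts([FragmentRecord("c", 10, 14)], 8, 16)
        assert np.array_equal(track.values, [0, 0, 1, 1, 1, 1, 0, 0])

    def test_no_fragments_all_zero(self):
        track = position_overlap_counts([], 0, 50)
        assert not track.values.any()

    def test_matches_per_position_scan_oracle(self, rng):
        frs = random_fragments(rng, 5000, hi=2000)
        track = position_overlap_counts(frs, 300, 800)
        oracle = np.array(
            [sum(f.start <= p < f.end for f in frs) for p in range(300, 800)]
        )
        assert np.array_equal(track.values, oracle)


class TestSmoothing:
    def test_constant_track_is_fixed_point(self):
        track = CoverageTrack("c", 0, np.full(100, 7.0))
        assert np.allclose(square_pulse_smooth(track, 21).values, 7.0)

    def test_impulse_response_is_flat_pulse(self):
        values = np.zeros(101)
        values[50] = 1.0
        out = square_pulse_smooth(CoverageTrack("c", 0, values), 21).values
        assert np.allclose(out[40:61], 1 / 21)
        assert np.allclose(np.delete(out, np.s_[40:61]), 0.0)

    def test_matches_truncated_window_oracle(self, rng):
        values = rng.uniform(0, 10, 200)
        out = square_pulse_smooth(CoverageTrack("c", 0, values), 21).values
        oracle = np.array(
            [values[max(0, i - 10) : i + 11].mean() for i in range(200)]
        )
        assert np.allclose(out, oracle)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            square_pulse_smooth(CoverageTrack("c", 0, np.zeros(50)), 20)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-3, 3, allow_nan=False),
        st.floats(-3, 3, allow_nan=False),
    )
    def test_linearity(self, seed, a, b):
        """smooth(a*x + b*y) == a*smooth(x) + b*smooth(y)."""
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 5, 80), rng.uniform(0, 5, 80)
        combo = a * x + b * y
        if np.any(combo < 0):
            return  # only the non-negative combination is a valid track
        sm = lambda v: square_pulse_smooth(CoverageTrack("c", 0, v), 11).values
        assert np.allclose(sm(combo), a * sm(x) + b * sm(y), atol=1e-9)

    def test_interior_mean_conservation(self, rng):
        """Away from edges, a window mean of the smoothed track equals the
        raw mean of the window extended by (width-1)/2 each side."""
        values = rng.uniform(0, 10, 300)
        out = square_pulse_smooth(CoverageTrack("c", 0, values), 21).values
        lo, hi = 50, 150
        assert out[lo:hi].mean() == pytest.approx(
            np.convolve(values, np.ones(21) / 21, "full")[lo + 10 : hi + 10].mean()
        )


class TestPeakCalling:
    def test_concentrated_dyads_single_high_stringency_peak(self):
        dyads = [500] * 200 + list(range(0, 2000, 40))
        nmap = call_nucleosome_peaks(dyads, bandwidth=15, background_window=600)
        strongest = nmap.positions[np.argmax(nmap.stringencies)]
        assert abs(strongest - 500) <= 2
        assert nmap.stringencies.max() > 1.0

    def test_uniform_scatter_stringencies_near_one(self, rng):
        dyads = rng.integers(0, 50_000, 20_000)
        nmap = call_nucleosome_peaks(dyads, bandwidth=30, background_window=1000)
        interior = (nmap.positions > 2000) & (nmap.positions < 48_000)
        med = np.median(nmap.stringencies[interior])
        assert 0.8 < med < 1.25

    def test_two_separated_concentrations_give_two_dominant_peaks(self, rng):
        dyads = np.r_[
            rng.normal(1000, 8, 300).astype(int), rng.normal(3000, 8, 300).astype(int)
        ]
        nmap = call_nucleosome_peaks(dyads, bandwidth=30, background_window=800,
                                     min_stringency=2.0)
        assert nmap.n_peaks == 2
        assert abs(nmap.positions[0] - 1000) <= 15
        assert abs(nmap.positions[1] - 3000) <= 15

    def test_no_dyads_is_an_error(self):
        with pytest.raises(ValueError):
            call_nucleosome_peaks([])


class TestInterception:
    def _map_at(self, positions):
        return NucleosomeMap("c", np.asarray(positions), np.ones(len(positions)),
                             30.0, 1000)

    def test_amplicons_on_every_peak_significant(self):
        peaks = np.arange(500, 20_000, 2000)
        nmap = self._map_at(peaks)
        panel = [make_amplicon(int(p) - 50, int(p) + 50, f"a{i}")
                 for i, p in enumerate(peaks)]
        p, obs = interception_test(nmap, panel, n_perm=999, seed=0,
                                   region=(0, 20_000))
        assert obs == len(panel)
        assert p <= 0.05

    def test_null_panels_give_roughly_uniform_p(self, rng):
        nmap = self._map_at(np.sort(rng.choice(50_000, 40, replace=False)))
        ps = []
        for rep in range(40):
            starts = np.sort(rng.integers(0, 49_000, 10))
            panel = [make_amplicon(int(s), int(s) + 120, f"a{i}")
                     for i, s in enumerate(starts)]
            p, _ = interception_test(nmap, panel, n_perm=199, seed=rep,
                                     region=(0, 50_000))
            ps.append(p)
        assert 0.2 < np.mean(ps) < 0.8
        assert np.std(ps) > 0.1  # not degenerate

    def test_degenerate_no_possible_interception_p_one(self):
        nmap = self._map_at([100])
        panel = [make_amplicon(5000, 5100, "a0")]
        # region excludes the peak entirely: no shift can intercept
        p, obs = interception_test(nmap, panel, n_perm=199, seed=1,
                                   region=(4000, 6000))
        assert obs == 0 and p == 1.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            interception_test(self._map_at([10]), [make_amplicon(0, 100)], n_perm=10)
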