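"""Tiling-array normalization, smoothing, extent calling, strand ratios."""

import numpy as np
import pytest

from imprintkit.intervals import GenomeInterval
from imprintkit.pipeline import build_relative_profile
from imprintkit.tiling import (
    Background,
    RelativeIntensityProfile,
    TilingProbe,
    apply_masks,
    call_extent,
    estimate_background,
    relative_intensity,
    segment_region,
    smooth_profile,
    strand_log_ratio,
    tukey_biweight_location,
    unmasked_ratios,
)
from imprintkit import simulate as sim


def _probes(values, gdna=1.0, start=0, spacing=100, length=50, chrom="chr1"):
    return [
        TilingProbe(
            GenomeInterval(chrom, start + i * spacing, start + i * spacing + length),
            float(v), gdna,
        )
        for i, v in enumerate(values)
    ]


class TestTukeyBiweight:
    def test_constant_input_returns_constant(self):
        assert tukey_biweight_location([5, 5, 5, 5]) == 5

    def test_symmetric_input_returns_center(self):
        assert tukey_biweight_location([1, 2, 3, 4, 5]) == pytest.approx(3.0)

    def test_single_outlier_downweighted(self):
        # independently computed: median 3, MAD 1, weights (1-u^2)^2 with
        # u = (x-3)/5.0001 zero out the outlier
        val = tukey_biweight_location([1, 2, 3, 4, 100])
        assert val == pytest.approx(2.602340288333645)
        assert 2 < val < 4 < np.mean([1, 2, 3, 4, 100])

    def test_equals_mean_on_outlier_free_symmetric_data(self):
        x = np.concatenate([np.linspace(-1, 1, 21) + 10])
        assert tukey_biweight_location(x) == pytest.approx(np.mean(x), abs=1e-9)

    def test_bounded_response_to_arbitrarily_large_outlier(self):
        base = [1, 2, 3, 4, 5]
        vals = [tukey_biweight_location(base + [m]) for m in (1e3, 1e6, 1e12)]
        assert max(vals) - min(vals) < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight_location([])


class TestRelativeIntensity:
    def test_uniform_track_is_all_ones(self):
        probes = _probes([2.0] * 30, gdna=2.0)
        np.testing.assert_allclose(relative_intensity(probes), 1.0)

    def test_two_segment_closed_form(self):
        probes = _probes([2.0] * 10 + [1.0] * 10)
        rel = relative_intensity(probes)
        np.testing.assert_allclose(rel[:10], 4 / 3)
        np.testing.assert_allclose(rel[10:], 2 / 3)

    def test_region_mean_is_one_on_random_inputs(self):
        rng = np.random.default_rng(3)
        probes = _probes(rng.lognormal(0, 0.5, 200), gdna=1.0)
        assert relative_intensity(probes).mean() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_cdna_warns_and_returns_zeros(self):
        probes = _probes([0.0] * 20)
        with pytest.warns(UserWarning):
            rel = relative_intensity(probes)
        assert np.all(rel == 0)


class TestApplyMasks:
    def test_no_overlap_is_identity(self):
        probes = _probes(np.ones(50))
        masks = [GenomeInterval("chr1", 10_000, 11_000)]
        assert apply_masks(probes, masks) == probes

    def test_mask_over_all_probes_empties_with_warning(self):
        probes = _probes(np.ones(10))
        with pytest.warns(UserWarning):
            out = apply_masks(probes, [GenomeInterval("chr1", 0, 10_000)])
        assert out == []

    def test_exact_probe_count_removed(self):
        probes = _probes(np.ones(1000))
        # probes 100..109 start at 10000..10900
        masks = [GenomeInterval("chr1", 10_000, 10_950)]
        out = apply_masks(probes, masks)
        assert len(probes) - len(out) == 10


class TestSmoothProfile:
    def test_constant_values_give_zero_sd_points(self):
        pos = np.arange(0, 60_000, 100)
        prof = smooth_profile(pos, np.full(pos.size, 2.5))
        assert all(p.mean == pytest.approx(2.5) for p in prof.points)
        full = [p for p in prof.points if not p.partial]
        assert all(p.sd == pytest.approx(0.0) for p in full)

    def test_28_probes_make_exactly_one_full_point(self):
        pos = np.arange(28) * 100.0
        prof = smooth_profile(pos, np.ones(28))
        assert len(prof.points) == 1
        assert prof.points[0].n_windows == 20 and not prof.points[0].partial

    def test_trailing_partial_block_is_flagged(self):
        pos = np.arange(40) * 100.0
        prof = smooth_profile(pos, np.ones(40))
        assert prof.points[-1].partial
        assert prof.points[-1].n_windows == 40 - 9 + 1 - 20

    def test_fewer_than_nine_probes_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.arange(8) * 100.0, np.ones(8))

    def test_sharp_step_inflates_sd_at_the_break(self):
        pos = np.arange(0, 30_000, 100)
        vals = np.where(pos < 15_000, 2.0, 0.5)
        prof = smooth_profile(pos, vals)
        sds = prof.sds
        positions = prof.positions
        at_break = sds[np.abs(positions - 15_000) < 2_000].max()
        flat = sds[(positions < 10_000)].max()
        assert at_break > 10 * max(flat, 1e-12)


class TestSegmentRegion:
    def test_display_region_tiles(self):
        seg = segment_region(-62_000, 28_000, 118_000)
        assert seg.igf2r_specific == (-62_000, 0.0)
        assert seg.overlap == (0.0, 28_000)
        assert seg.transcript_specific == (28_000, 118_000)

    def test_degenerate_boundaries_rejected(self):
        with pytest.raises(ValueError):
            segment_region(-62_000, 118_000, 118_000)

    def test_minimal_valid_segmentation(self):
        seg = segment_region(0, 1_000, 2_000)
        assert seg.igf2r_specific == (0.0, 0.0)
        assert seg.transcript_specific == (1_000, 2_000)


class TestCallExtent:
    def _profile(self, means, start=28_000, spacing=2_000):
        from imprintkit.tiling import ProfilePoint

        points = [
            ProfilePoint(start + i * spacing, float(m), 0.02, 20) for i, m in enumerate(means)
        ]
        return RelativeIntensityProfile(points)

    def test_identical_profiles_yield_no_calls(self):
        means = np.linspace(1.2, 0.8, 30)
        prof = self._profile(means)
        call = call_extent(prof, prof, Background(0.05, 0.005))
        assert call.reduction_start is None and call.absence_start is None

    def test_mismatched_grids_rejected(self):
        a = self._profile(np.ones(10))
        b = self._profile(np.ones(10), start=29_000)
        with pytest.raises(ValueError, match="grid"):
            call_extent(a, b, Background(0.0, 0.0))

    def test_criterion_params_recorded(self):
        prof = self._profile(np.ones(12))
        call = call_extent(prof, prof, Background(0.0, 0.0), delta=0.3, k=4, z=1.5)
        assert call.criterion_params == {"delta": 0.3, "k": 4, "z": 1.5}

    def test_absence_monotone_in_true_truncation(self):
        # later truth truncation must never yield an earlier absence call
        calls = []
        for trunc in (60_000, 75_000, 90_000, 105_000):
            scen = sim.TilingScenario(decline_start=trunc - 10_000, truncation=trunc)
            wt, _, _ = sim.gen_tiling(sim.WILDTYPE, seed=901)
            mu, _, _ = sim.gen_tiling(scen, seed=902)
            wtp = build_relative_profile(wt, tss_genomic_pos=62_000)
            mup = build_relative_profile(mu, tss_genomic_pos=62_000)
            c = call_extent(mup, wtp, estimate_background(mup), segment=(28_000, 118_000))
            calls.append(c.absence_start)
        assert all(a is not None for a in calls)
        spacing = 2_000
        assert all(b >= a - spacing for a, b in zip(calls, calls[1:]))

    def test_synthetic_truncation_recovery_within_point_spacing(self):
        wt, _, _ = sim.gen_tiling(sim.WILDTYPE, seed=41)
        mu, _, _ = sim.gen_tiling(sim.TDR_DELETION, seed=42)
        wtp = build_relative_profile(wt, tss_genomic_pos=62_000)
        mup = build_relative_profile(mu, tss_genomic_pos=62_000)
        call = call_extent(mup, wtp, estimate_background(mup), segment=(28_000, 118_000))
        assert abs(call.reduction_start - 68_000) <= 2_000
        assert abs(call.absence_start - 90_000) <= 2_000


class TestStrandLogRatio:
    region = GenomeInterval("chr1", 0, 32_000)

    def _reads(self, entries):
        reads = []
        for pos, strand, n in entries:
            reads += [("chr1", pos, strand)] * n
        return reads

    def test_balanced_windows_have_zero_ratio(self):
        reads = self._reads([(100, "+", 5), (150, "-", 5), (5_000, "+", 2), (5_100, "-", 2)])
        out = unmasked_ratios(strand_log_ratio(reads, self.region))
        assert all(w.log2_ratio == pytest.approx(0.0) for w in out)

    def test_strand_swap_negates_every_ratio(self):
        rng = np.random.default_rng(5)
        reads = [
            ("chr1", int(rng.integers(0, 32_000)), "+" if rng.random() < 0.7 else "-")
            for _ in range(2_000)
        ]
        flipped = [(c, p, "-" if s == "+" else "+") for c, p, s in reads]
        fwd = strand_log_ratio(reads, self.region)
        rev = strand_log_ratio(flipped, self.region)
        for a, b in zip(fwd, rev):
            if a.log2_ratio is None:
                assert b.log2_ratio is None
            else:
                assert b.log2_ratio == pytest.approx(-a.log2_ratio)

    def test_pseudocount_arithmetic(self):
        reads = self._reads([(10, "+", 8), (20, "-", 2)])
        region = GenomeInterval("chr1", 0, 3_200)
        no_pseudo = strand_log_ratio(reads, region, alpha=0.0)[0]
        with_pseudo = strand_log_ratio(reads, region, alpha=1.0)[0]
        assert no_pseudo.log2_ratio == pytest.approx(2.0)
        assert with_pseudo.log2_ratio == pytest.approx(np.log2(3.0))

    def test_masked_windows_excluded_exactly(self):
        reads = self._reads([(100, "+", 10), (10_000, "+", 10)])
        masks = [GenomeInterval("chr1", 3_000, 3_500)]  # overlaps window [0,3200)
        out = strand_log_ratio(reads, self.region, masks=masks)
        assert out[0].masked and out[0].log2_ratio is None
        assert not out[3].masked and out[3].log2_ratio is not None
        assert all(not w.masked for w in unmasked_ratios(out))

    def test_empty_window_carries_no_ratio(self):
        out = strand_log_ratio([], self.region)
        assert all(w.log2_ratio is None for w in out)

    def test_nonpositive_window_size_rejected(self):
        with pytest.raises(ValueError):
            strand_log_ratio([], self.region, window_size=0)
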