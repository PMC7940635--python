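"""Regulatory masks, ensemble statistics, z-scores, BH-corrected region calls."""

import numpy as np
import pytest
from scipy import stats

from atacdenoise import (
    DenseTrack,
    GenomeLayout,
    Interval,
    IntervalSet,
    call_significant_regions,
    ensemble_stats,
    normalize_by_coverage,
    regulatory_mask,
    zscore_track,
)

LAYOUT = GenomeLayout((("c", 400_000),))


def brute_bh(pvals):
    """Reference BH: q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def tss(positions):
    return IntervalSet([Interval("c", p, p + 1) for p in positions], LAYOUT)


class TestRegulatoryMask:
    def test_nearby_sites_merge(self):
        mask = regulatory_mask(tss([100_000, 150_000]), LAYOUT, flank=100_000)
        assert len(mask) == 1
        assert (mask[0].start, mask[0].end) == (0, 250_001)

    def test_zero_flank_is_sites(self):
        mask = regulatory_mask(tss([10, 20]), LAYOUT, flank=0)
        assert [(r.start, r.end) for r in mask] == [(10, 11), (20, 21)]

    def test_total_bp_bound(self):
        sites = [5_000, 200_000, 300_000]
        flank = 2_000
        mask = regulatory_mask(tss(sites), LAYOUT, flank=flank)
        assert mask.total_bp() == len(sites) * (2 * flank + 1)  # no overlap/clip
        clipped = regulatory_mask(tss([500]), LAYOUT, flank=2_000)
        assert clipped.total_bp() < 2 * 2_000 + 1


class TestNormalize:
    def _track(self, seed):
        rng = np.random.default_rng(seed)
        return DenseTrack(LAYOUT, {"c": rng.gamma(1.0, 1.0, 400_000)})

    def test_target_total_reached(self):
        t = normalize_by_coverage(self._track(0), 12_345.0)
        assert t.total() == pytest.approx(12_345.0, rel=1e-9)

    def test_scale_invariance(self):
        t = self._track(1)
        a = normalize_by_coverage(t, 1_000.0)
        b = normalize_by_coverage(t.scaled(2.0), 1_000.0)
        assert np.allclose(a.flatten(), b.flatten(), rtol=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_coverage(DenseTrack.zeros(LAYOUT), 1.0)


class TestEnsembleStats:
    SMALL = GenomeLayout((("c", 500),))

    def _tracks(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            DenseTrack(self.SMALL, {"c": rng.random(500) + 0.5}) for _ in range(n)
        ]

    def test_identical_tracks_zero_sigma(self):
        t = self._tracks(1)[0]
        ens = ensemble_stats(
            [t.copy(), t.copy(), t.copy()],
            IntervalSet([Interval("c", 0, 500)], self.SMALL),
        )
        assert np.allclose(ens.sigma["c"], 0.0, atol=1e-9)

    def test_two_track_mean(self):
        mask = IntervalSet([Interval("c", 0, 500)], self.SMALL)
        a, b = self._tracks(2, seed=3)
        ens = ensemble_stats([a, b], mask, normalize=False)
        assert np.allclose(ens.mu["c"], (a["c"] + b["c"]) / 2, rtol=1e-12)

    def test_matches_bruteforce(self):
        mask = IntervalSet([Interval("c", 0, 500)], self.SMALL)
        tracks = self._tracks(10, seed=4)
        ens = ensemble_stats(tracks, mask, normalize=False)
        stacked = np.stack([t["c"] for t in tracks])
        assert np.allclose(ens.mu["c"], stacked.mean(axis=0), rtol=1e-10)
        assert np.allclose(ens.sigma["c"], stacked.std(axis=0, ddof=1), rtol=1e-7)

    def test_normalization_equalizes_totals(self):
        mask = IntervalSet([Interval("c", 0, 500)], self.SMALL)
        tracks = self._tracks(5, seed=5)
        target = float(np.mean([t.total() for t in tracks]))
        ens = ensemble_stats(tracks, mask)
        assert ens.target_total == pytest.approx(target, rel=1e-12)
        for t in tracks:
            nt = normalize_by_coverage(t, ens.target_total)
            assert nt.total() == pytest.approx(target, rel=1e-6)

    def test_fewer_than_two_rejected(self):
        mask = IntervalSet([Interval("c", 0, 500)], self.SMALL)
        with pytest.raises(ValueError):
            ensemble_stats(self._tracks(1), mask)


class TestZScoreTrack:
    SMALL = GenomeLayout((("c", 300),))

    def _ensemble(self):
        rng = np.random.default_rng(6)
        tracks = [
            DenseTrack(self.SMALL, {"c": rng.random(300) + 1.0}) for _ in range(20)
        ]
        mask = IntervalSet([Interval("c", 50, 250)], self.SMALL)
        return ensemble_stats(tracks, mask, normalize=False)

    def test_mean_sample_zero_z(self):
        ens = self._ensemble()
        sample = DenseTrack(self.SMALL, {"c": ens.mu["c"].copy()})
        z = zscore_track(sample, ens)
        assert np.allclose(z.flatten(), 0.0)

    def test_two_sigma_deviation(self):
        ens = self._ensemble()
        sample = DenseTrack(self.SMALL, {"c": ens.mu["c"] + 2 * ens.sigma["c"]})
        z = zscore_track(sample, ens)
        assert np.allclose(z["c"][50:250], 2.0, atol=1e-9)
        assert np.all(z["c"][:50] == 0)  # outside mask

    def test_direct_formula(self):
        ens = self._ensemble()
        rng = np.random.default_rng(7)
        sample = DenseTrack(self.SMALL, {"c": rng.random(300) + 1.0})
        z = zscore_track(sample, ens)
        sel = slice(50, 250)
        expect = (sample["c"][sel] - ens.mu["c"][sel]) / ens.sigma["c"][sel]
        assert np.allclose(z["c"][sel], expect, rtol=1e-12)


class TestCallSignificantRegions:
    SMALL = GenomeLayout((("c", 2_000),))

    def _z(self, positions, value=5.0):
        z = DenseTrack.zeros(self.SMALL)
        for p in positions:
            z["c"][p] = value
        return z

    def _cov(self, value=10.0):
        return DenseTrack(self.SMALL, {"c": np.full(2_000, value)})

    def test_merge_rule(self):
        regions = call_significant_regions(
            self._z([100, 250, 600]), self._cov(), z_cut=2, merge_dist=200,
            fdr=0.5, min_coverage=0,
        )
        assert [(r.start, r.end) for r in regions] == [(100, 251), (600, 601)]

    def test_no_exceeding_bases_empty(self):
        assert call_significant_regions(self._z([], 0.0), self._cov()) == []

    def test_signed_peak_z_and_two_sided_p(self):
        z = DenseTrack.zeros(self.SMALL)
        z["c"][100] = -6.0
        regions = call_significant_regions(
            z, self._cov(), fdr=0.5, min_coverage=0
        )
        assert regions[0].peak_z == -6.0
        assert regions[0].p == pytest.approx(2 * stats.norm.sf(6.0), rel=1e-12)

    def test_min_coverage_filter(self):
        regions = call_significant_regions(
            self._z([100]), self._cov(0.5), min_coverage=1.0, fdr=0.5
        )
        assert regions == []

    def test_bh_matches_bruteforce(self):
        """The (p -> q) mapping equals the explicit step-up BH recursion for 50
        random regions."""
        rng = np.random.default_rng(8)
        layout = GenomeLayout((("c", 100_000),))
        z = DenseTrack.zeros(layout)
        zs = rng.uniform(2.05, 6.0, 50) * rng.choice([-1, 1], 50)
        for i, zval in enumerate(zs):
            z["c"][i * 1_000] = zval
        cov = DenseTrack(layout, {"c": np.full(100_000, 5.0)})
        regions = call_significant_regions(
            z, cov, fdr=1.01, min_coverage=0  # keep all to compare q exactly
        )
        assert len(regions) == 50
        pvals = [r.p for r in regions]
        q_ref = brute_bh(pvals)
        for r, q in zip(regions, q_ref):
            assert r.q == pytest.approx(q, rel=1e-12)
            assert r.q >= r.p

    def test_spiked_region_recovered_exactly(self):
        """A +5 sigma spike over 400 bp yields exactly one significant region
        overlapping the spike and nothing else.

        The sample deviates from the ensemble mean by a fraction of sigma
        outside the spike, emulating a sample whose denoised track closely
        follows the background consensus except at a genuinely differential
        region; a sample deviating by a full sigma at every base would by
        construction exceed |z| = 2 at ~5% of bases genome-wide.
        """
        rng = np.random.default_rng(11)
        layout = GenomeLayout((("c", 50_000),))
        mask = IntervalSet([Interval("c", 0, 50_000)], layout)
        backgrounds = [
            DenseTrack(layout, {"c": rng.normal(10.0, 1.0, 50_000).clip(0)})
            for _ in range(100)
        ]
        ens = ensemble_stats(backgrounds, mask, normalize=False)
        sample_values = ens.mu["c"] + 0.3 * ens.sigma["c"] * rng.normal(size=50_000)
        sample_values[20_000:20_400] += 5 * ens.sigma["c"][20_000:20_400]
        sample = DenseTrack(layout, {"c": sample_values.clip(0)})
        z = zscore_track(sample, ens)
        regions = call_significant_regions(z, sample, fdr=0.05, min_coverage=1.0)
        assert len(regions) == 1
        assert regions[0].start >= 19_900 and regions[0].end <= 20_500
        assert regions[0].peak_z > 0
        assert regions[0].q < 0.05

    def test_fdr_loosely_controlled_under_null(self):
        """With samples drawn from the background distribution itself, few
        seeds yield any significant region. Tracks are spatially smooth
        (moving-average noise), as denoised coverage is: base-pair-independent
        noise would let the 200 bp merge rule chain isolated null exceedances
        into long regions whose maximal z is not a single test statistic."""
        layout = GenomeLayout((("c", 20_000),))
        mask = IntervalSet([Interval("c", 0, 20_000)], layout)
        kernel = np.ones(200) / 200

        def smooth_noise(r, n=20_000):
            return np.convolve(r.normal(0.0, 1.0, n + 199), kernel, "valid")

        rng = np.random.default_rng(12)
        backgrounds = [
            DenseTrack(layout, {"c": 10.0 + smooth_noise(rng)}) for _ in range(100)
        ]
        ens = ensemble_stats(backgrounds, mask, normalize=False)
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            # null sample: follows the consensus with sub-sigma smooth deviation
            sn = smooth_noise(r)
            sn /= sn.std()
            values = ens.mu["c"] + 0.5 * ens.sigma["c"] * sn
            sample = DenseTrack(layout, {"c": values.clip(0)})
            z = zscore_track(sample, ens)
            regions = call_significant_regions(z, sample, fdr=0.05, min_coverage=0)
            hits += bool(regions)
        assert hits / 50 <= 0.3

    def test_regions_lie_within_mask(self):
        rng = np.random.default_rng(13)
        layout = GenomeLayout((("c", 10_000),))
        mask = IntervalSet([Interval("c", 2_000, 8_000)], layout)
        backgrounds = [
            DenseTrack(layout, {"c": rng.normal(5, 1, 10_000).clip(0)})
            for _ in range(20)
        ]
        ens = ensemble_stats(backgrounds, mask, normalize=False)
        sample = DenseTrack(layout, {"c": np.full(10_000, 50.0)})
        z = zscore_track(sample, ens)
        regions = call_significant_regions(z, sample, fdr=0.05)
        assert regions  # massive deviation inside the mask
        for r in regions:
            assert r.start >= 2_000 and r.end <= 8_000
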