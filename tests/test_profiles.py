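import numpy as np
import pandas as pd
import pytest

from methpath.coverage import EnrichmentTrack
from methpath.io import FeatureInterval, SizedReadSet
from methpath.profiles import (
    autocorrelate,
    dyad_profile,
    ends_profile,
    estimate_nrl,
    phasing_profile,
)


def _uniform_track(value=1.0, n_bins=100, width=100, kind="raw"):
    return EnrichmentTrack(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_bins) * width,
                "end": (np.arange(n_bins) + 1) * width,
                "value": value,
            }
        ),
        value_kind=kind,
    )


class TestEndsProfile:
    def test_uniform_signal_gives_flat_metaplot(self):
        track = _uniform_track(1.0)
        feats = [FeatureInterval("chr1", 3000, 4000, "+", "a"),
                 FeatureInterval("chr1", 6000, 7500, "-", "b")]
        prof = ends_profile(track, feats, flank_bp=500, bin_bp=100)
        assert np.allclose(prof.five_prime["mean"], 1.0)
        assert np.allclose(prof.three_prime["mean"], 1.0)

    def test_rpkm_cap_excludes_hot_bins(self):
        track = _uniform_track(1.0, kind="rpkm")
        track.bins.loc[30, "value"] = 500.0  # bin [3000,3100) right at a 5' end
        feats = [FeatureInterval("chr1", 3000, 4000, "+", "a"),
                 FeatureInterval("chr1", 6000, 7000, "+", "b")]
        prof = ends_profile(track, feats, flank_bp=500, bin_bp=100, rpkm_cap=200)
        first_inside = prof.five_prime[prof.five_prime["offset"] == 0].iloc[0]
        assert first_inside["n"] == 1  # the 500-rpkm bin was dropped
        assert first_inside["mean"] == pytest.approx(1.0)

    def test_cap_ignored_for_non_rpkm_tracks(self):
        track = _uniform_track(1.0, kind="log2ratio")
        track.bins.loc[30, "value"] = 500.0
        feats = [FeatureInterval("chr1", 3000, 4000, "+", "a")]
        prof = ends_profile(track, feats, flank_bp=500, bin_bp=100, rpkm_cap=200)
        assert prof.five_prime[prof.five_prime["offset"] == 0]["n"].iloc[0] == 1

    def test_minus_strand_feature_aligns_with_plus(self):
        # signal step: high inside each feature, zero outside
        bins = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(200) * 100,
                "end": (np.arange(200) + 1) * 100,
                "value": 0.0,
            }
        )
        bins.loc[30:39, "value"] = 2.0  # [3000,4000) plus-strand feature body
        bins.loc[60:69, "value"] = 2.0  # [6000,7000) minus-strand feature body
        track = EnrichmentTrack(bins, "raw")
        plus = ends_profile(track, [FeatureInterval("chr1", 3000, 4000, "+", "a")],
                            flank_bp=500, bin_bp=100)
        minus = ends_profile(track, [FeatureInterval("chr1", 6000, 7000, "-", "b")],
                             flank_bp=500, bin_bp=100)
        assert np.allclose(plus.five_prime["mean"], minus.five_prime["mean"])

    def test_short_features_skipped_and_counted(self):
        track = _uniform_track()
        feats = [FeatureInterval("chr1", 3000, 3050, "+", "tiny"),
                 FeatureInterval("chr1", 5000, 6000, "+", "ok")]
        prof = ends_profile(track, feats, flank_bp=500, bin_bp=100)
        assert prof.n_skipped == 1 and prof.n_features == 1


class TestDyadProfile:
    def test_reads_at_fixed_offset_occupy_one_bin(self):
        dyads = [FeatureInterval("chr1", p, p + 1, "+", f"d{p}") for p in (5000, 9000)]
        starts = [p + 85 for p in (5000, 9000)]
        reads = SizedReadSet(["chr1"] * 2, starts, [s + 24 for s in starts])
        offsets, mean = dyad_profile(reads, dyads, window_bp=200, bin_bp=10)
        hot = offsets[mean > 0]
        assert hot.tolist() == [80]

    def test_empty_reads_not_allowed_but_zero_profile_for_far_dyads(self):
        dyads = [FeatureInterval("chr1", 5000, 5001, "+", "d")]
        far = SizedReadSet(["chr1"] * 3, [100, 130, 160], [124, 154, 184])
        offsets, mean = dyad_profile(far, dyads, window_bp=200, bin_bp=10)
        assert np.all(mean == 0)
        with pytest.raises(ValueError, match="no dyads"):
            dyad_profile(far, [], window_bp=200, bin_bp=10)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(1000, 20_000, 300)
        reads = SizedReadSet(["chr1"] * 300, pos, pos + 24)
        dyads = [FeatureInterval("chr1", p, p + 1, "+", f"d{i}")
                 for i, p in enumerate(range(2000, 18_000, 180))]
        shift = 5_000
        reads2 = SizedReadSet(["chr1"] * 300, pos + shift, pos + shift + 24)
        dyads2 = [FeatureInterval("chr1", d.start + shift, d.end + shift, "+", d.id)
                  for d in dyads]
        _, m1 = dyad_profile(reads, dyads, window_bp=500, bin_bp=10)
        _, m2 = dyad_profile(reads2, dyads2, window_bp=500, bin_bp=10)
        assert np.allclose(m1, m2)


class TestAutocorrelation:
    def test_periodic_signal_peaks_at_its_period(self):
        v = np.cos(2 * np.pi * np.arange(100) / 17)
        acf = autocorrelate(v, max_lag=40)
        assert acf[0] == pytest.approx(1.0)
        k = np.argmax(acf[10:25]) + 10
        assert k == 17

    def test_acf_bounded_and_unit_at_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=150)
        acf = autocorrelate(v, max_lag=30)
        assert acf[0] == 1.0
        assert np.all(np.abs(acf) <= 1 + 1e-12)

    def test_white_noise_stays_inside_band(self):
        n, hits, trials = 200, 0, 40
        for seed in range(trials):
            v = np.random.default_rng(seed).normal(size=n)
            acf = autocorrelate(v, max_lag=10)
            hits += np.sum(np.abs(acf[1:]) > 1.96 / np.sqrt(n))
        # 10 lags x 40 trials, ~5% expected outside the band
        assert hits / (10 * trials) < 0.12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            autocorrelate(np.ones(50), max_lag=5)


class TestNRL:
    def test_period_17_bins_at_10bp_is_170(self):
        v = np.cos(2 * np.pi * np.arange(200) / 17)
        acf = autocorrelate(v, max_lag=40)
        est = estimate_nrl(acf, bin_bp=10)
        assert est.peak_lag == 17
        assert est.nrl_bp == pytest.approx(170, abs=3)
        assert estimate_nrl(acf, bin_bp=10, refine=False).nrl_bp == 170

    def test_flat_acf_is_undefined(self):
        acf = np.zeros(41)
        acf[0] = 1.0
        est = estimate_nrl(acf, bin_bp=10)
        assert not est.defined and "no local maximum" in est.reason

    def test_search_range_must_be_covered(self):
        v = np.cos(2 * np.pi * np.arange(100) / 17)
        acf = autocorrelate(v, max_lag=10)
        with pytest.raises(ValueError, match="search range"):
            estimate_nrl(acf, bin_bp=10)

    @pytest.mark.parametrize("nrl", [160, 190])
    def test_simulated_phased_reads_recover_repeat_length(self, nrl):
        """Reads biased to linkers of dyads tiled at repeat length R give an
        NRL estimate within +/-10 bp of R."""
        rng = np.random.default_rng(nrl)
        n_dyads = 2500
        dyad_pos = np.cumsum(np.full(n_dyads, nrl)) + 1000
        dyad_pos = dyad_pos + np.rint(rng.normal(0, 10, n_dyads)).astype(int)
        dyads = [FeatureInterval("chr1", int(p), int(p) + 1, "+", f"d{i}")
                 for i, p in enumerate(dyad_pos)]
        # sample read 5' ends preferentially from linker midpoints
        linker_mid = (dyad_pos[:-1] + dyad_pos[1:]) // 2
        choice = rng.choice(linker_mid, size=40_000)
        jitter = rng.integers(-(nrl - 147) // 2, (nrl - 147) // 2 + 1, size=40_000)
        starts = choice + jitter
        reads = SizedReadSet(["chr1"] * len(starts), starts, starts + 24)
        prof = phasing_profile(reads, dyads, window_bp=1000, bin_bp=10)
        assert prof.nrl.defined
        assert abs(prof.nrl.nrl_bp - nrl) <= 10
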