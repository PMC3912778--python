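import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ehgkit.detection import SegmentCandidate
from ehgkit.envelopes import tocolike
from ehgkit.features import (
    BaselineReference,
    FeatureError,
    extract_baseline_reference,
    featurize,
    sample_entropy,
    spectral_band_ratios,
    temporal_features,
)
from ehgkit.preprocessing import preprocess
from ehgkit.synthesis import SynthesisConfig, band_noise, synthesize_recording

FS = 20.0


def brute_force_sampen(x, m=3, r=0.15):
    """Independent template-counting oracle built on scipy.cdist."""
    x = np.asarray(x, float)
    tol = r * x.std()
    n_t = x.size - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_t]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    d_m = cdist(emb_m, emb_m, metric="chebyshev")
    d_m1 = cdist(emb_m1, emb_m1, metric="chebyshev")
    iu = np.triu_indices(n_t, k=1)
    b = np.sum(d_m[iu] <= tol)
    a = np.sum(d_m1[iu] <= tol)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


class TestSpectralBandRatios:
    @pytest.mark.parametrize("freq, dominant", [(0.5, 1), (2.0, 2)],
                             ids=["tone-0.5Hz->E2", "tone-2Hz->E3"])
    def test_pure_tones(self, freq, dominant):
        t = np.arange(int(60 * FS)) / FS
        e = spectral_band_ratios(np.sin(2 * np.pi * freq * t), FS)
        assert e[dominant] > 0.95
        assert sum(e) == pytest.approx(1.0, abs=1e-9)

    def test_normalization_on_random_segments(self, rng):
        for _ in range(20):
            x = rng.standard_normal(int(rng.integers(600, 2000)))
            e = spectral_band_ratios(x, FS)
            assert sum(e) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= v <= 1.0 for v in e)

    def test_band_limited_white_noise_fractions(self, rng):
        # flat spectrum over 0.1-4 Hz -> fractions proportional to bandwidth
        n = 40_000
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / FS)
        spec[(f < 0.1) | (f > 4.0)] = 0.0
        x = np.fft.irfft(spec, n)
        e1, e2, e3 = spectral_band_ratios(x, FS)
        assert e1 == pytest.approx(0.2 / 3.9, abs=0.03)
        assert e2 == pytest.approx(0.7 / 3.9, abs=0.03)
        assert e3 == pytest.approx(3.0 / 3.9, abs=0.03)

    def test_zero_segment_flagged(self):
        with pytest.raises(FeatureError, match="E1"):
            spectral_band_ratios(np.zeros(600), FS)


class TestTemporalFeatures:
    def ref(self, rng, sd=2.0):
        return BaselineReference(samples=sd * rng.standard_normal(5000))

    def test_sine_closed_forms(self, rng):
        t = np.arange(10_000) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        sigma_x, ra, kappa, md_bs, md_x, r_rms = temporal_features(x, self.ref(rng))
        assert ra == pytest.approx(2 * np.sqrt(2), abs=0.05)
        assert kappa == pytest.approx(1.5, abs=0.05)

    def test_gaussian_kurtosis(self, rng):
        x = rng.standard_normal(10_000)
        _, _, kappa, *_ = temporal_features(x, self.ref(rng))
        assert kappa == pytest.approx(3.0, abs=0.2)

    def test_identities_when_segment_is_reference(self, rng):
        ref = self.ref(rng)
        sigma_x, ra, kappa, md_bs, md_x, r_rms = temporal_features(ref.samples, ref)
        assert r_rms == pytest.approx(1.0)
        assert md_bs == pytest.approx(md_x * sigma_x / ref.sigma_bs)

    def test_scale_behaviour(self, rng):
        ref = self.ref(rng)
        x = rng.standard_normal(2000)
        f1 = temporal_features(x, ref)
        f5 = temporal_features(5 * x, ref)
        # sigma_x and MD_bs scale linearly; RA, kappa, MD_x are invariant
        assert f5[0] == pytest.approx(5 * f1[0])
        assert f5[3] == pytest.approx(5 * f1[3])
        assert f5[1] == pytest.approx(f1[1])
        assert f5[2] == pytest.approx(f1[2])
        assert f5[4] == pytest.approx(f1[4])

    def test_zero_variance_flagged(self, rng):
        with pytest.raises(FeatureError, match="sigma_x"):
            temporal_features(np.ones(100), self.ref(rng))


class TestSampleEntropy:
    def test_periodic_series_is_regular(self):
        x = np.tile([0.0, 1.0, 2.0, 1.0], 100)
        assert sample_entropy(x) < 0.05

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(500)
        assert sample_entropy(x) == pytest.approx(sample_entropy(10 * x), abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(400)
            assert sample_entropy(x) == pytest.approx(
                brute_force_sampen(x), abs=1e-12
            )

    def test_no_matches_is_infinite(self):
        # linear ramp with tolerance below the step: no template pair matches
        x = np.arange(30.0)
        assert sample_entropy(x, m=2, r=0.01) == np.inf

    def test_too_short_flagged(self):
        with pytest.raises(FeatureError, match="En"):
            sample_entropy(np.arange(4.0), m=3)


class TestBaselineReference:
    def _quiet_recording(self, seed=3):
        cfg = SynthesisConfig(duration_s=600.0, rng_seed=seed,
                              contraction_rate=0.0, artifact_rate=0.0)
        rec, _ = synthesize_recording(cfg)
        return preprocess(rec)

    def test_quiet_recording_reference_matches_global_sd(self):
        bip = self._quiet_recording()
        x = bip.channel("B1")
        env = tocolike(x, bip.fs, "rms")
        ref = extract_baseline_reference(x, bip.fs, env)
        inner = x[int(30 * bip.fs) : -int(30 * bip.fs)]
        assert ref.sigma_bs == pytest.approx(np.std(inner), rel=0.10)

    def test_artifact_samples_excluded(self):
        cfg = SynthesisConfig(duration_s=600.0, rng_seed=5,
                              contraction_rate=0.0, artifact_rate=6.0,
                              artifact_types=("hf_burst",))
        rec, gt = synthesize_recording(cfg)
        bip = preprocess(rec)
        x = bip.channel("B1")
        env = tocolike(x, bip.fs, "rms")
        ref = extract_baseline_reference(x, bip.fs, env)
        ev = gt.artifacts()[0]
        burst = x[int(ev.onset_s * bip.fs) : int(ev.offset_s * bip.fs)]
        # reference SD reflects quiet signal, far below the burst amplitude
        assert ref.sigma_bs < 0.3 * np.std(burst)

    def test_zero_signal_rejected(self):
        env = tocolike(np.zeros(int(600 * FS)), FS, "rms", prefilter=False)
        with pytest.raises((FeatureError, ValueError)):
            extract_baseline_reference(np.zeros(int(600 * FS)), FS, env)


class TestFeaturize:
    def test_deterministic_given_seed(self, rng):
        x = band_noise(np.random.default_rng(0), 1200, FS, 0.1, 4.0)
        seg = SegmentCandidate(channel="B1", method="rms", onset_s=0.0,
                               offset_s=60.0, samples=x, fs=FS)
        ref = BaselineReference(samples=rng.standard_normal(2000))
        f1 = featurize(seg, ref, n_surrogates=10, seed=77)
        f2 = featurize(seg, ref, n_surrogates=10, seed=77)
        assert f1.as_dict() == f2.as_dict()

    def test_zero_variance_names_feature(self, rng):
        seg = SegmentCandidate(channel="B1", method="rms", onset_s=0.0,
                               offset_s=60.0, samples=np.ones(1200), fs=FS)
        ref = BaselineReference(samples=rng.standard_normal(2000))
        with pytest.raises(FeatureError):
            featurize(seg, ref, n_surrogates=5, seed=1)
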