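"""Sway statistics: preprocessing, closed forms, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_sway_features
from conftest import random_stabilogram
from swaylift.sway_features import (
    FEATURE_NAMES,
    DegenerateSignalError,
    FeatureError,
    Stabilogram,
    compute_feature_vector,
    frequency_domain_features,
    make_stabilogram,
    power_spectral_density,
    resultant_distance,
    spectral_moment,
    time_domain_features,
)


def all_features(stab):
    td = time_domain_features(stab)
    fd = frequency_domain_features(stab, td)
    return {**{k: v for k, v in td.items() if k != "TOTEX"}, **fd}


class TestMakeStabilogram:
    def test_channels_are_mean_removed(self):
        rng = np.random.default_rng(0)
        stab = make_stabilogram(*rng.standard_normal((2, 1280)), fs_in=128.0)
        assert abs(stab.ap.mean()) < 1e-9
        assert abs(stab.ml.mean()) < 1e-9

    def test_output_rate_arithmetic(self):
        stab = make_stabilogram(np.ones(1280), np.ones(1280), fs_in=128.0)
        assert abs(stab.n - 200) <= 1
        assert stab.fs == 20.0

    def test_passband_tone_survives_stopband_tone_dies(self):
        t = np.arange(1280) / 128.0
        keep = make_stabilogram(np.sin(2 * np.pi * 2 * t), np.zeros_like(t), 128.0)
        core = keep.ap[40:-40]
        assert np.abs(core).max() == pytest.approx(1.0, rel=0.05)
        kill = make_stabilogram(np.sin(2 * np.pi * 8 * t), np.zeros_like(t), 128.0)
        assert 20 * np.log10(np.abs(kill.ap[40:-40]).max()) < -20

    def test_short_segment_rejected(self):
        with pytest.raises(FeatureError):
            make_stabilogram(np.ones(100), np.ones(100), fs_in=128.0)

    def test_unequal_segments_rejected(self):
        with pytest.raises(FeatureError):
            make_stabilogram(np.ones(300), np.ones(299), fs_in=128.0)


class TestResultantDistance:
    def test_three_four_five(self):
        stab = Stabilogram(np.full(10, 3.0), np.full(10, 4.0))
        assert np.allclose(resultant_distance(stab), 5.0)

    def test_sign_flip_invariant(self):
        stab = random_stabilogram(np.random.default_rng(1))
        flipped = Stabilogram(-stab.ap, -stab.ml, stab.fs)
        assert np.allclose(resultant_distance(stab), resultant_distance(flipped))


class TestClosedForms:
    def test_circle_path(self):
        # one revolution of radius r: constant RD, known velocity and area rate
        r, n, fs = 2.5, 2000, 20.0
        t0 = n / fs
        theta = 2 * np.pi * np.arange(n) / n
        stab = Stabilogram(r * np.cos(theta), r * np.sin(theta), fs)
        f = time_domain_features(stab)
        assert f["MDIST"] == pytest.approx(r, rel=1e-9)
        assert f["RMS_DIST"] == pytest.approx(r, rel=1e-9)
        assert f["RDIST"] == pytest.approx(0.0, abs=1e-9)
        assert f["MV"] == pytest.approx(2 * np.pi * r / t0, rel=1e-3)
        assert f["SA"] == pytest.approx(np.pi * r**2 / t0, rel=1e-3)

    def test_circle_mean_frequency_counts_revolutions(self):
        r, n, fs, revs = 1.0, 3000, 20.0, 3
        theta = 2 * np.pi * revs * np.arange(n) / n
        stab = Stabilogram(r * np.cos(theta), r * np.sin(theta), fs)
        fd = frequency_domain_features(stab)
        assert fd["MF"] == pytest.approx(revs / (n / fs), rel=1e-3)

    def test_pure_tone_resultant_distance(self):
        # RD oscillating at a single on-bin frequency: CF = f0, DF = 0
        n, fs, f0 = 200, 20.0, 2.0
        t = np.arange(n) / fs
        stab = Stabilogram(1.0 + 0.5 * np.sin(2 * np.pi * f0 * t), np.zeros(n), fs)
        fd = frequency_domain_features(stab)
        assert fd["CF"] == pytest.approx(f0, rel=1e-9)
        assert fd["DF"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_stabilogram_time_features_vanish_and_spectrum_degenerates(self):
        stab = Stabilogram(np.zeros(50), np.zeros(50))
        f = time_domain_features(stab)
        assert all(f[k] == 0.0 for k in f)
        with pytest.raises(DegenerateSignalError):
            frequency_domain_features(stab)


class TestSpectrum:
    def test_constant_series_has_no_retained_power(self):
        psd = power_spectral_density(np.full(64, 3.0), 20.0)
        assert np.allclose(psd.G, 0.0)

    def test_on_bin_tone_concentrates_mass(self):
        n, fs = 128, 20.0
        rd = np.sin(2 * np.pi * (fs * 8 / n) * np.arange(n) / fs)
        psd = power_spectral_density(rd, fs)
        assert psd.G.max() / psd.G.sum() > 0.99

    def test_parseval(self):
        rng = np.random.default_rng(4)
        rd = rng.standard_normal(200)
        psd = power_spectral_density(rd, 20.0)
        assert psd.G.sum() * psd.delta_f == pytest.approx(rd.var(), rel=0.01)

    def test_moments_of_single_line(self):
        from swaylift.sway_features import SpectralDensity

        psd = SpectralDensity(np.array([3.0]), np.array([7.0]), 0.1)
        assert spectral_moment(psd, 0) == pytest.approx(7.0)
        assert spectral_moment(psd, 1) == pytest.approx(21.0)
        assert spectral_moment(psd, 2) == pytest.approx(63.0)
        with pytest.raises(ValueError):
            spectral_moment(psd, 3)


class TestOracleAgreement:
    def test_features_match_direct_summation(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            stab = random_stabilogram(rng)
            ours = all_features(stab)
            ref = oracle_sway_features(stab.ap, stab.ml, stab.fs)
            for name in FEATURE_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


class TestInvariants:
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=40)
    def test_homogeneity(self, seed, scale):
        stab = random_stabilogram(np.random.default_rng(seed))
        base = all_features(stab)
        scaled = all_features(Stabilogram(scale * stab.ap, scale * stab.ml, stab.fs))
        for name in FEATURE_NAMES:
            if name in ("MF", "CF", "DF"):
                assert scaled[name] == pytest.approx(base[name], rel=1e-9)
            elif name == "SA":
                assert scaled[name] == pytest.approx(scale**2 * base[name], rel=1e-9)
            else:
                assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9)

    @given(seed=st.integers(0, 10_000), flip_ap=st.booleans(), flip_ml=st.booleans())
    @settings(derandomize=True, max_examples=40)
    def test_channel_negation_invariance(self, seed, flip_ap, flip_ml):
        stab = random_stabilogram(np.random.default_rng(seed))
        sa = -1 if flip_ap else 1
        sm = -1 if flip_ml else 1
        flipped = all_features(Stabilogram(sa * stab.ap, sm * stab.ml, stab.fs))
        base = all_features(stab)
        for name in FEATURE_NAMES:
            assert flipped[name] == pytest.approx(base[name], rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60)
    def test_bounds(self, seed):
        f = all_features(random_stabilogram(np.random.default_rng(seed)))
        assert 0.0 <= f["DF"] <= 1.0
        assert f["RMS_DIST"] >= f["MDIST"]
        assert f["RMS_DIST_AP"] >= f["MDIST_AP"]
        assert f["RMS_DIST_ML"] >= f["MDIST_ML"]
        assert f["MF"] >= 0 and f["CF"] >= 0


class TestFeatureVector:
    def test_has_exactly_fourteen_features(self):
        rng = np.random.default_rng(6)
        vec = compute_feature_vector(*rng.standard_normal((2, 512)), fs_in=128.0,
                                     label="Risk", roi_id="r0", subject_id="S01")
        assert [k for k in vec if k in FEATURE_NAMES] == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 14

    def test_equals_stagewise_composition(self):
        rng = np.random.default_rng(7)
        z, y = rng.standard_normal((2, 512))
        vec = compute_feature_vector(z, y, fs_in=128.0)
        stab = make_stabilogram(z, y, 128.0)
        ref = all_features(stab)
        for name in FEATURE_NAMES:
            assert vec[name] == pytest.approx(ref[name], rel=1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(FeatureError):
            compute_feature_vector(np.zeros(512), np.zeros(512), fs_in=128.0)
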