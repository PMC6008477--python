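import numpy as np
import pytest
from helpers_oracles import (
    naive_apen,
    naive_spectral_entropy,
    naive_turning_point_ratio,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgkit.heartrate import RRSeries
from mcgkit.preprocess import AxisSegment
from mcgkit.rhythm import (
    RHYTHM_FEATURE_NAMES,
    approximate_entropy,
    hrv_features,
    rhythm_block,
    rri_tpr,
    spectral_entropy,
    turning_point_ratio,
)

FS = 200.0


def _rrs(values):
    return RRSeries(rr=np.asarray(values, float), valid_count=len(values))


class TestHRV:
    def test_constant_intervals_give_zero(self):
        assert hrv_features(_rrs([0.8] * 8)) == (0.0, 0.0, 0.0)

    def test_alternating_intervals(self):
        # DERIVED oracle: direct median of |first differences|
        rr = [1.0, 1.1, 1.0, 1.1, 1.0, 1.1, 1.0, 1.1]
        hrv1, _, _ = hrv_features(_rrs(rr))
        assert hrv1 == pytest.approx(np.median(np.abs(np.diff(rr))))
        assert hrv1 == pytest.approx(0.1)

    def test_matches_direct_definitions(self):
        rng = np.random.default_rng(8)
        rr = rng.uniform(0.5, 1.2, size=8)
        hrv1, hrv2, hrv3 = hrv_features(_rrs(rr))
        d1 = np.diff(rr)
        assert hrv1 == pytest.approx(np.median(np.abs(d1)))
        assert hrv2 == pytest.approx(np.median(np.abs(np.diff(rr, n=2))))
        assert hrv3 == pytest.approx(np.median(np.abs(np.diff(np.abs(d1)))))

    def test_requires_three_intervals(self):
        with pytest.raises(ValueError):
            hrv_features(_rrs([0.8, 0.9]))


class TestApproximateEntropy:
    def test_matches_naive_oracle(self):
        # DERIVED oracle: direct O(n^2) loop implementation.
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2] * 3, dtype=float)
        assert approximate_entropy(x, m=2, r=0.5) == pytest.approx(
            naive_apen(x, 2, 0.5), abs=1e-12
        )

    def test_matches_naive_oracle_random(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(80)
        r = 0.2 * np.std(x)
        assert approximate_entropy(x, m=2, r=r) == pytest.approx(
            naive_apen(x, 2, r), abs=1e-12
        )

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(10)
        t = np.arange(500) / FS
        sine = np.sin(2 * np.pi * 2.0 * t)
        noise = rng.standard_normal(500) * np.std(sine)
        r = 0.2 * np.std(sine)
        assert approximate_entropy(noise, 2, r) > approximate_entropy(sine, 2, r)

    def test_rejects_nonpositive_tolerance(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.zeros(100), 2, 0.0)


class TestSpectralEntropy:
    def test_single_tone_zero_entropy(self):
        t = np.arange(2000) / FS
        assert spectral_entropy(np.sin(2 * np.pi * 5.0 * t), FS) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_two_equal_tones_log2(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 4.0 * t) + np.sin(2 * np.pi * 8.0 * t)
        assert spectral_entropy(x, FS) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_noise_above_tone_and_matches_oracle(self):
        # DERIVED oracle: naive DFT + noise floor + entropy formula.
        rng = np.random.default_rng(11)
        t = np.arange(1000) / FS
        tone = np.sin(2 * np.pi * 5.0 * t)
        noise = rng.standard_normal(1000)
        se_tone = spectral_entropy(tone, FS)
        se_noise = spectral_entropy(noise, FS)
        assert se_noise > se_tone
        assert se_noise == pytest.approx(
            naive_spectral_entropy(noise, FS), rel=1e-9
        )

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(1000)
        assert spectral_entropy(x, FS) == pytest.approx(
            spectral_entropy(123.4 * x, FS), rel=1e-12
        )

    def test_all_zero_band_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert spectral_entropy(np.zeros(1000), FS) == 0.0


class TestTurningPointRatio:
    def test_monotone_ramp_zero(self):
        assert turning_point_ratio(np.arange(100, dtype=float)) == 0.0

    def test_alternating_sequence_one(self):
        x = np.array([0.0, 1.0] * 50)
        assert turning_point_ratio(x) == 1.0

    def test_iid_noise_near_two_thirds(self):
        # DERIVED oracle: classical expectation 2/3 for an i.i.d. series,
        # Var(count) = (16n - 29) / 90
        rng = np.random.default_rng(13)
        n = 10_000
        x = rng.standard_normal(n)
        tpr = turning_point_ratio(x)
        se = np.sqrt((16 * n - 29) / 90.0) / (n - 2)
        assert abs(tpr - 2.0 / 3.0) < 3 * se

    def test_matches_naive_loop(self, random_segment):
        x = random_segment.samples
        assert turning_point_ratio(x) == pytest.approx(
            naive_turning_point_ratio(x), abs=1e-12
        )

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            turning_point_ratio(np.array([1.0, 2.0]))

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=60
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval(self, values):
        tpr = turning_point_ratio(np.asarray(values))
        assert 0.0 <= tpr <= 1.0


class TestRRITPR:
    def test_monotone_zero(self):
        assert rri_tpr(_rrs([0.7, 0.8, 0.9, 1.0])) == 0.0

    def test_alternating_one(self):
        assert rri_tpr(_rrs([0.8, 1.0] * 4)) == 1.0

    def test_random_permutation_matches_brute_force(self):
        rng = np.random.default_rng(14)
        rr = rng.permutation(np.linspace(0.6, 1.3, 8))
        assert rri_tpr(_rrs(rr)) == pytest.approx(
            naive_turning_point_ratio(rr), abs=1e-12
        )

    def test_requires_three(self):
        with pytest.raises(ValueError):
            rri_tpr(_rrs([0.8, 0.9]))


class TestRhythmBlock:
    def test_eighteen_named_features(self, normal_axis_segment, config):
        block = rhythm_block(normal_axis_segment, config)
        assert tuple(block.keys()) == RHYTHM_FEATURE_NAMES
        assert len(block) == 18
        assert all(np.isfinite(v) for v in block.values())

    def test_tpr_features_in_unit_interval(self, random_segment, config):
        block = rhythm_block(random_segment, config)
        for m in range(1, 12):
            assert 0.0 <= block[f"tpr{m:02d}"] <= 1.0
        assert 0.0 <= block["rritpr"] <= 1.0

    def test_silent_segment_imputes_zero(self, config):
        seg = AxisSegment(np.zeros(2000), FS, "accx", 0, "s")
        with pytest.warns(UserWarning):
            block = rhythm_block(seg, config)
        assert block["hr"] == 0.0
        assert block["hrv1"] == 0.0
        assert block["apent"] == 0.0
        assert len(block) == 18
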