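"""Signal primitives and the reliability pipeline against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owlspace.hrtf_io import Condition, Direction, HRIRSet, ValidationError
from owlspace.ipd_reliability import (
    FilterbankSpec,
    ReliabilityConfig,
    ReliabilityMap,
    band_ipd,
    binaural_render,
    circular_sd,
    difference_map,
    gammatone_filterbank,
    normalize_and_average,
    normalize_map,
    reliability_map,
    wrap_phase,
)

FS = 24_000.0


class TestBinauralRender:
    def test_unit_impulse_identity(self, rng):
        x = rng.standard_normal(500)
        imp = np.zeros(64)
        imp[0] = 1.0
        left, right = binaural_render(x, (imp, imp))
        np.testing.assert_allclose(left[:500], x, atol=1e-12)
        np.testing.assert_allclose(right[:500], x, atol=1e-12)
        assert left.size == 500 + 64 - 1

    def test_delayed_impulse_shifts(self, rng):
        x = rng.standard_normal(300)
        imp = np.zeros(64)
        imp[0] = 1.0
        delayed = np.zeros(64)
        delayed[7] = 1.0
        _, right = binaural_render(x, (imp, delayed))
        np.testing.assert_allclose(right[7 : 7 + 300], x, atol=1e-12)

    def test_linearity(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        ir = rng.standard_normal(32)
        la, _ = binaural_render(a, (ir, ir))
        lb, _ = binaural_render(b, (ir, ir))
        lab, _ = binaural_render(a + b, (ir, ir))
        np.testing.assert_allclose(lab, la + lb, atol=1e-10)

    def test_2d_signal_rejected(self):
        with pytest.raises(ValueError):
            binaural_render(np.zeros((2, 10)), (np.zeros(4), np.zeros(4)))


class TestGammatoneFilterbank:
    def test_default_band_count(self):
        spec = FilterbankSpec()
        assert len(spec.center_freqs_hz) == 36

    def test_tone_peaks_in_own_band(self, rng):
        spec = FilterbankSpec()
        t = np.arange(int(0.2 * FS)) / FS
        tone = np.sin(2 * np.pi * 4000.0 * t)
        bands = gammatone_filterbank(tone, spec, FS)
        power = (bands**2).mean(axis=1)
        centers = np.asarray(spec.center_freqs_hz)
        best = centers[np.argmax(power)]
        assert abs(best - 4000.0) <= 200.0
        far = np.abs(centers - 4000.0) >= 1000.0
        assert power[np.argmax(power)] >= power[far].max()

    def test_dc_rejected(self):
        spec = FilterbankSpec()
        bands = gammatone_filterbank(np.ones(2000), spec, FS)
        assert np.abs(bands[:, 1000:]).max() < 1e-2

    def test_center_above_nyquist_rejected(self):
        spec = FilterbankSpec(center_freqs_hz=(1000.0, 13_000.0))
        with pytest.raises(ValueError):
            gammatone_filterbank(np.zeros(100), spec, FS)

    def test_non_increasing_centers_rejected(self):
        with pytest.raises(ValueError):
            FilterbankSpec(center_freqs_hz=(2000.0, 1000.0))


def delayed_pair(delay_s, fs, seed=0, n=4096, band=(400.0, 10_000.0)):
    """Left/right pair where the right ear leads by ``delay_s`` (left delayed)."""
    from owlspace.synthetic_data import make_broadband_stimulus

    x = make_broadband_stimulus(band[0], band[1], n / fs, fs, seed)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    left = np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * delay_s), n)
    return left, x


class TestBandIpd:
    def test_pure_delay_quarter_cycle(self):
        fs = 48_000.0
        left, right = delayed_pair(50e-6, fs)
        ipd = band_ipd(left, right, 5000.0, fs)
        assert ipd == pytest.approx(np.pi / 2, abs=0.1)

    def test_identical_channels_zero(self, rng):
        x = rng.standard_normal(2000)
        assert band_ipd(x, x, 5000.0, FS) == pytest.approx(0.0, abs=1e-9)

    def test_wrapped_delay(self):
        # 250 us at 5 kHz is 2.5 cycles; wraps to +pi/2
        fs = 48_000.0
        left, right = delayed_pair(250e-6, fs)
        ipd = band_ipd(left, right, 5000.0, fs)
        assert ipd == pytest.approx(np.pi / 2, abs=0.15)

    def test_cross_spectrum_phase_oracle(self):
        # independent oracle: phase of the cross spectrum at f_c
        fs = 48_000.0
        for delay in (30e-6, 80e-6, 130e-6):
            left, right = delayed_pair(delay, fs, seed=2)
            ipd = band_ipd(left, right, 4000.0, fs)
            cross = np.fft.rfft(left) * np.conj(np.fft.rfft(right))
            freqs = np.fft.rfftfreq(left.size, 1 / fs)
            # L(f) R*(f) has phase -IPD under the right-ear-leads convention
            oracle = -np.angle(cross[np.argmin(np.abs(freqs - 4000.0))])
            assert ipd == pytest.approx(oracle, abs=0.1)

    def test_zero_energy_flagged(self):
        assert np.isnan(band_ipd(np.zeros(100), np.zeros(100), 5000.0, FS))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            band_ipd(np.zeros(10), np.zeros(12), 5000.0, FS)


class TestCircularSd:
    def test_equal_angles_zero(self):
        assert circular_sd([1.3, 1.3, 1.3]) == 0.0

    def test_cardinal_angles_infinite(self):
        assert circular_sd([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]) == np.inf

    def test_wrapped_normal_matches_definition_oracle(self, rng):
        angles = wrap_phase(rng.normal(0.4, 0.7, size=1000))
        # direct-definition oracle computed independently
        c, s = np.cos(angles).mean(), np.sin(angles).mean()
        rbar = np.hypot(c, s)
        expected = np.sqrt(-2 * np.log(rbar))
        assert circular_sd(angles) == pytest.approx(expected, rel=1e-12)

    def test_needs_two_angles(self):
        with pytest.raises(ValueError):
            circular_sd([0.1])

    def test_nan_ignored(self):
        assert circular_sd([0.5, 0.5, np.nan]) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-3.1, 3.1), min_size=3, max_size=20),
        st.floats(-10, 10),
    )
    def test_rotation_invariance(self, angles, rot):
        a = np.asarray(angles)
        s0 = circular_sd(a)
        s1 = circular_sd(wrap_phase(a + rot))
        if np.isfinite(s0):
            assert s1 == pytest.approx(s0, abs=1e-8)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-3.1, 3.1), min_size=3, max_size=20), st.integers(0, 1000))
    def test_permutation_invariance(self, angles, seed):
        a = np.asarray(angles)
        p = np.random.default_rng(seed).permutation(a.size)
        assert circular_sd(a[p]) == pytest.approx(circular_sd(a), abs=1e-10)


def tiny_cfg(**kw):
    defaults = dict(duration_s=0.03, n_repetitions=2, seed=0)
    defaults.update(kw)
    return ReliabilityConfig(**defaults)


SMALL_FB = FilterbankSpec(center_freqs_hz=tuple(np.arange(1000.0, 8001.0, 1000.0)))


class TestReliabilityMap:
    def test_zero_masker_uniform_epsilon_ceiling(self, small_normal_head):
        cfg = tiny_cfg(masker_amplitude=0.0)
        m = reliability_map(small_normal_head, SMALL_FB, cfg)
        np.testing.assert_allclose(m.reliability_raw, 1.0 / cfg.epsilon_sd_rad)

    def test_identical_ears_zero_sd(self):
        rng = np.random.default_rng(0)
        ir = rng.standard_normal(64)
        dirs = [Direction(a) for a in (-40.0, 0.0, 40.0)]
        s = HRIRSet(
            owl_id="sym",
            condition=Condition.SYNTHETIC_CUSTOM,
            sample_rate_hz=FS,
            directions=dirs,
            left=np.tile(ir, (3, 1)),
            right=np.tile(ir, (3, 1)),
        )
        m = reliability_map(s, SMALL_FB, tiny_cfg())
        np.testing.assert_allclose(m.raw_sd_rad, 0.0, atol=1e-9)

    def test_condition_separation_frontal_high_freq(
        self, small_normal_head, small_ruffless_head
    ):
        fb = FilterbankSpec(center_freqs_hz=tuple(np.arange(2000.0, 8001.0, 1000.0)))
        cfg = tiny_cfg(n_repetitions=3)
        mn = normalize_map(reliability_map(small_normal_head, fb, cfg))
        mr = normalize_map(reliability_map(small_ruffless_head, fb, cfg))
        f = mn.frequencies_hz
        az = mn.target_azimuths_deg
        sel = (f[:, None] > 4000) & (np.abs(az[None, :]) <= 40)
        assert mn.reliability_norm[sel].mean() > mr.reliability_norm[sel].mean()

    def test_mirrored_head_mirrors_map(self, small_normal_head):
        cfg = tiny_cfg()
        m = reliability_map(small_normal_head, SMALL_FB, cfg)
        mm = reliability_map(small_normal_head.mirrored(), SMALL_FB, cfg)
        np.testing.assert_allclose(
            mm.reliability_raw, m.reliability_raw[:, ::-1], rtol=1e-6
        )

    def test_masker_amplitude_monotone_corruption(self, small_normal_head):
        means = []
        for amp in (0.0, 0.5, 1.0):
            m = reliability_map(small_normal_head, SMALL_FB, tiny_cfg(masker_amplitude=amp))
            means.append(m.reliability_raw.mean())
        assert means[0] >= means[1] >= means[2]

    def test_determinism(self, small_normal_head):
        a = reliability_map(small_normal_head, SMALL_FB, tiny_cfg())
        b = reliability_map(small_normal_head, SMALL_FB, tiny_cfg())
        np.testing.assert_array_equal(a.reliability_raw, b.reliability_raw)

    def test_exclude_coincident_masker_runs(self, small_normal_head):
        m = reliability_map(
            small_normal_head, SMALL_FB, tiny_cfg(include_coincident_masker=False)
        )
        assert np.isfinite(m.reliability_raw).all()

    def test_no_elevation_zero_grid_rejected(self, head_params):
        from owlspace.hrtf_io import GridSpec
        from owlspace.synthetic_data import make_head_model_hrirs

        s = make_head_model_hrirs(
            head_params, "normal", GridSpec((0.0, 20.0), (30.0,)), seed=0
        )
        with pytest.raises(ValidationError):
            reliability_map(s, SMALL_FB, tiny_cfg())


def hand_map(values, freqs=(1000.0, 2000.0), azs=(0.0, 20.0)):
    values = np.asarray(values, dtype=float)
    return ReliabilityMap(
        frequencies_hz=np.asarray(freqs),
        target_azimuths_deg=np.asarray(azs),
        raw_sd_rad=1.0 / values,
        reliability_raw=values,
        provenance={"owl_ids": ["h"], "condition": "normal"},
    )


class TestNormalizeAndAverage:
    def test_single_owl_column_maxima_one(self, small_normal_head):
        m = reliability_map(small_normal_head, SMALL_FB, tiny_cfg())
        out = normalize_and_average([m])
        np.testing.assert_allclose(out.reliability_norm.max(axis=0), 1.0)

    def test_two_identical_owls_equal_either(self):
        a = hand_map([[4.0, 2.0], [1.0, 6.0]])
        b = hand_map([[4.0, 2.0], [1.0, 6.0]])
        out = normalize_and_average([a, b])
        np.testing.assert_allclose(
            out.reliability_norm, normalize_map(a).reliability_norm
        )

    def test_swapped_profiles_arithmetic_mean(self):
        # hand computation on 2x2 maps with swapped frequency profiles
        a = hand_map([[4.0, 1.0], [2.0, 2.0]])  # columns: [4,2] and [1,2]
        b = hand_map([[2.0, 2.0], [4.0, 1.0]])
        out = normalize_and_average([a, b])
        # a normalized: [[1, .5], [.5, 1]]; b normalized: [[.5, 1], [1, .5]]
        np.testing.assert_allclose(out.reliability_norm, [[0.75, 0.75], [0.75, 0.75]])

    def test_grid_mismatch_rejected(self):
        a = hand_map([[1.0, 2.0], [3.0, 4.0]])
        b = hand_map([[1.0, 2.0], [3.0, 4.0]], freqs=(1500.0, 2500.0))
        with pytest.raises(ValidationError):
            normalize_and_average([a, b])

    def test_normalized_in_unit_interval(self, small_normal_head, small_ruffless_head):
        m1 = reliability_map(small_normal_head, SMALL_FB, tiny_cfg())
        m2 = reliability_map(small_ruffless_head, SMALL_FB, tiny_cfg())
        out = normalize_and_average([m1, m2])
        assert (out.reliability_norm >= 0).all() and (out.reliability_norm <= 1).all()


class TestDifferenceMap:
    def test_self_difference_zero(self):
        a = normalize_map(hand_map([[4.0, 1.0], [2.0, 2.0]]))
        d = difference_map(a, a)
        np.testing.assert_allclose(d.reliability_norm, 0.0)

    def test_antisymmetry(self):
        a = normalize_map(hand_map([[4.0, 1.0], [2.0, 2.0]]))
        b = normalize_map(hand_map([[1.0, 3.0], [5.0, 2.0]]))
        np.testing.assert_allclose(
            difference_map(a, b).reliability_norm,
            -difference_map(b, a).reliability_norm,
        )

    def test_requires_normalized(self):
        a = hand_map([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError):
            difference_map(a, a)

    def test_grid_mismatch(self):
        a = normalize_map(hand_map([[1.0, 2.0], [3.0, 4.0]]))
        b = normalize_map(hand_map([[1.0, 2.0], [3.0, 4.0]], azs=(0.0, 40.0)))
        with pytest.raises(ValidationError):
            difference_map(a, b)


class TestWrapPhase:
    @settings(max_examples=50, deadline=None)
    @given(st.floats(-100.0, 100.0))
    def test_range_and_congruence(self, phi):
        w = float(wrap_phase(phi))
        assert -np.pi < w <= np.pi + 1e-12
        assert np.cos(w) == pytest.approx(np.cos(phi), abs=1e-6)
        assert np.sin(w) == pytest.approx(np.sin(phi), abs=1e-6)
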