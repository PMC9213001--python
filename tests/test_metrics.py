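"""Centre-of-mass, peak-time, best-frequency and PSTH metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from revadapt.metrics import (
    TemporalProfile,
    best_frequency,
    center_of_mass,
    peak_time,
    psth_com,
    rf_metrics,
    temporal_profiles,
)
from revadapt.ridge import Kernel


def _profile(v_plus=None, v_minus=None, h=20):
    vp = np.zeros(h) if v_plus is None else np.asarray(v_plus, dtype=float)
    vm = np.zeros(h) if v_minus is None else np.asarray(v_minus, dtype=float)
    return TemporalProfile(v_plus=vp, v_minus=vm)


class TestProfiles:
    def test_single_weight_arithmetic(self):
        w = np.zeros((30, 20))
        w[5, 3] = 2.0
        prof = temporal_profiles(w)
        assert prof.v_plus[3] == pytest.approx(2.0 / 30.0)
        assert np.all(prof.v_plus[np.arange(20) != 3] == 0)
        assert np.all(prof.v_minus == 0)

    def test_sign_flip_swaps_profiles(self, rng):
        w = rng.standard_normal((10, 20))
        a = temporal_profiles(w)
        b = temporal_profiles(-w)
        np.testing.assert_allclose(a.v_plus, -b.v_minus)
        np.testing.assert_allclose(a.v_minus, -b.v_plus)

    def test_rectification_identity(self, rng):
        w = rng.standard_normal((12, 20))
        prof = temporal_profiles(w)
        np.testing.assert_allclose(prof.v_plus + prof.v_minus, w.mean(axis=0))


class TestCenterOfMass:
    def test_single_bin(self):
        v = np.zeros(20)
        v[2] = 1.0  # third bin: centre (3 - 0.5) * 10 = 25 ms
        assert center_of_mass(_profile(v_plus=v), "+") == 25.0

    def test_uniform_profile(self):
        assert center_of_mass(_profile(v_plus=np.ones(20)), "+") == pytest.approx(100.0)

    def test_symmetric_pair(self):
        v = np.zeros(20)
        v[0] = v[19] = 0.5
        assert center_of_mass(_profile(v_plus=v), "+") == pytest.approx(100.0)

    def test_negative_profile_uses_magnitude(self):
        v = np.zeros(20)
        v[9] = -2.0
        assert center_of_mass(_profile(v_minus=v), "-") == pytest.approx(95.0)

    def test_zero_profile_undefined(self):
        assert np.isnan(center_of_mass(_profile(), "+"))


class TestPeakTime:
    def test_isolated_peak_bin(self):
        v = np.zeros(20)
        v[6] = 1.0  # bin centre 65 ms
        assert peak_time(_profile(v_plus=v), "+") == pytest.approx(65.0, abs=0.1)

    def test_raised_cosine_peak_recovered(self):
        t = (np.arange(20) + 0.5) * 10.0
        v = 1.0 + np.cos(2 * np.pi * (t - 95.0) / 200.0)
        assert peak_time(_profile(v_plus=v), "+") == pytest.approx(95.0, abs=0.1)

    def test_scale_invariance(self, rng):
        v = np.abs(rng.standard_normal(20))
        p1 = peak_time(_profile(v_plus=v), "+")
        p2 = peak_time(_profile(v_plus=17.3 * v), "+")
        assert p1 == p2

    def test_inhibitory_peak_is_minimum(self):
        v = np.zeros(20)
        v[11] = -3.0
        assert peak_time(_profile(v_minus=v), "-") == pytest.approx(115.0, abs=0.1)

    def test_zero_profile_undefined(self):
        assert np.isnan(peak_time(_profile(), "-"))


class TestBounds:
    """COM and PT always stay within the lag window [5, 195] ms."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_kernels_stay_in_window(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((30, 20))
        prof = temporal_profiles(w)
        for sign in "+-":
            for value in (center_of_mass(prof, sign), peak_time(prof, sign)):
                assert 5.0 <= value <= 195.0

    def test_frequency_permutation_leaves_metrics_unchanged(self, rng):
        w = rng.standard_normal((30, 20))
        perm = rng.permutation(30)
        a, b = temporal_profiles(w), temporal_profiles(w[perm])
        for sign in "+-":
            assert center_of_mass(a, sign) == pytest.approx(center_of_mass(b, sign))
            assert peak_time(a, sign) == pytest.approx(peak_time(b, sign))

    def test_com_within_contiguous_support_block(self, rng):
        v = np.zeros(20)
        v[4:9] = rng.uniform(0.1, 1.0, 5)
        com = center_of_mass(_profile(v_plus=v), "+")
        assert 45.0 <= com <= 85.0


class TestBestFrequency:
    def _kernel(self, w):
        return Kernel(
            weights=w, bias=0.0, channel_centers=np.geomspace(400, 19000, w.shape[0])
        )

    def test_peak_channel_selected(self):
        w = np.zeros((30, 20))
        w[12, 4] = 1.0
        k = self._kernel(w)
        assert best_frequency(k) == pytest.approx(k.channel_centers[12])

    def test_tie_resolves_to_lower_frequency(self):
        w = np.zeros((30, 20))
        w[8, 2] = w[20, 5] = 1.0
        k = self._kernel(w)
        assert best_frequency(k) == pytest.approx(k.channel_centers[8])

    def test_constant_boost_moves_bf_only_if_global(self):
        w = np.zeros((30, 20))
        w[10, 3] = 1.0
        w[22, 6] = 0.8
        k = self._kernel(w)
        assert best_frequency(k) == pytest.approx(k.channel_centers[10])
        w2 = w.copy()
        w2[22] += 0.5  # now channel 22 peaks at 1.3
        assert best_frequency(self._kernel(w2)) == pytest.approx(k.channel_centers[22])

    def test_no_positive_weight_undefined(self):
        w = -np.ones((30, 20))
        assert np.isnan(best_frequency(self._kernel(w)))

    def test_rf_metrics_bundle(self, rng):
        w = rng.standard_normal((30, 20))
        m = rf_metrics(self._kernel(w))
        assert np.isfinite(m.com_plus) and np.isfinite(m.com_minus)


class TestPsthCom:
    def test_all_rate_in_first_bin(self):
        r = np.zeros(20)
        r[0] = 4.0
        assert psth_com(r) == pytest.approx(5.0)

    def test_uniform_rate(self):
        assert psth_com(np.ones(10)) == pytest.approx(50.0)

    def test_slower_decay_has_larger_com(self):
        t = np.arange(10)
        fast = np.exp(-t / 1.5)
        slow = np.exp(-t / 4.0)
        assert psth_com(slow) > psth_com(fast)

    def test_zero_rate_undefined(self):
        assert np.isnan(psth_com(np.zeros(10)))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            psth_com(np.array([1.0, -0.1, 0.0]))


class TestProfileProperties:
    """Invariants over arbitrary kernels, via hypothesis."""

    kernels = hnp.arrays(
        float,
        (8, 20),
        elements=st.floats(-5, 5, allow_nan=False, allow_infinity=False),
    )

    @given(kernels)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metrics_bounded_and_scale_invariant(self, w):
        prof = temporal_profiles(w)
        for sign in "+-":
            com = center_of_mass(prof, sign)
            pt = peak_time(prof, sign)
            for v in (com, pt):
                assert np.isnan(v) or 5.0 <= v <= 195.0
            scaled = temporal_profiles(3.7 * w)
            c2 = center_of_mass(scaled, sign)
            if not np.isnan(com):
                assert c2 == pytest.approx(com, rel=1e-9)

    @given(kernels)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rectification_decomposition(self, w):
        prof = temporal_profiles(w)
        assert np.all(prof.v_plus >= 0)
        assert np.all(prof.v_minus <= 0)
        np.testing.assert_allclose(
            prof.v_plus + prof.v_minus, w.mean(axis=0), atol=1e-12
        )
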