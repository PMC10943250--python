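import numpy as np
import pytest

from polholo.phase_scan import PolarizationMap
from polholo.wavelet import (
    ScaleStatistics,
    SeparationNotFoundError,
    WaveletField,
    cwt_row,
    mhat,
    scale_statistics,
    select_discriminative_scales,
    wavelet_map,
)


def brute_force_cwt(signal, scale, support=8.0):
    """Independent Riemann-sum oracle with symmetric (edge-repeating) extension."""
    n = len(signal)
    k = int(np.ceil(support * scale))
    idx = np.arange(-k, n + k)
    # symmetric extension (edge-repeating), tiled: triangular map of period 2n
    m = np.mod(idx, 2 * n)
    refl = np.where(m < n, m, 2 * n - 1 - m)
    ext = np.asarray(signal, float)[refl]
    out = np.empty(n)
    for b in range(n):
        total = 0.0
        for j, x in enumerate(idx):
            total += ext[j] * mhat((x - b) / scale)
        out[b] = total / np.sqrt(scale)
    return out


class TestMhat:
    def test_unit_at_zero(self):
        assert mhat(0.0) == 1.0

    def test_zero_crossings(self):
        assert mhat(1.0) == pytest.approx(0, abs=1e-15)
        assert mhat(-1.0) == pytest.approx(0, abs=1e-15)

    def test_zero_mean(self):
        x = np.linspace(-10, 10, 200001)
        assert np.trapezoid(mhat(x), x) == pytest.approx(0, abs=1e-8)


class TestCwtRow:
    def test_constant_signal_zero(self):
        out = cwt_row(np.full(64, 3.7), [2, 4, 8])
        assert np.abs(out).max() < 1e-8

    def test_impulse_sifting(self):
        n, b0, a = 128, 64, 5.0
        sig = np.zeros(n)
        sig[b0] = 1.0
        out = cwt_row(sig, [a])[0]
        b = np.arange(n)
        interior = (b > 20) & (b < n - 20)
        expect = mhat((b0 - b) / a) / np.sqrt(a)
        np.testing.assert_allclose(out[interior], expect[interior], atol=1e-10)

    def test_brute_force_oracle(self, rng):
        sig = rng.normal(size=64)
        scales = [2, 4, 8, 16 - 0.5]  # 16 would be excluded at length 64
        out = cwt_row(sig, scales)
        for i, a in enumerate(scales):
            np.testing.assert_allclose(out[i], brute_force_cwt(sig, a), atol=1e-8)

    def test_gaussian_bump_scale_selectivity(self):
        # |W(a, center)| maximal within one grid step of the dense-sweep optimum
        n, sigma = 512, 6.0
        x = np.arange(n)
        sig = np.exp(-((x - n // 2) ** 2) / (2 * sigma**2))
        coarse = np.arange(2.0, 40.0)
        vals = [abs(cwt_row(sig, [a])[0][n // 2]) for a in coarse]
        a_best = coarse[int(np.argmax(vals))]
        dense = np.arange(2.0, 40.0, 0.1)
        dvals = [abs(cwt_row(sig, [a])[0][n // 2]) for a in dense]
        a_opt = dense[int(np.argmax(dvals))]
        assert abs(a_best - a_opt) <= 1.0

    def test_large_scale_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = cwt_row(np.zeros(64), [2, 40])
        assert out.shape[0] == 1

    def test_no_valid_scale_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                cwt_row(np.zeros(16), [8])

    def test_shift_covariance(self, rng):
        sig = rng.normal(size=256)
        shift = 10
        w1 = cwt_row(sig, [4])[0]
        w2 = cwt_row(np.roll(sig, shift), [4])[0]
        interior = slice(60, 200)
        np.testing.assert_allclose(np.roll(w1, shift)[interior], w2[interior], atol=1e-10)


class TestWaveletMap:
    def test_constant_map_zero(self):
        out = wavelet_map(np.full((8, 64), 1.3), scales=[2, 4])
        assert np.abs(out.coefficients).max() < 1e-8

    def test_single_row_reduction(self, rng):
        sig = rng.normal(size=64)
        wm = wavelet_map(sig[None, :], scales=[2, 4, 8])
        direct = cwt_row(sig, [2, 4, 8])
        np.testing.assert_allclose(wm.coefficients[:, 0, :], direct, atol=1e-12)

    def test_periodic_stripe_scale_tracking(self):
        # dominant |W| scale grows monotonically with the stripe period
        n = 256
        x = np.arange(n)
        dominant = []
        scales = list(range(2, 30))
        for period in (8, 16, 32):
            img = np.tile(0.3 * np.sin(2 * np.pi * x / period), (8, 1))
            wf = wavelet_map(img, scales=scales)
            power = np.mean(np.abs(wf.coefficients) ** 2, axis=(1, 2))
            dominant.append(scales[int(np.argmax(power))])
        assert dominant[0] < dominant[1] < dominant[2]

    def test_masked_fill_and_skip(self, rng):
        data = rng.normal(size=(6, 64))
        mask = np.ones_like(data, bool)
        mask[2] = False  # fully masked row -> skipped
        mask[3, :10] = False  # partially masked -> filled with row median
        pmap = PolarizationMap(alpha_map=data, beta_map=data, mask=mask, delta_t=1.0)
        wf = wavelet_map(pmap, scales=[2, 4], component="alpha")
        assert wf.skipped_rows == (2,)
        assert wf.coefficients.shape[1] == 5
        assert wf.fill_fraction == pytest.approx(10 / data.size)

    def test_all_masked_raises(self):
        pmap = PolarizationMap(
            alpha_map=np.zeros((4, 64)),
            beta_map=np.zeros((4, 64)),
            mask=np.zeros((4, 64), bool),
            delta_t=1.0,
        )
        with pytest.raises(ValueError):
            wavelet_map(pmap, scales=[2])


class TestScaleStatistics:
    def test_zero_field(self):
        wf = wavelet_map(np.zeros((4, 64)), scales=[2, 4])
        st = scale_statistics(wf)
        np.testing.assert_allclose(st.z1, 0)
        np.testing.assert_allclose(st.z2, 0)

    def test_brute_force_accumulation(self, rng):
        wf = wavelet_map(rng.normal(size=(4, 64)), scales=[2, 4, 8])
        st = scale_statistics(wf, use_magnitude=True)
        for i in range(3):
            vals = np.abs(wf.coefficients[i]).ravel()
            assert st.z1[i] == pytest.approx(sum(vals) / len(vals), abs=1e-12)
            assert st.z2[i] == pytest.approx(sum(v * v for v in vals) / len(vals), abs=1e-12)

    def test_homogeneity(self, rng):
        img = rng.normal(size=(4, 64))
        c = 2.75
        s1 = scale_statistics(wavelet_map(img, scales=[2, 4]))
        s2 = scale_statistics(wavelet_map(c * img, scales=[2, 4]))
        np.testing.assert_allclose(s2.z1, c * s1.z1, rtol=1e-12)
        np.testing.assert_allclose(s2.z2, c**2 * s1.z2, rtol=1e-12)

    def test_signed_mode_near_zero_mean(self, rng):
        wf = wavelet_map(rng.normal(size=(8, 128)), scales=[4])
        st = scale_statistics(wf, use_magnitude=False)
        assert abs(st.z1[0]) < 0.1 * np.sqrt(st.z2[0])


def synthetic_group(scales, bump_centers, n_samples, seed, amplitude=1.0):
    """Curves with programmed group separation bumps.

    Per-sample scatter is a constant offset across scales, so the pooled SD is
    flat in scale and the separation score profile is shaped by the bumps only.
    """
    rng = np.random.default_rng(seed)
    out = []
    s = np.asarray(scales, float)
    base = 0.5 + 0.01 * s
    offsets = 0.01 * rng.normal(size=n_samples)
    for k in range(n_samples):
        z1 = base + offsets[k]
        for c in bump_centers:
            z1 = z1 + amplitude * np.exp(-((s - c) ** 2) / (2 * 2.0**2))
        out.append(ScaleStatistics(scales=tuple(scales), z1=z1, z2=z1**2, group="g"))
    return out


class TestSelectDiscriminativeScales:
    def test_single_programmed_peak(self):
        scales = tuple(range(2, 61))
        a = synthetic_group(scales, [15], 6, seed=1)
        b = synthetic_group(scales, [], 6, seed=2)
        sel = select_discriminative_scales(a, b)
        assert sel.a_min == 15

    def test_two_programmed_peaks(self):
        scales = tuple(range(2, 61))
        a = synthetic_group(scales, [22, 43], 6, seed=3)
        b = synthetic_group(scales, [], 6, seed=4)
        sel = select_discriminative_scales(a, b)
        assert (sel.a_min, sel.a_max) == (22, 43)

    def test_identical_groups_none_found(self):
        scales = tuple(range(2, 21))
        a = synthetic_group(scales, [], 5, seed=5)
        b = synthetic_group(scales, [], 5, seed=5)  # identical construction
        with pytest.raises(SeparationNotFoundError):
            select_discriminative_scales(a, b, threshold=50.0)

    def test_needs_two_samples(self):
        scales = tuple(range(2, 11))
        a = synthetic_group(scales, [5], 1, seed=6)
        b = synthetic_group(scales, [], 5, seed=7)
        with pytest.raises(ValueError):
            select_discriminative_scales(a, b)


class TestWaveletFieldValidation:
    def test_scales_must_increase(self):
        with pytest.raises(ValueError):
            WaveletField(coefficients=np.zeros((2, 2, 8)), scales=(4, 2))

    def test_finite_required(self):
        c = np.zeros((1, 2, 8))
        c[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            WaveletField(coefficients=c, scales=(2,))
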