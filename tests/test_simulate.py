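"""Determinism, noise statistics and deviation models of the generator."""

import numpy as np
import pytest

from vfalin.signal_model import TissueParams, ernst_signal
from vfalin.simulate import (DeviationSpec, PhantomSpec, agar_phantom,
                             brain3c_phantom, gaussian_profile,
                             generate_phantom_volumes, generate_vfa_signals,
                             mncl2_phantom, protocol_preset,
                             slice_profile_signal)
from vfalin.transforms import rho1_from_relaxation
from vfalin.uncertainty import NoiseModel


class TestSignalGeneration:
    def test_noiseless_equals_model(self):
        angles = np.array([5.0, 20.0, 45.0, 80.0])
        tr = 0.012
        ss = generate_vfa_signals(agar_phantom(), angles, tr)
        e1 = np.exp(-tr / 2.41)
        assert np.allclose(ss.signal, ernst_signal(1.0, angles, e1), rtol=1e-12)

    def test_gaussian_noise_variance(self):
        sigma = 0.01
        angles = np.full(100_000, 20.0)
        ss = generate_vfa_signals(
            agar_phantom(), angles, 0.012, noise=NoiseModel(sigma), seed=3
        )
        clean = generate_vfa_signals(agar_phantom(), angles[:1], 0.012).signal[0]
        assert np.var(ss.signal - clean) == pytest.approx(sigma**2, rel=0.02)

    def test_rician_mean_offset_matches_exact_distribution(self):
        # oracle: exact Rician mean sigma*sqrt(pi/2)*exp(-x/2)*[(1+x)I0(x/2)
        # + x*I1(x/2)], x = S^2/sigma^2; at SNR = 50 the offset from S is
        # sigma^2/(2S), i.e. 1% of sigma
        from scipy.special import ive

        sigma, snr = 0.01, 50.0
        s_true = snr * sigma
        a = s_true**2 / (2.0 * sigma**2)
        # ive(v, z) = iv(v, z)*exp(-z) supplies the e^{-a/2} factor directly
        exact_mean = sigma * np.sqrt(np.pi / 2.0) * (
            (1.0 + a) * ive(0, a / 2.0) + a * ive(1, a / 2.0)
        )
        assert exact_mean - s_true == pytest.approx(sigma**2 / (2 * s_true), rel=0.01)

        clean = generate_vfa_signals(mncl2_phantom(), [30.0], 0.007).signal[0]
        phantom = PhantomSpec("c", 0.54, s_true / clean)
        n = 400_000
        ss = generate_vfa_signals(
            phantom, np.full(n, 30.0), 0.007, noise=NoiseModel(sigma, "rician"), seed=11
        )
        se = np.std(ss.signal) / np.sqrt(n)
        assert np.mean(ss.signal) == pytest.approx(exact_mean, abs=4 * se)

    def test_seed_reproducibility_and_mandatory_seed(self):
        angles = np.arange(2.0, 20.0)
        kw = dict(noise=NoiseModel(0.01), seed=5)
        a = generate_vfa_signals(agar_phantom(), angles, 0.012, **kw)
        b = generate_vfa_signals(agar_phantom(), angles, 0.012, **kw)
        assert np.array_equal(a.signal, b.signal)
        c = generate_vfa_signals(agar_phantom(), angles, 0.012,
                                 noise=NoiseModel(0.01), seed=6)
        assert not np.array_equal(a.signal, c.signal)
        with pytest.raises(ValueError, match="seed"):
            generate_vfa_signals(agar_phantom(), angles, 0.012, noise=NoiseModel(0.01))

    def test_high_angle_deviation_constant_and_ramp(self):
        angles = np.array([5.0, 10.0, 20.0, 30.0])
        base = generate_vfa_signals(mncl2_phantom(), angles, 0.007).signal
        dev = generate_vfa_signals(
            mncl2_phantom(), angles, 0.007,
            deviation=DeviationSpec("high_angle_multiplicative", -0.05, 15.0),
        ).signal
        assert np.allclose(dev[:2], base[:2])
        assert np.allclose(dev[2:], 0.95 * base[2:])
        ramp = generate_vfa_signals(
            mncl2_phantom(), angles, 0.007,
            deviation=DeviationSpec("high_angle_multiplicative", -0.05, 15.0, ramp=True),
        ).signal
        # ramp: deviation grows linearly toward the top angle
        assert abs(ramp[2] / base[2] - 1) < abs(ramp[3] / base[3] - 1)
        assert ramp[3] == pytest.approx(0.95 * base[3], rel=1e-12)


class TestSliceProfile:
    tissue = TissueParams(1.0, rho1_from_relaxation(0.007, 0.54))

    def test_boxcar_profile_reproduces_nonselective_signal(self):
        e1 = np.exp(-0.007 / 0.54)
        for alpha in (5.0, 20.0, 60.0):
            s = slice_profile_signal(alpha, np.ones(151), self.tissue, 0.007)
            assert s == pytest.approx(ernst_signal(1.0, alpha, e1), rel=1e-12)

    def test_tapered_profile_shifts_maximum_to_higher_angles(self):
        profile = gaussian_profile(201, fwhm=0.5)
        alphas = np.linspace(2.0, 120.0, 240)
        s2d = np.array([
            slice_profile_signal(a, profile, self.tissue, 0.007) for a in alphas
        ])
        e1 = np.exp(-0.007 / 0.54)
        s3d = ernst_signal(1.0, alphas, e1)
        assert alphas[np.argmax(s2d)] > alphas[np.argmax(s3d)]
        # and the high-angle tail shows positive bias vs the ideal curve
        assert np.all(s2d[-20:] > s3d[-20:])

    def test_sparse_profile_is_resampled(self):
        s_fine = slice_profile_signal(20.0, np.ones(151), self.tissue, 0.007)
        s_coarse = slice_profile_signal(20.0, np.ones(5), self.tissue, 0.007)
        assert s_coarse == pytest.approx(s_fine, rel=1e-10)

    def test_invalid_profiles(self):
        with pytest.raises(ValueError):
            slice_profile_signal(20.0, -np.ones(101), self.tissue, 0.007)
        with pytest.raises(ValueError):
            slice_profile_signal(20.0, np.zeros(101), self.tissue, 0.007)


class TestVolumes:
    def test_noiseless_volumes_are_exact_and_deterministic(self):
        phantom = brain3c_phantom((12, 12, 12))
        tr, angles = protocol_preset("exp4")
        a = generate_phantom_volumes(phantom, angles, tr)
        b = generate_phantom_volumes(phantom, angles, tr)
        assert np.array_equal(a.data, b.data)
        # spot-check one WM voxel against the scalar model
        idx = tuple(np.argwhere(phantom.labels == 1)[0])
        e1 = np.exp(-tr / 0.85)
        expect = ernst_signal(0.7, np.asarray(angles, float), e1)
        assert np.allclose(a.data[idx], expect, rtol=1e-12)

    def test_noisy_volumes_reproducible_per_seed(self):
        phantom = brain3c_phantom((10, 10, 10))
        tr, angles = protocol_preset("exp4")
        kw = dict(noise=NoiseModel(0.01), seed=42)
        a = generate_phantom_volumes(phantom, angles, tr, **kw)
        b = generate_phantom_volumes(phantom, angles, tr, **kw)
        assert np.array_equal(a.data, b.data)

    def test_geometry_cap(self):
        phantom = brain3c_phantom((20, 20, 20))
        tr, angles = protocol_preset("exp4")
        with pytest.raises(ValueError, match="cap"):
            generate_phantom_volumes(phantom, angles, tr, max_voxels=1000)

    def test_scalar_phantom_rejected(self):
        tr, angles = protocol_preset("exp4")
        with pytest.raises(ValueError):
            generate_phantom_volumes(agar_phantom(), angles, tr)


def test_phantom_presets_carry_reference_t1():
    assert agar_phantom().t1_s == 2.41
    assert mncl2_phantom().t1_s == 0.54
    comp = brain3c_phantom().compartments
    assert comp[1][0] == 0.85 and comp[2][0] == 1.29 and comp[3][0] == 4.58


def test_protocol_presets():
    tr3, a3 = protocol_preset("exp3")
    assert tr3 == 0.007 and len(a3) == 13 and a3[0] == 2 and a3[-1] == 36
    tr4, a4 = protocol_preset("exp4")
    assert tr4 == 0.011 and len(a4) == 16 and a4[-1] == 60
    assert [tr for tr, _ in protocol_preset("exp1")] == [0.006, 0.012, 0.024, 0.048]
    with pytest.raises(ValueError):
        protocol_preset("exp9")
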