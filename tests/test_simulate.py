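"""Projection, FBP reconstruction, noise and splitting."""

import numpy as np
import pytest
from scipy.ndimage import affine_transform

from equitomo.simulate import (
    NoiseModel,
    SplitScheme,
    TiltSeries,
    add_noise,
    bin_tilt_series,
    fbp,
    make_split_pair,
    project,
)
from equitomo.wedge import TiltScheme, make_wedge_mask, wedge_interior


def _rotate_about_y(v, theta_deg, center):
    """Real-space rotation oracle (cubic spline, explicit center)."""
    th = np.radians(theta_deg)
    rot = np.array(
        [[np.cos(th), 0, -np.sin(th)], [0, 1, 0], [np.sin(th), 0, np.cos(th)]]
    )
    rin = rot.T
    c = np.asarray(center, float)
    return affine_transform(v, rin, offset=c - rin @ c, order=3)


class TestProject:
    def test_zero_tilt_is_z_sum(self, smooth_phantom32):
        t = project(smooth_phantom32, TiltScheme(-2, 2, 2))
        oracle = smooth_phantom32.sum(axis=0)
        assert np.allclose(t.projections[1], oracle,
                           atol=1e-3 * np.abs(oracle).max())

    def test_spherical_phantom_angle_invariant(self):
        """Projections of a centered sphere agree at every tilt (1e-3)."""
        n = 32
        z, y, x = np.indices((n, n, n)) - n // 2
        v = np.exp(-(z**2 + y**2 + x**2) / (2 * 3.0**2))
        t = project(v, TiltScheme(-60, 60, 30), oversample=6)
        ref = t.projections[2]
        for p in t.projections:
            assert np.allclose(p, ref, atol=1e-3 * np.abs(ref).max())

    def test_slice_matches_realspace_rotation_oracle(self, smooth_phantom32):
        """Fourier-slice extraction vs rotate-then-sum, 2% relative."""
        n = 32
        t = project(smooth_phantom32, TiltScheme(-30, 30, 30))
        oracle = _rotate_about_y(smooth_phantom32, 30, (n // 2,) * 3).sum(axis=0)
        rel = np.linalg.norm(t.projections[2] - oracle) / np.linalg.norm(oracle)
        assert rel <= 0.02

    def test_linearity(self, smooth_phantom32):
        scheme = TiltScheme(-60, 60, 20)
        a = project(smooth_phantom32, scheme).projections
        b = project(np.roll(smooth_phantom32, 3, axis=2), scheme).projections
        ab = project(
            smooth_phantom32 + np.roll(smooth_phantom32, 3, axis=2), scheme
        ).projections
        assert np.allclose(a + b, ab, atol=1e-5 * np.abs(ab).max())


class TestFBP:
    def test_dense_full_range_recovery(self, smooth_phantom32):
        """fbp(project(v)) at dense ±90° sampling: NRMSE <= 5%."""
        t = project(smooth_phantom32, TiltScheme(-90, 90, 1))
        rec = fbp(t, smooth_phantom32.shape)
        nrmse = np.linalg.norm(rec - smooth_phantom32) / np.linalg.norm(
            smooth_phantom32
        )
        assert nrmse <= 0.05

    def test_limited_range_leaves_wedge_empty(self, smooth_phantom32, scheme60):
        t = project(smooth_phantom32, scheme60)
        rec = fbp(t, smooth_phantom32.shape)
        m = make_wedge_mask(smooth_phantom32.shape, scheme60)
        E = np.abs(np.fft.fftn(rec)) ** 2
        core = wedge_interior(m, shells=2)
        assert E[core].sum() / E.sum() <= 1e-3

    def test_zero_in_zero_out_and_shape_check(self):
        t = TiltSeries(np.zeros((5, 16, 16)), np.linspace(-60, 60, 5))
        assert np.allclose(fbp(t, (16, 16, 16)), 0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            fbp(t, (16, 16, 8))


class TestNoise:
    def test_sigma_zero_identity(self):
        t = TiltSeries(np.ones((3, 8, 8)), [-10, 0, 10])
        out = add_noise(t, NoiseModel("gaussian", 0.0, seed=1))
        assert np.array_equal(out.projections, t.projections)

    def test_gaussian_std_and_seed_independence(self):
        """MC: empirical sigma within 1% at >= 1e6 samples; seeds decorrelate."""
        t = TiltSeries(np.zeros((16, 256, 256)), np.arange(16))
        n1 = add_noise(t, NoiseModel("gaussian", 1.5, seed=3))
        assert n1.projections.std() == pytest.approx(1.5, rel=0.01)
        n2 = add_noise(t, NoiseModel("gaussian", 1.5, seed=4))
        r = np.corrcoef(n1.projections.ravel(), n2.projections.ravel())[0, 1]
        assert abs(r) < 0.01

    def test_determinism_and_unknown_kind(self):
        t = TiltSeries(np.zeros((2, 8, 8)), [0, 10])
        a = add_noise(t, NoiseModel("gaussian", 1.0, seed=5))
        b = add_noise(t, NoiseModel("gaussian", 1.0, seed=5))
        assert np.array_equal(a.projections, b.projections)
        with pytest.raises(ValueError):
            NoiseModel("salt-pepper", 1.0)

    def test_poisson_gaussian_positive_rate(self):
        t = TiltSeries(np.full((2, 32, 32), 2.0), [0, 10])
        out = add_noise(t, NoiseModel("poisson-gaussian", 0.1, gain=50, seed=6))
        assert out.projections.mean() == pytest.approx(2.0, rel=0.05)


class TestSplitting:
    def test_dose_split_means_exact(self):
        rng = np.random.default_rng(7)
        frames = rng.standard_normal((5, 4, 8, 8))
        t = TiltSeries(frames.mean(axis=1), np.arange(5), frames=frames)
        a, b = make_split_pair(t, SplitScheme("dose", split0=(0, 1), split1=(2, 3)))
        assert np.array_equal(a.projections, frames[:, :2].mean(axis=1))
        assert np.array_equal(b.projections, frames[:, 2:].mean(axis=1))
        assert a.n_angles == b.n_angles == 5

    def test_angle_split_66_tilts_gives_33_33(self):
        """A -65..+65 deg, 2 deg series has 66 tilts; parity split is 33/33."""
        scheme = TiltScheme(-65, 65, 2)
        assert len(scheme.angles) == 66
        t = TiltSeries(np.zeros((66, 4, 4)), scheme.angles)
        a, b = make_split_pair(t, SplitScheme("angle"))
        assert a.n_angles == 33 and b.n_angles == 33
        assert not set(a.angles) & set(b.angles)

    def test_excluding_two_of_ten_frames_leaves_4_4(self):
        rng = np.random.default_rng(8)
        frames = rng.standard_normal((3, 10, 4, 4))
        t = TiltSeries(frames.mean(axis=1), [-10, 0, 10], frames=frames)
        a, b = make_split_pair(
            t, SplitScheme("dose", excluded_frames=(8, 9))
        )
        assert a.frames.shape[1] == 4 and b.frames.shape[1] == 4

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitScheme("dose", split0=(0, 1), split1=(1, 2))

    def test_noise_free_dose_splits_identical(self):
        frames = np.broadcast_to(
            np.arange(16.0).reshape(1, 1, 4, 4), (2, 4, 4, 4)
        ).copy()
        t = TiltSeries(frames.mean(axis=1), [0, 10], frames=frames)
        a, b = make_split_pair(t, SplitScheme("dose"))
        assert np.array_equal(a.projections, b.projections)
        assert np.array_equal(a.projections, t.projections)


class TestBinning:
    def test_pixel_size_arithmetic(self):
        """Binning a 2.36 A series by 6 gives an effective 14.16 A pixel."""
        t = TiltSeries(np.zeros((2, 12, 12)), [0, 10], pixel_size=2.36)
        b = bin_tilt_series(t, 6)
        assert b.pixel_size == pytest.approx(14.16, abs=1e-9)
        assert b.projections.shape == (2, 2, 2)

    def test_block_average_values(self):
        p = np.arange(16.0).reshape(1, 4, 4)
        t = TiltSeries(p, [0.0])
        b = bin_tilt_series(t, 2)
        assert np.array_equal(
            b.projections[0], np.array([[2.5, 4.5], [10.5, 12.5]])
        )
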