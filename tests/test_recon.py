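"""Filtered back-projection: oracle equivalence, fidelity, invariances."""

import dataclasses

import numpy as np
import pytest

from flytomo.acquisition import DetectorModel, forward_project, simulate_flyscan
from flytomo.geometry import ScanGeometry
from flytomo.phantom import DissolutionModel, PhantomState
from flytomo.preprocess import Sinogram
from flytomo.recon import fbp_reconstruct, filter_sinogram, ramp_kernel, reconstruct_window
from flytomo.timestep import WindowSpec

from conftest import make_disc

QUIET = DetectorModel(poisson=False, read_noise_std=0.0)


def radon_sino(field, angles, pixel_size_um=1.0, t0=0.0):
    vals = np.array([forward_project(field, a, pixel_size_um=pixel_size_um) for a in angles])
    return Sinogram(vals, np.asarray(angles, float), t0 + np.arange(len(angles)) * 0.5,
                    0, pixel_size_um)


def fbp_direct_oracle(values, angles_deg, pixel_size_um, center_offset_px=0.0):
    """Independent FBP oracle: spatial-domain ramp convolution and
    per-pixel direct-summation backprojection with explicit linear
    interpolation. Shares only the mathematical conventions (pixel-center
    coordinates, trapezoid quadrature per half-turn) with the
    implementation under test, none of its code path."""
    values = np.asarray(values, float)
    n = values.shape[1]
    tau = pixel_size_um
    # full convolution with the (2n-1)-tap kernel, cropped to its center
    q = np.array(
        [np.convolve(row, ramp_kernel(n, tau))[n - 1 : 2 * n - 1] for row in values]
    ) * tau
    d_theta = np.deg2rad(angles_deg[1] - angles_deg[0])
    span = np.deg2rad(angles_deg[-1] - angles_deg[0])
    w = np.full(len(angles_deg), d_theta)
    w[0] = w[-1] = d_theta / 2.0
    w /= span / np.pi
    c = (n - 1) / 2.0
    thetas = np.deg2rad(np.asarray(angles_deg) % 360.0)
    img = np.zeros((n, n))
    for iy in range(n):
        y = (iy - c) * tau
        for ix in range(n):
            x = (ix - c) * tau
            if np.hypot(y, x) > c * tau:
                continue
            acc = 0.0
            for a in range(len(thetas)):
                pos = (x * np.cos(thetas[a]) + y * np.sin(thetas[a])) / tau + c + center_offset_px
                if pos < 0.0 or pos > n - 1:
                    continue
                j0 = int(np.floor(pos))
                fr = pos - j0
                v = (1.0 - fr) * q[a, j0]
                if j0 + 1 <= n - 1:
                    v += fr * q[a, j0 + 1]
                acc += w[a] * v
            img[iy, ix] = acc
    return img


class TestOracleEquivalence:
    @pytest.mark.parametrize("start_deg, offset", [(0.0, 0.0), (540.0, 1.5)])
    def test_matches_direct_summation(self, start_deg, offset):
        """On a small grid the FFT-filtered, vectorized FBP agrees with
        the brute-force oracle to well below 1e-6 of dynamic range."""
        n = 48
        rng = np.random.default_rng(3)
        field = make_disc(n, 15.0, 0.01) * (0.5 + rng.random((n, n)))
        angles = start_deg + np.arange(41) * 4.5  # 180 deg inclusive
        sino = radon_sino(field, angles)
        tomo = fbp_reconstruct(sino, center_offset_px=offset)
        oracle = fbp_direct_oracle(sino.values, angles, 1.0, center_offset_px=offset)
        dyn = tomo.image.max() - tomo.image.min()
        assert np.abs(tomo.image - oracle).max() < 1e-6 * dyn


class TestFbpBasics:
    def test_uniform_disc_recovered(self):
        n, r, mu = 161, 50.0, 0.01
        field = make_disc(n, r, mu)
        angles = np.arange(0, 251) * 0.72
        tomo = fbp_reconstruct(radon_sino(field, angles))
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[:n, :n]
        rr = np.hypot(yy - c, xx - c)
        assert tomo.image[rr <= r - 3].mean() == pytest.approx(mu, rel=0.05)
        assert abs(tomo.image[(rr > r + 3) & tomo.circle_mask()].mean()) < 0.05 * mu

    def test_linear_and_zero(self):
        field = make_disc(65, 20.0, 0.01)
        angles = np.arange(0, 91) * 2.0
        sino = radon_sino(field, angles)
        t1 = fbp_reconstruct(sino)
        t2 = fbp_reconstruct(Sinogram(2.5 * sino.values, sino.angles_deg,
                                      sino.times_s, 0, 1.0))
        np.testing.assert_allclose(t2.image, 2.5 * t1.image, atol=1e-15)
        zero = fbp_reconstruct(Sinogram(np.zeros_like(sino.values), sino.angles_deg,
                                        sino.times_s, 0, 1.0))
        assert np.all(zero.image == 0.0)

    def test_insufficient_span_rejected(self):
        field = make_disc(65, 20.0)
        angles = np.arange(0, 80) * 2.0  # 158 deg
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            fbp_reconstruct(radon_sino(field, angles))

    def test_non_uniform_spacing_rejected(self):
        field = make_disc(65, 20.0)
        angles = np.concatenate([np.arange(0, 60) * 2.0, 120 + np.arange(40) * 3.0])
        with pytest.raises(ValueError, match="spacing"):
            fbp_reconstruct(radon_sino(field, angles))

    @pytest.mark.parametrize("filter_name", ["ramp", "shepp-logan", "hann", "cosine"])
    def test_apodized_filters_reconstruct(self, filter_name):
        field = make_disc(65, 20.0, 0.01)
        angles = np.arange(0, 126) * 1.44
        tomo = fbp_reconstruct(radon_sino(field, angles), filter_name=filter_name)
        assert tomo.filter_name == filter_name
        assert tomo.image.max() > 0.005  # reconstructs the disc contrast

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            filter_sinogram(np.zeros((3, 16)), 1.0, "butterworth")


def _nrmse(a, b, mask):
    return np.sqrt(np.mean((a[mask] - b[mask]) ** 2)) / (b[mask].max() - b[mask].min())


class TestWindowInvariance:
    def test_any_start_angle_agrees(self):
        """Static object: windows starting at 0, 180, and 900 deg (wrapped
        mod 360) reconstruct the same image — the core correctness
        property of the sliding-window interpretation."""
        n = 96
        rng = np.random.default_rng(7)
        field = make_disc(n, 30.0, 0.01) * (0.5 + rng.random((n, n)))
        angles0 = np.arange(0, 251) * 0.72
        ref = fbp_reconstruct(radon_sino(field, angles0))
        m = ref.circle_mask()
        for start in (180.0, 540.0, 900.0):
            tomo = fbp_reconstruct(radon_sino(field, start + angles0))
            assert _nrmse(tomo.image, ref.image, m) < 1e-2

    def test_half_turn_fold(self):
        """[0, 180] and [180, 360] describe the same static object."""
        n = 96
        field = make_disc(n, 30.0, 0.01)
        angles = np.arange(0, 126) * 1.44
        a = fbp_reconstruct(radon_sino(field, angles))
        b = fbp_reconstruct(radon_sino(field, 180.0 + angles))
        assert _nrmse(b.image, a.image, a.circle_mask()) < 1e-2


class TestRoundTripFidelity:
    @staticmethod
    def _sweep(field, counts):
        n = field.shape[0]
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[:n, :n]
        mask = np.hypot(yy - c, xx - c) <= c - 2
        errs = []
        for n_ang in counts:
            angles = np.arange(n_ang) * (180.0 / (n_ang - 1))
            tomo = fbp_reconstruct(radon_sino(field, angles))
            errs.append(
                np.sqrt(np.mean((tomo.image[mask] - field[mask]) ** 2))
                / (field[mask].max() - field[mask].min())
            )
        return errs

    def test_smooth_phantom_round_trip_nrmse(self):
        """radon -> FBP on a smooth field recovers it to NRMSE << 0.05."""
        n = 64
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[:n, :n]
        field = 0.01 * np.exp(-(((yy - c - 5) ** 2 + (xx - c + 3) ** 2) / (2 * 8.0**2)))
        field[np.hypot(yy - c, xx - c) > c] = 0.0
        errs = self._sweep(field, (181,))
        assert errs[0] < 0.05

    def test_error_decreases_with_angle_count(self):
        """On a field with fine structure (rod texture), angular
        undersampling streaks dominate and the round-trip error falls
        monotonically with view count up to the desk-scale grid's
        angular Nyquist (~100 views for 64 px)."""
        field = PhantomState(grid_shape=(64, 64), voxel_size_um=1.0,
                             rod_period_um=8.0).base_slice()
        errs = self._sweep(field, (21, 61, 181))
        assert errs[0] > errs[1] > errs[2]


@pytest.fixture(scope="module")
def evolving_stack():
    geom = ScanGeometry(
        angular_step_deg=1.44,
        n_projections=376,  # three half-turns of 126 frames
        exposure_s=2.0,
        detector_shape=(1, 96),
        pixel_size_um=1.0,
        n_dark=3,
        n_flat=3,
    )
    state = PhantomState(
        grid_shape=(96, 96),
        voxel_size_um=1.0,
        dissolution=DissolutionModel(
            onset_s=100.0, front_speed_um_per_s=0.05, window_width_um=30.0
        ),
    )
    return state, simulate_flyscan(state, geom, QUIET, seed=4)


class TestReconstructWindow:
    def test_static_window_cavity_free(self, evolving_stack):
        state, stack = evolving_stack
        frozen = dataclasses.replace(
            state, dissolution=dataclasses.replace(state.dissolution, front_speed_um_per_s=0.0)
        )
        s2 = simulate_flyscan(frozen, stack.geom, QUIET, seed=4)
        t0 = reconstruct_window(s2, WindowSpec(0, 126))
        t1 = reconstruct_window(s2, WindowSpec(250, 126))
        diff = t0.image - t1.image
        assert np.abs(diff).max() < 0.05 * t0.image.max()

    def test_time_labels_ride_along(self, evolving_stack):
        _, stack = evolving_stack
        tomo = reconstruct_window(stack, WindowSpec(125, 126))
        assert tomo.window is not None
        assert tomo.t_mid_s == pytest.approx((125 + 62.5) * 2.0)

    def test_full_span_window_averages_down_noise(self, evolving_stack):
        """A 540-deg window averages three half-turns: its noise residual
        is strictly smaller than any single 180-deg window's."""
        state, stack = evolving_stack
        frozen = dataclasses.replace(
            state, dissolution=dataclasses.replace(state.dissolution, front_speed_um_per_s=0.0)
        )
        noisy = simulate_flyscan(frozen, stack.geom, DetectorModel(), seed=9)
        clean = simulate_flyscan(frozen, stack.geom, QUIET, seed=9)

        def resid_std(stk, spec):
            t = reconstruct_window(stk, spec)
            ref = reconstruct_window(clean, spec)
            m = t.circle_mask()
            return (t.image - ref.image)[m].std()

        full = resid_std(noisy, WindowSpec(0, 376))
        halves = [resid_std(noisy, WindowSpec(s, 126)) for s in (0, 125, 250)]
        assert all(full < h for h in halves)
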