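"""Time-parameterized attenuation phantom: enamel block under acid attack.

The phantom stands in for the real specimen — a varnished enamel block
with a small exposed window attacked by citric acid — since no real scan
data is bundled. It is a 2D disc (optionally extruded to 3D) of
"enamel" with a deterministic quasi-periodic rod/inter-rod texture,
immersed in a lower-attenuation liquid bath, inside which a dissolution
front advances inward from an exposed arc of the sample boundary at
constant speed, optionally faster along the rod direction (anisotropic
demineralization).

Everything is deterministic: the texture is a fixed pattern given the
grid and period (no random field), so phantom tests need no seeds. The
constant-speed front is the simplest kinetics reproducing the
qualitative observations (progressive grey-value loss, anisotropic
cavity); it is not chemically realistic and other laws can be plugged
in behind :class:`DissolutionModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = ["DissolutionModel", "PhantomState", "attenuation_at", "demineralized_volume"]


@dataclass(frozen=True)
class DissolutionModel:
    """Constant-speed dissolution front entering through an exposed window.

    Parameters
    ----------
    window_center_deg : float
        Angular position (deg, CCW from +x) of the exposed window's center
        on the sample boundary.
    window_width_um : float
        Arc length (um) of the exposed (unvarnished) window.
    front_speed_um_per_s : float
        Radial advance rate of the front (um/s) after onset.
    mu_dissolved_frac : float
        Residual attenuation fraction in [0, 1] inside the dissolved
        region: 0 means the lesion drops to the bath attenuation, 1 means
        no contrast change at all.
    onset_s : float
        Time (s) at which acid exposure begins; before it nothing dissolves.
    anisotropy_gain : float
        Multiplicative speed-up (>= 1) of the front along the rod
        direction, modelling preferential inter-rod dissolution.
    """

    window_center_deg: float = 90.0
    window_width_um: float = 40.0
    front_speed_um_per_s: float = 0.02
    mu_dissolved_frac: float = 0.3
    onset_s: float = 300.0
    anisotropy_gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_dissolved_frac <= 1.0:
            raise ValueError(f"mu_dissolved_frac must be in [0, 1], got {self.mu_dissolved_frac}")
        if self.front_speed_um_per_s < 0:
            raise ValueError("front_speed_um_per_s must be >= 0")
        if self.anisotropy_gain < 1.0:
            raise ValueError(f"anisotropy_gain must be >= 1, got {self.anisotropy_gain}")
        if self.window_width_um <= 0:
            raise ValueError("window_width_um must be > 0")

    def front_depth_um(self, t: float) -> float:
        """Nominal (isotropic) front depth at time ``t``: 0 before onset,
        then ``speed * (t - onset)``. Monotone non-decreasing in ``t``."""
        return max(0.0, (t - self.onset_s)) * self.front_speed_um_per_s


@dataclass(frozen=True)
class PhantomState:
    """A 2D (or extruded 3D) attenuation field evolving under dissolution.

    Attenuation is in inverse micrometers (arbitrary but consistent
    units); defaults give path integrals of order 1 through the sample so
    simulated transmittance sits in a realistic 0.2-0.6 band.

    Parameters
    ----------
    grid_shape : tuple
        (ny, nx) for a slice phantom or (nz, ny, nx) for a volume.
    voxel_size_um : float
        Voxel edge length (um).
    mu_enamel : float
        Baseline enamel attenuation (1/um) before texture modulation.
    mu_liquid : float
        Attenuation of the surrounding bath; 0 <= mu_liquid < mu_enamel,
        and also <= mu_enamel * (1 - texture_amplitude) so that
        dissolution can only ever lower a voxel's value.
    texture_amplitude : float
        Relative modulation in [0, 1) of the rod/inter-rod pattern.
    rod_period_um : float
        Spatial period of the texture (um); enamel rods are a few um apart.
    rod_angle_deg : float
        Orientation of the rod axis; also the fast direction of an
        anisotropic front.
    sample_radius_frac : float
        Sample (enamel disc) radius as a fraction of the reconstruction
        circle radius.
    support_radius_frac : float
        Radius of the liquid-filled support/bath as a fraction of the
        half-width; must be <= 1 (fully inside the reconstruction circle).
    dissolution : DissolutionModel
    """

    grid_shape: tuple[int, ...] = (160, 160)
    voxel_size_um: float = 0.78
    mu_enamel: float = 0.010
    mu_liquid: float = 0.002
    texture_amplitude: float = 0.25
    rod_period_um: float = 6.0
    rod_angle_deg: float = 25.0
    sample_radius_frac: float = 0.72
    support_radius_frac: float = 0.95
    dissolution: DissolutionModel = field(default_factory=DissolutionModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_liquid < self.mu_enamel:
            raise ValueError(
                f"need 0 <= mu_liquid < mu_enamel, got {self.mu_liquid}, {self.mu_enamel}"
            )
        if not 0.0 <= self.texture_amplitude < 1.0:
            raise ValueError(f"texture_amplitude must be in [0, 1), got {self.texture_amplitude}")
        if self.mu_liquid > self.mu_enamel * (1.0 - self.texture_amplitude):
            raise ValueError(
                "mu_liquid exceeds the darkest enamel voxel "
                f"({self.mu_enamel * (1 - self.texture_amplitude):.4g}); "
                "dissolution would raise attenuation somewhere"
            )
        if not 0.0 < self.support_radius_frac <= 1.0:
            raise ValueError("support_radius_frac must be in (0, 1]")
        if not 0.0 < self.sample_radius_frac <= 1.0:
            raise ValueError("sample_radius_frac must be in (0, 1]")
        if len(self.grid_shape) not in (2, 3):
            raise ValueError(f"grid_shape must be 2D or 3D, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))

    # -- geometry helpers ---------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.grid_shape[-2:]

    @property
    def half_width_um(self) -> float:
        n = min(self.slice_shape)
        return (n - 1) / 2.0 * self.voxel_size_um

    @property
    def sample_radius_um(self) -> float:
        return self.sample_radius_frac * self.support_radius_frac * self.half_width_um

    @property
    def voxel_volume(self) -> float:
        """um^2 for a 2D phantom, um^3 for 3D."""
        return self.voxel_size_um ** self.ndim

    def _coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered (y, x) coordinate grids in um for one slice."""
        ny, nx = self.slice_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size_um
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size_um
        return np.meshgrid(y, x, indexing="ij")

    # -- base (t = 0) field -------------------------------------------------

    def texture(self) -> np.ndarray:
        """Deterministic rod/inter-rod pattern in [-1, 1] on one slice.

        Sum of two oblique sinusoids, amplified and softly saturated by
        clipping, giving quasi-periodic bands that reach the extremes +-1
        on plateaus (so the voxelwise maximum of the textured field is
        exactly ``mu_enamel * (1 + texture_amplitude)``).
        """
        yy, xx = self._coords_um()
        a = np.deg2rad(self.rod_angle_deg)
        u1 = (xx * np.cos(a) + yy * np.sin(a)) * (2 * np.pi / self.rod_period_um)
        # second sinusoid oblique to the first, incommensurate period
        a2 = a + np.deg2rad(67.0)
        u2 = (xx * np.cos(a2) + yy * np.sin(a2)) * (2 * np.pi / (self.rod_period_um * 1.6180339887))
        raw = 0.5 * (np.sin(u1) + np.sin(u2))
        return np.clip(2.0 * raw, -1.0, 1.0)

    def base_slice(self) -> np.ndarray:
        """Attenuation of one slice at t = 0 (float64, 1/um)."""
        yy, xx = self._coords_um()
        r = np.hypot(xx, yy)
        mu = np.zeros(self.slice_shape)
        bath = r <= self.support_radius_frac * self.half_width_um
        mu[bath] = self.mu_liquid
        sample = r <= self.sample_radius_um
        tex = self.mu_enamel * (1.0 + self.texture_amplitude * self.texture())
        mu[sample] = tex[sample]
        return mu

    # -- dissolution geometry ----------------------------------------------

    def _dissolved_mask(self, t: float) -> np.ndarray:
        """Boolean slice mask of voxels dissolved at time ``t``.

        A voxel dissolves when (a) it lies in the enamel, (b) its boundary
        arc position falls inside the exposed window, and (c) its depth
        below the surface is within the current front depth along its
        inward direction. Anisotropy scales the admissible depth by
        ``1 + (gain - 1) * cos^2(phi - rod_angle)`` where ``phi`` is the
        voxel's boundary angle, so the front runs deepest where the inward
        normal aligns with the rods.
        """
        d = self.dissolution
        depth = d.front_depth_um(t)
        if depth <= 0.0:
            return np.zeros(self.slice_shape, dtype=bool)
        yy, xx = self._coords_um()
        r = np.hypot(xx, yy)
        phi = np.degrees(np.arctan2(yy, xx))
        rs = self.sample_radius_um
        in_sample = r <= rs
        # arc distance from the window center along the boundary
        dphi = np.abs((phi - d.window_center_deg + 180.0) % 360.0 - 180.0)
        half_arc_deg = np.degrees((d.window_width_um / 2.0) / rs)
        in_window = dphi <= half_arc_deg
        ani = 1.0 + (d.anisotropy_gain - 1.0) * np.cos(
            np.deg2rad(phi - self.rod_angle_deg)
        ) ** 2
        reached = (rs - r) <= depth * ani
        return in_sample & in_window & reached


def attenuation_at(state: PhantomState, t: float) -> np.ndarray:
    """Attenuation field at time ``t`` (deterministic, total on valid states).

    Outside the current dissolution front the field equals the t=0 field;
    inside it the attenuation drops toward the bath value,
    ``mu = mu_liquid + mu_dissolved_frac * (mu0 - mu_liquid)``.
    For a 3D state the 2D slice is extruded with a slow axial modulation
    of the texture amplitude (the dissolution window spans all slices).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    base = state.base_slice()
    mask = state._dissolved_mask(t)
    d = state.dissolution
    slc = base.copy()
    slc[mask] = state.mu_liquid + d.mu_dissolved_frac * (base[mask] - state.mu_liquid)
    if state.ndim == 2:
        return slc
    nz = state.grid_shape[0]
    # slow axial variation: scale the contrast above the bath level, keep
    # air (mu = 0) outside the support untouched
    z = np.linspace(-1.0, 1.0, nz)
    scale = 1.0 - 0.1 * z ** 2
    inside = slc > 0
    vol = np.empty(state.grid_shape)
    for k in range(nz):
        vol[k] = np.where(inside, state.mu_liquid + scale[k] * (slc - state.mu_liquid), 0.0)
    return vol


def demineralized_volume(state: PhantomState, t: float) -> float:
    """Ground-truth dissolved volume at ``t``.

    Counts voxels whose attenuation is strictly below their t=0 value and
    multiplies by the voxel volume — um^2 for 2D phantoms, um^3 for 3D.
    Monotone non-decreasing in ``t``; identically 0 up to the onset, and 0
    at all times when ``mu_dissolved_frac == 1`` (contrast-free
    dissolution changes no voxel).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    f0 = attenuation_at(state, 0.0)
    ft = attenuation_at(state, t)
    return float(np.count_nonzero(ft < f0)) * state.voxel_volume
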