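"""Index/angle/time bookkeeping for continuous-rotation (fly-scan) tomography.

In a fly scan the rotation stage never stops: projection index ``i`` maps
linearly to both the rotation angle and the wall-clock time,

    theta_i = start_angle + i * angular_step,      t_i = i * (exposure + overhead).

All angles are kept *unwrapped* (cumulative, e.g. 0..1080 deg for a
three-turn scan) so that angle order equals time order; wrapping into
[0, 360) is a separate pure function used only where periodicity matters
(the reconstructor). Timestamps refer to the start of each frame's
exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

__all__ = [
    "ScanGeometry",
    "angle_of_index",
    "time_of_index",
    "n_projections_for_range",
    "wrap_angle_deg",
]

#: Commensurability tolerance (degrees) when converting an angular range to
#: a projection count.
RANGE_TOL_DEG = 1e-9


@dataclass(frozen=True)
class ScanGeometry:
    """Full parameterization of one continuous-rotation acquisition.

    Defaults mirror a synchrotron micro-CT fly scan: 15 001 frames at an
    angular step of 0.072 deg (three full turns, 0 to 1080 deg) with 0.5 s
    exposure, 20 dark and 20 flat fields, and a 0.325 um effective pixel
    at 10x magnification.

    Parameters
    ----------
    angular_step_deg : float
        Rotation increment between consecutive frames (deg). Must be > 0.
    exposure_s : float
        Exposure time per frame (s). Must be > 0.
    overhead_s : float
        Dead time (readout etc.) per frame (s), >= 0. Default 0; real
        acquisitions typically have a small nonzero value, which is why
        total wall clock can exceed ``n_projections * exposure_s``.
    n_projections : int
        Number of frames in the scan file (>= 2).
    start_angle_deg : float
        Unwrapped angle of projection index 0.
    detector_shape : tuple of int
        (rows, cols) of the detector in pixels.
    pixel_size_um : float
        Effective pixel size at the sample plane (um).
    magnification : float
        Objective magnification. ``pixel_size_um * magnification`` is the
        native detector pitch and is invariant across objectives.
    n_dark, n_flat : int
        Counts of dark-/flat-field frames recorded at the scan start.
    """

    angular_step_deg: float = 0.072
    exposure_s: float = 0.5
    overhead_s: float = 0.0
    n_projections: int = 15_001
    start_angle_deg: float = 0.0
    detector_shape: tuple[int, int] = (1080, 1280)
    pixel_size_um: float = 0.325
    magnification: float = 10.0
    n_dark: int = 20
    n_flat: int = 20

    def __post_init__(self) -> None:
        if not self.angular_step_deg > 0:
            raise ValueError(f"angular_step_deg must be > 0, got {self.angular_step_deg}")
        if not self.exposure_s > 0:
            raise ValueError(f"exposure_s must be > 0, got {self.exposure_s}")
        if self.overhead_s < 0:
            raise ValueError(f"overhead_s must be >= 0, got {self.overhead_s}")
        if self.n_projections < 2:
            raise ValueError(f"n_projections must be >= 2, got {self.n_projections}")
        if self.magnification <= 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"detector_shape must be positive, got {self.detector_shape}")
        object.__setattr__(self, "detector_shape", (int(rows), int(cols)))

    # -- derived quantities -------------------------------------------------

    @property
    def frame_period_s(self) -> float:
        """Time between consecutive frame starts: exposure + overhead."""
        return self.exposure_s + self.overhead_s

    @property
    def total_range_deg(self) -> float:
        """Unwrapped angular span of the scan, ``(N - 1) * step``."""
        return (self.n_projections - 1) * self.angular_step_deg

    @property
    def total_duration_s(self) -> float:
        """Wall-clock duration from first frame start to last frame end."""
        return self.n_projections * self.frame_period_s

    @property
    def detector_pitch_um(self) -> float:
        """Native detector pixel pitch, ``pixel_size_um * magnification``."""
        return self.pixel_size_um * self.magnification

    def with_magnification(self, magnification: float) -> "ScanGeometry":
        """Same setup seen through a different objective lens.

        The sample-plane pixel size rescales so the native detector pitch
        stays fixed (e.g. 0.325 um at 10x becomes 0.8125 um at 4x).
        """
        pixel = self.detector_pitch_um / magnification
        return ScanGeometry(
            **{**asdict(self), "magnification": magnification, "pixel_size_um": pixel}
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector_shape"] = list(self.detector_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        if "detector_shape" in d:
            d["detector_shape"] = tuple(int(v) for v in d["detector_shape"])
        return cls(**d)


def _check_index(geom: ScanGeometry, i: int) -> None:
    if not 0 <= i < geom.n_projections:
        raise IndexError(
            f"projection index {i} out of range: valid interval is "
            f"[0, {geom.n_projections - 1}]"
        )


def angle_of_index(geom: ScanGeometry, i: int) -> float:
    """Unwrapped rotation angle (deg) of projection ``i``.

    Computed multiplicatively (``start + i * step``), never by repeated
    addition, so there is no floating-point accumulation drift.
    """
    _check_index(geom, i)
    return geom.start_angle_deg + i * geom.angular_step_deg


def time_of_index(geom: ScanGeometry, i: int) -> float:
    """Exposure-start time (s) of projection ``i``, relative to frame 0."""
    _check_index(geom, i)
    return i * geom.frame_period_s


def n_projections_for_range(geom: ScanGeometry, range_deg: float) -> int:
    """Number of frames spanning ``range_deg``, endpoints inclusive.

    Uses the fence-post convention in which both endpoint frames belong to
    the window: a 180 deg span at a 0.072 deg step holds 2501 frames. The
    range must be a whole number of angular steps.
    """
    if not range_deg > 0:
        raise ValueError(f"range_deg must be > 0, got {range_deg}")
    steps = range_deg / geom.angular_step_deg
    nearest = round(steps)
    if abs(steps - nearest) * geom.angular_step_deg > RANGE_TOL_DEG or nearest < 1:
        lo = max(1, int(np.floor(steps))) * geom.angular_step_deg
        hi = int(np.ceil(steps)) * geom.angular_step_deg
        raise ValueError(
            f"range {range_deg} deg is not a multiple of the angular step "
            f"{geom.angular_step_deg} deg; nearest commensurate ranges are "
            f"{lo} deg and {hi} deg"
        )
    return int(nearest) + 1


def wrap_angle_deg(angle_deg):
    """Wrap unwrapped angle(s) into [0, 360). Pure; accepts scalars/arrays."""
    return np.mod(angle_deg, 360.0)
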