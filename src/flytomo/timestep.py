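"""Sliding-window enumeration over a continuous-rotation scan.

This is the heart of the time-stepping interpretation of a fly scan:
one long projection sequence (e.g. 15 001 frames over 1080 deg) is
sliced into (possibly overlapping) windows that each span at least 180
deg, and every window is reconstructed as an independent tomogram
labelled with its start/mid/end times. With the disjoint layout
(stride = n_window - 1 frames) a three-turn scan yields six tomograms;
shrinking the stride toward one frame refines the nominal time step
between successive tomograms down to a single frame period, with no
change to the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .geometry import ScanGeometry, angle_of_index, time_of_index

if TYPE_CHECKING:  # pragma: no cover
    from .acquisition import ProjectionStack

__all__ = ["WindowSpec", "TomogramWindow", "enumerate_windows", "extract_window"]


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous projection subset ``[start_index, start_index + n_window)``.

    ``stride`` is the index step to the next window in an enumeration:
    ``n_window - 1`` gives the disjoint 180-deg layout in which adjacent
    windows share exactly one boundary frame; smaller strides overlap.
    """

    start_index: int
    n_window: int = 2501
    stride: int = 2500

    def __post_init__(self) -> None:
        if self.start_index < 0:
            raise ValueError(f"start_index must be >= 0, got {self.start_index}")
        if self.n_window < 2:
            raise ValueError(f"n_window must be >= 2, got {self.n_window}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    @property
    def stop_index(self) -> int:
        return self.start_index + self.n_window

    def span_deg(self, geom: ScanGeometry) -> float:
        return (self.n_window - 1) * geom.angular_step_deg

    def validate(self, geom: ScanGeometry, require_half_turn: bool = True) -> None:
        if self.stop_index > geom.n_projections:
            raise ValueError(
                f"window [{self.start_index}, {self.stop_index}) exceeds the "
                f"scan's {geom.n_projections} projections"
            )
        if require_half_turn and self.span_deg(geom) < 180.0 - 1e-9:
            raise ValueError(
                f"window spans {self.span_deg(geom):.4g} deg < 180 deg: "
                "insufficient angular coverage for reconstruction"
            )


@dataclass(frozen=True)
class TomogramWindow:
    """A window with its derived angle list and time labels.

    ``t_start_s`` is the exposure start of the first frame (the label
    convention used when reporting time differences between tomograms);
    ``t_mid_s`` — the time at the window's central frame — is the
    headline nominal time of the reconstruction, since the object keeps
    evolving during the window; ``t_end_s`` closes the interval.
    """

    spec: WindowSpec
    angles_deg: np.ndarray
    t_start_s: float
    t_mid_s: float
    t_end_s: float
    label: int = 0

    @property
    def start_angle_deg(self) -> float:
        return float(self.angles_deg[0])

    @property
    def mid_angle_deg(self) -> float:
        return float(0.5 * (self.angles_deg[0] + self.angles_deg[-1]))


def _window_from_spec(geom: ScanGeometry, spec: WindowSpec, label: int) -> TomogramWindow:
    idx = spec.start_index + np.arange(spec.n_window)
    angles = geom.start_angle_deg + idx * geom.angular_step_deg
    period = geom.frame_period_s
    return TomogramWindow(
        spec=spec,
        angles_deg=angles,
        t_start_s=spec.start_index * period,
        t_mid_s=(spec.start_index + (spec.n_window - 1) / 2.0) * period,
        t_end_s=(spec.stop_index - 1) * period + geom.exposure_s,
        label=label,
    )


def enumerate_windows(
    geom: ScanGeometry, n_window: int = 2501, stride: int = 2500
) -> list[TomogramWindow]:
    """All windows ``[s, s + n_window)`` for ``s = 0, stride, 2*stride, ...``

    Ordered by start index; the count is
    ``floor((N - n_window) / stride) + 1``. Each carries its angle list
    and start/mid/end times; ``t_mid_s`` is strictly increasing along the
    enumeration.
    """
    if n_window > geom.n_projections:
        raise ValueError(
            f"n_window ({n_window}) exceeds the scan's {geom.n_projections} projections"
        )
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n_windows = (geom.n_projections - n_window) // stride + 1
    return [
        _window_from_spec(geom, WindowSpec(k * stride, n_window, stride), label=k)
        for k in range(n_windows)
    ]


def extract_window(stack: "ProjectionStack", spec: WindowSpec) -> "ProjectionStack":
    """Sub-stack of the window's frames (numpy views, nothing re-zeroed).

    Each frame keeps its original unwrapped angle and timestamp; darks
    and flats are inherited from the parent scan, where they were
    recorded.
    """
    spec.validate(stack.geom, require_half_turn=False)
    return stack.substack(spec.start_index, spec.n_window)
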