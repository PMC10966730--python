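"""Raw frames to line-integral sinograms.

The standard normalization chain: combine the dark/flat fields
(pixelwise median by default, robust to zingers), convert each raw frame
to transmittance ``T = (P - D) / (F - D)``, take the Beer-Lambert
negative log ``p = -ln(max(T, eps))``, and assemble per-slice sinograms
carrying each projection's angle and timestamp.

Dead pixels — where the flat does not exceed the dark — are filled from
the nearest valid neighbor and recorded in a mask; the count of clamped
transmittance values is kept as a QC metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import ProjectionStack
from .timestep import WindowSpec

__all__ = ["Sinogram", "flat_dark_correct", "neg_log", "combine_fields", "assemble_sinogram"]

#: Transmittance floor before the log transform.
DEFAULT_EPS = 1e-6


@dataclass
class Sinogram:
    """Line integrals of one detector row across a projection window.

    ``values[k]`` is the corrected, log-transformed detector row at the
    window's k-th projection; ``angles_deg``/``times_s`` are that
    projection's unwrapped angle and exposure-start time.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    times_s: np.ndarray
    slice_index: int
    pixel_size_um: float
    center_offset_px: float = 0.0
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if np.any(np.diff(self.angles_deg) <= 0) or np.any(np.diff(self.times_s) <= 0):
            raise ValueError("sinogram rows must be strictly increasing in angle and time")

    @property
    def n_projections(self) -> int:
        return self.values.shape[0]

    @property
    def n_detector(self) -> int:
        return self.values.shape[1]

    @property
    def span_deg(self) -> float:
        return float(self.angles_deg[-1] - self.angles_deg[0])

    def save_tiff(self, path) -> None:
        """32-bit float TIFF with an angle/time JSON sidecar."""
        import json

        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))
        meta = {
            "slice_index": self.slice_index,
            "pixel_size_um": self.pixel_size_um,
            "center_offset_px": self.center_offset_px,
            "angles_deg": [float(a) for a in self.angles_deg],
            "times_s": [float(t) for t in self.times_s],
            "qc": self.qc,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)


def combine_fields(fields: np.ndarray, statistic: str = "median") -> np.ndarray:
    """Combine a stack of dark or flat frames into one reference image."""
    fields = np.asarray(fields, dtype=np.float64)
    if statistic == "median":
        return np.median(fields, axis=0)
    if statistic == "mean":
        return fields.mean(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}; use 'median' or 'mean'")


def flat_dark_correct(
    frame: np.ndarray, dark: np.ndarray, flat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a raw frame to transmittance ``T = (P - D) / (F - D)``.

    Pixels where the flat does not exceed the dark carry no signal
    ("dead"); their transmittance is filled from the nearest valid pixel.

    Returns
    -------
    (T, dead_mask) : transmittance image and the boolean dead-pixel mask.

    Raises
    ------
    ValueError
        On shape mismatch or if every pixel is dead.
    """
    frame = np.asarray(frame, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    flat = np.asarray(flat, dtype=np.float64)
    if frame.shape != dark.shape or frame.shape != flat.shape:
        raise ValueError(
            f"shape mismatch: frame {frame.shape}, dark {dark.shape}, flat {flat.shape}"
        )
    denom = flat - dark
    dead = denom <= 0
    if dead.all():
        raise ValueError("all detector pixels are dead (flat <= dark everywhere)")
    T = np.empty_like(frame)
    valid = ~dead
    T[valid] = (frame[valid] - dark[valid]) / denom[valid]
    if dead.any():
        # nearest-valid-neighbor fill
        idx = ndimage.distance_transform_edt(dead, return_distances=False, return_indices=True)
        T = T[tuple(idx)]
    return T, dead


def neg_log(T: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Beer-Lambert inversion ``p = -ln(max(T, eps))``; total via clamping."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    return -np.log(np.maximum(np.asarray(T, dtype=np.float64), eps))


def assemble_sinogram(
    stack: ProjectionStack,
    slice_index: int,
    window: WindowSpec | None = None,
    statistic: str = "median",
    eps: float = DEFAULT_EPS,
    center_offset_px: float = 0.0,
) -> Sinogram:
    """Corrected, log-transformed sinogram of one detector row.

    Applies dark/flat correction (reference images combined with
    ``statistic``) and the negative log to detector row ``slice_index``
    of every projection in ``window`` (default: the whole stack). Angle
    and time of each projection ride along. The number of pixels clamped
    at the transmittance floor is recorded in ``qc``.
    """
    rows, _cols = stack.detector_shape
    if not 0 <= slice_index < rows:
        raise IndexError(f"slice_index {slice_index} out of range [0, {rows - 1}]")
    if window is None:
        sub = stack
    else:
        sub = stack.substack(window.start_index, window.n_window)

    dark = combine_fields(stack.darks, statistic)[slice_index]
    flat = combine_fields(stack.flats, statistic)[slice_index]
    raw = sub.frames[:, slice_index, :]
    T, dead = flat_dark_correct(raw, np.broadcast_to(dark, raw.shape), np.broadcast_to(flat, raw.shape))
    clamped = int(np.count_nonzero(T < eps))
    values = neg_log(T, eps)
    return Sinogram(
        values=values,
        angles_deg=sub.angles_deg.copy(),
        times_s=sub.times_s.copy(),
        slice_index=slice_index,
        pixel_size_um=stack.geom.pixel_size_um,
        center_offset_px=center_offset_px,
        qc={"clamped_pixels": clamped, "dead_pixels": int(dead.any(axis=0).sum())},
    )
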