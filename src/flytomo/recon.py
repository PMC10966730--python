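"""Parallel-beam filtered back-projection for arbitrary start angles.

A quantitative FBP: sinogram rows are convolved with the band-limited
ramp kernel (Ram-Lak, optionally apodized), then smeared back across the
image at their acquisition angles. Angles may start anywhere and exceed
360 deg — rows are backprojected at their wrapped angle, which realizes
the parallel-beam identity ``p(theta + 180, s) = p(theta, -s)``
automatically, so a window beginning at 900 deg reconstructs identically
to one beginning at 0 deg for a static object.

Conventions (the field has no single standard; these are explicit):

* image pixel (i, j) sits at ``x = (j - (n-1)/2) * px``,
  ``y = (i - (n-1)/2) * px`` relative to the rotation axis;
* the rotation axis projects to detector column ``(n-1)/2 +
  center_offset_px``;
* a row at angle theta samples ``p(theta, s)`` on rays
  ``x cos(theta) + y sin(theta) = s``;
* interpolation during backprojection is linear, rays outside the
  detector contribute zero;
* the angular quadrature is a trapezoid rule over the window scaled by
  the number of half-turns covered, so spans of 180 deg, 360 deg, 1080
  deg ... all reconstruct on the same grey scale (attenuation per um,
  unnormalized).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .preprocess import Sinogram, assemble_sinogram
from .timestep import TomogramWindow, WindowSpec, _window_from_spec

__all__ = ["Tomogram", "ramp_kernel", "filter_sinogram", "fbp_reconstruct", "reconstruct_window"]

FILTERS = ("ramp", "shepp-logan", "hann", "cosine")


@dataclass
class Tomogram:
    """One reconstructed slice with enough provenance to re-run it."""

    image: np.ndarray
    voxel_size_um: float
    window: TomogramWindow | None = None
    filter_name: str = "ramp"
    center_offset_px: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def t_mid_s(self) -> float | None:
        return None if self.window is None else self.window.t_mid_s

    def circle_mask(self) -> np.ndarray:
        n = self.image.shape[0]
        c = (n - 1) / 2.0
        yy, xx = np.ogrid[:n, :n]
        return np.hypot(yy - c, xx - c) <= (n - 1) / 2.0

    def save_tiff(self, path) -> None:
        """32-bit float TIFF plus a JSON provenance sidecar."""
        tifffile.imwrite(path, self.image.astype(np.float32))
        meta = {
            "voxel_size_um": self.voxel_size_um,
            "filter_name": self.filter_name,
            "center_offset_px": self.center_offset_px,
            "provenance": self.provenance,
        }
        if self.window is not None:
            meta["window"] = {
                "start_index": self.window.spec.start_index,
                "n_window": self.window.spec.n_window,
                "stride": self.window.spec.stride,
                "t_start_s": self.window.t_start_s,
                "t_mid_s": self.window.t_mid_s,
                "t_end_s": self.window.t_end_s,
                "label": self.window.label,
            }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def ramp_kernel(n_detector: int, pixel_size_um: float) -> np.ndarray:
    """Band-limited spatial-domain ramp (Ram-Lak) kernel.

    Indices run -(n-1) .. (n-1); ``h[0] = 1/(4 tau^2)``, odd taps
    ``-1/(pi^2 k^2 tau^2)``, even taps zero. Convolving a sinogram row
    with this kernel (times the detector pitch ``tau``) approximates the
    continuous ramp filtering of FBP without the DC bias a plain |f|
    multiplication in Fourier space would introduce.
    """
    tau = pixel_size_um
    k = np.arange(-(n_detector - 1), n_detector)
    h = np.zeros(k.size)
    h[k == 0] = 1.0 / (4.0 * tau**2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi**2 * k[odd].astype(np.float64) ** 2 * tau**2)
    return h


def _fourier_filter(n_detector: int, pixel_size_um: float, filter_name: str, m: int) -> np.ndarray:
    """FFT (length m) of the padded ramp kernel, optionally apodized."""
    h = ramp_kernel(n_detector, pixel_size_um)
    H = np.fft.fft(h, n=m)
    if filter_name == "ramp":
        return H
    f = np.fft.fftfreq(m, d=pixel_size_um)
    fn = 1.0 / (2.0 * pixel_size_um)  # Nyquist
    if filter_name == "shepp-logan":
        w = np.sinc(f / (2.0 * fn))
    elif filter_name == "cosine":
        w = np.cos(np.pi * f / (2.0 * fn))
    elif filter_name == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * f / fn))
    else:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    return H * w


def filter_sinogram(
    values: np.ndarray, pixel_size_um: float, filter_name: str = "ramp"
) -> np.ndarray:
    """Ramp-filter every sinogram row (exact linear convolution via FFT).

    Returns rows in units of attenuation (1/um): the discrete convolution
    is scaled by the detector pitch.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[-1]
    m = int(2 ** np.ceil(np.log2(3 * n)))  # room for full linear convolution
    H = _fourier_filter(n, pixel_size_um, filter_name, m)
    q = np.fft.ifft(np.fft.fft(values, n=m, axis=-1) * H, axis=-1).real
    # central 'same' part of the length 2n-1 kernel convolution
    return q[..., n - 1 : 2 * n - 1] * pixel_size_um


def fbp_reconstruct(
    sino: Sinogram,
    filter_name: str = "ramp",
    center_offset_px: float | None = None,
    window: TomogramWindow | None = None,
) -> Tomogram:
    """Filtered back-projection of one sinogram into a Tomogram.

    Requires an angular span of at least 180 deg and uniform angular
    spacing; the window may start at any (unwrapped) angle. Linear in the
    sinogram, deterministic, zero in = zero out. Pixels outside the
    inscribed reconstruction circle are masked to zero.
    """
    angles = np.asarray(sino.angles_deg, dtype=np.float64)
    if angles.size < 2:
        raise ValueError("need at least two projections")
    steps = np.diff(angles)
    if np.any(np.abs(steps - steps[0]) > 1e-6 * max(1.0, abs(steps[0]))):
        raise ValueError("non-uniform angle spacing beyond tolerance")
    span = float(angles[-1] - angles[0])
    if span < 180.0 - 1e-9:
        raise ValueError(
            f"insufficient angular coverage: window spans {span:.6g} deg < 180 deg"
        )
    if center_offset_px is None:
        center_offset_px = sino.center_offset_px

    n = sino.n_detector
    tau = sino.pixel_size_um
    q = filter_sinogram(sino.values, tau, filter_name)

    # trapezoid quadrature over the closed window, normalized per half-turn
    d_theta = np.deg2rad(steps[0])
    w = np.full(angles.size, d_theta)
    w[0] = w[-1] = d_theta / 2.0
    half_turns = np.deg2rad(span) / np.pi
    w /= half_turns

    c = (n - 1) / 2.0
    x = (np.arange(n) - c) * tau
    yy, xx = np.meshgrid(x, x, indexing="ij")
    theta = np.deg2rad(angles % 360.0)
    det_axis = np.arange(n, dtype=np.float64)

    image = np.zeros((n, n))
    for k in range(angles.size):
        t = xx * np.cos(theta[k]) + yy * np.sin(theta[k])
        idx = t / tau + c + center_offset_px
        image += w[k] * np.interp(idx, det_axis, q[k], left=0.0, right=0.0)

    mask = np.hypot(yy, xx) <= (n - 1) / 2.0 * tau
    image[~mask] = 0.0
    return Tomogram(
        image=image,
        voxel_size_um=tau,
        window=window,
        filter_name=filter_name,
        center_offset_px=float(center_offset_px),
        provenance={
            "n_projections": int(angles.size),
            "span_deg": span,
            "start_angle_deg": float(angles[0]),
            "slice_index": sino.slice_index,
            "qc": dict(sino.qc),
        },
    )


def reconstruct_window(
    stack,
    spec: WindowSpec,
    slice_index: int = 0,
    filter_name: str = "ramp",
    center_offset_px: float = 0.0,
    eps: float = 1e-6,
) -> Tomogram:
    """Preprocess + assemble + FBP for one window of a raw scan.

    The tomogram carries the window's start/mid/end time labels so a
    sequence of reconstructions forms a time series.
    """
    spec.validate(stack.geom)
    win = _window_from_spec(stack.geom, spec, label=spec.start_index // max(spec.stride, 1))
    sino = assemble_sinogram(
        stack, slice_index, window=spec, eps=eps, center_offset_px=center_offset_px
    )
    return fbp_reconstruct(sino, filter_name=filter_name, window=win)
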