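"""Temporal quantification across a tomogram sequence.

Given the ordered reconstructions from a sliding-window fly scan, this
module computes what an experimenter reads off a demineralization time
series: signed grey-value change maps against the first tomogram,
threshold segmentation of the lesion (material loss shows up as a
*positive* difference, since attenuation drops where mineral leaves),
and the cavity-size-versus-time curve.

No image registration is performed: simulated tomograms share a frame
by construction, and registering real data is a documented prerequisite,
not something this module attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import PhantomState, attenuation_at
from .recon import Tomogram

__all__ = [
    "TimeSeriesResult",
    "difference_map",
    "segment_cavity",
    "progression_curve",
    "motion_blur_qc",
]


@dataclass
class TimeSeriesResult:
    """Per-tomogram quantities of one progression analysis.

    ``cavity_volume`` is in um^2 for slice tomograms (um^3 once volumes
    are analyzed); ``monotone_fraction`` is the fraction of consecutive
    steps on which the cavity did not shrink — 1.0 for a perfectly
    monotone dissolution signal.
    """

    times_s: np.ndarray
    cavity_volume: np.ndarray
    mean_grey_in_roi: np.ndarray
    diff_maps: list[np.ndarray]
    threshold_used: dict
    monotone_fraction: float = 1.0
    roi_mask: np.ndarray | None = None
    start_times_s: np.ndarray | None = None  # per-window first-frame times

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if not (n == len(self.cavity_volume) == len(self.mean_grey_in_roi) == len(self.diff_maps)):
            raise ValueError("all per-tomogram series must have equal length")

    def to_rows(self) -> list[dict]:
        return [
            {
                "time_s": float(t),
                "cavity_volume": float(v),
                "mean_grey_in_roi": float(g),
            }
            for t, v, g in zip(self.times_s, self.cavity_volume, self.mean_grey_in_roi)
        ]


def difference_map(tomo_t: Tomogram, tomo_0: Tomogram) -> np.ndarray:
    """Signed change image ``tomo_0 - tomo_t`` (positive = material loss).

    Both tomograms must share shape and voxel size and be co-registered.
    Masked (zeroed) outside the reconstruction circle.
    """
    if tomo_t.image.shape != tomo_0.image.shape:
        raise ValueError(
            f"shape mismatch: {tomo_t.image.shape} vs {tomo_0.image.shape}"
        )
    if not np.isclose(tomo_t.voxel_size_um, tomo_0.voxel_size_um):
        raise ValueError(
            f"voxel size mismatch: {tomo_t.voxel_size_um} vs {tomo_0.voxel_size_um}"
        )
    diff = tomo_0.image - tomo_t.image
    diff[~tomo_0.circle_mask()] = 0.0
    return diff


def segment_cavity(
    diff_map: np.ndarray,
    threshold_rule: str | float = "otsu",
    voxel_size_um: float = 1.0,
    largest_component: bool = False,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold the change map into a lesion mask and measure its size.

    ``threshold_rule`` is either a fixed value (float) or ``"otsu"``,
    which picks the threshold from the difference histogram restricted to
    ``mask`` (typically the reconstruction circle). The returned size is
    ``count * voxel_size_um**2`` for a 2D map (``**3`` for 3D). An empty
    mask is a valid result. With ``largest_component`` only the biggest
    connected region is kept, suppressing speckle.
    """
    diff_map = np.asarray(diff_map, dtype=np.float64)
    if mask is None:
        mask = np.ones(diff_map.shape, dtype=bool)
    if isinstance(threshold_rule, str):
        if threshold_rule != "otsu":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        tau = float(threshold_otsu(diff_map[mask]))
    else:
        tau = float(threshold_rule)
    cavity = (diff_map > tau) & mask
    if largest_component and cavity.any():
        labels, n_lab = ndimage.label(cavity)
        sizes = ndimage.sum_labels(cavity, labels, index=np.arange(1, n_lab + 1))
        cavity = labels == (1 + int(np.argmax(sizes)))
    volume = float(cavity.sum()) * voxel_size_um**diff_map.ndim
    return cavity, volume


def progression_curve(
    tomograms: list[Tomogram],
    threshold_rule: str | float = "otsu-final",
    largest_component: bool = False,
    roi_mask: np.ndarray | None = None,
) -> TimeSeriesResult:
    """Cavity size and mean grey value against time over a tomogram series.

    The first tomogram is the reference; every later one is compared to
    it with :func:`difference_map` and segmented with a common threshold.
    ``threshold_rule`` may be:

    * ``"otsu-final"`` (default) — Otsu computed once on the last (most
      developed) difference map and applied to all, which keeps early,
      signal-free maps from being over-segmented;
    * ``"otsu"`` — Otsu per map;
    * a float — fixed threshold.

    ``mean_grey_in_roi`` is the mean attenuation inside ``roi_mask`` —
    by default the final segmented cavity, a fixed region in which grey
    values fall as mineral dissolves.
    """
    if len(tomograms) < 2:
        raise ValueError("need at least two tomograms (reference + one)")
    ref = tomograms[0]
    circle = ref.circle_mask()
    diffs = [difference_map(t, ref) for t in tomograms]

    if isinstance(threshold_rule, str) and threshold_rule == "otsu-final":
        tau = float(threshold_otsu(diffs[-1][circle]))
        rule_used = {"rule": "otsu-final", "tau": tau}
    elif isinstance(threshold_rule, str) and threshold_rule == "otsu":
        tau = None
        rule_used = {"rule": "otsu", "tau": "per-map"}
    else:
        tau = float(threshold_rule)
        rule_used = {"rule": "fixed", "tau": tau}

    volumes = np.empty(len(tomograms))
    masks = []
    for k, d in enumerate(diffs):
        rule = tau if tau is not None else "otsu"
        m, v = segment_cavity(
            d,
            threshold_rule=rule,
            voxel_size_um=ref.voxel_size_um,
            largest_component=largest_component,
            mask=circle,
        )
        masks.append(m)
        volumes[k] = v

    if roi_mask is None:
        roi_mask = masks[-1] if masks[-1].any() else circle
    greys = np.array([float(t.image[roi_mask].mean()) for t in tomograms])

    times = np.array(
        [t.t_mid_s if t.t_mid_s is not None else float(k) for k, t in enumerate(tomograms)]
    )
    starts = np.array(
        [
            t.window.t_start_s if t.window is not None else times[k]
            for k, t in enumerate(tomograms)
        ]
    )
    steps = np.diff(volumes)
    monotone = float(np.mean(steps >= 0)) if steps.size else 1.0
    return TimeSeriesResult(
        times_s=times,
        cavity_volume=volumes,
        mean_grey_in_roi=greys,
        diff_maps=diffs,
        threshold_used=rule_used,
        monotone_fraction=monotone,
        roi_mask=roi_mask,
        start_times_s=starts,
    )


def estimate_onset(
    result: TimeSeriesResult, null_sigma: float, n_sigma: float = 3.0
) -> float | None:
    """Dissolution onset: start time of the first window leaving the noise band.

    ``null_sigma`` is the spread of the cavity-volume estimate under the
    no-change null (from a static-phantom control run). The onset
    estimate is the *start* time of the first tomogram whose volume
    exceeds ``n_sigma * null_sigma`` — the window start is the right
    label here because a detected cavity only proves dissolution began
    before the window ended, so the start time is within one window
    duration of any onset this window is the first to detect. ``None``
    if the series never leaves the band.
    """
    above = result.cavity_volume > n_sigma * null_sigma
    if not above.any():
        return None
    k = int(np.argmax(above))
    times = result.start_times_s if result.start_times_s is not None else result.times_s
    return float(times[k])


def motion_blur_qc(tomo: Tomogram, state: PhantomState) -> float:
    """Normalized RMSE between a window reconstruction and the phantom
    frozen at the window's mid-time.

    Material dissolving *during* a window violates the static-object
    assumption of FBP; this metric quantifies the resulting discrepancy
    (it is reported, not corrected). Requires the reconstruction grid to
    match the phantom grid (same shape and voxel size). Normalization is
    by the phantom's dynamic range inside the reconstruction circle.
    """
    if tomo.t_mid_s is None:
        raise ValueError("tomogram carries no window time label")
    truth = attenuation_at(state, tomo.t_mid_s)
    if truth.ndim == 3:
        truth = truth[truth.shape[0] // 2]
    if truth.shape != tomo.image.shape:
        raise ValueError(
            f"grid mismatch: phantom {truth.shape} vs reconstruction {tomo.image.shape}"
        )
    m = tomo.circle_mask()
    rng_ = truth[m].max() - truth[m].min()
    return float(np.sqrt(np.mean((tomo.image[m] - truth[m]) ** 2)) / rng_)
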