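"""Index/angle/time bookkeeping of a full-scale continuous-rotation scan.

A fly scan maps projection index linearly to angle and time. With the
reference geometry (0.072 deg/frame, 0.5 s exposure, 15 001 frames) the
file spans three full turns; any 2501 consecutive frames span exactly
180 deg and are a valid reconstruction window.
"""

from flytomo import ScanGeometry, angle_of_index, n_projections_for_range, time_of_index
from flytomo.timestep import enumerate_windows

geom = ScanGeometry()  # reference full-scale scan
print(f"scan: {geom.n_projections} frames x {geom.angular_step_deg} deg "
      f"-> {geom.total_range_deg:.0f} deg total")
print(f"frames per 180 deg window : {n_projections_for_range(geom, 180.0)}")
print(f"frames per full scan file : {n_projections_for_range(geom, 1080.0)}")
print(f"angle of frame 15000      : {angle_of_index(geom, 15_000):.1f} deg")
print(f"time of frame 15000       : {time_of_index(geom, 15_000):.1f} s "
      f"(pure exposure; add overhead_s per frame for wall clock)")
print(f"voxel at 10x / 4x         : {geom.pixel_size_um} / "
      f"{geom.with_magnification(4.0).pixel_size_um} um")

print("\ndisjoint 180-deg windows (stride 2500):")
print(f"{'#':>2} {'start':>6} {'start_deg':>10} {'t_start_s':>10} {'t_mid_s':>9}")
for w in enumerate_windows(geom, n_window=2501, stride=2500):
    print(f"{w.label:>2} {w.spec.start_index:>6} {w.start_angle_deg:>10.1f} "
          f"{w.t_start_s:>10.1f} {w.t_mid_s:>9.1f}")
# Six tomograms from one scan; with stride < 2500 the time step between
# successive tomograms shrinks, down to one frame period at stride 1.
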