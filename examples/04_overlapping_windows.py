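"""Refine the time axis with overlapping windows.

The same scan supports any stride >= 1 frame: halving the stride doubles
the number of tomograms without changing the acquisition. The disjoint
curve is exactly a subsequence of the overlapping one — refinement never
rewrites history, it interpolates new time points between the old ones.
"""

from flytomo import ScanGeometry
from flytomo.timestep import enumerate_windows

geom = ScanGeometry(angular_step_deg=1.44, n_projections=751, exposure_s=2.0,
                    detector_shape=(1, 64), pixel_size_um=1.0)

for stride in (125, 25, 5, 1):
    wins = enumerate_windows(geom, n_window=126, stride=stride)
    dt = wins[1].t_start_s - wins[0].t_start_s
    print(f"stride {stride:>3} frames -> {len(wins):>3} tomograms, "
          f"time step {dt:>6.1f} s between window starts")
print("\nat stride 1 the nominal time step equals one frame period "
      f"({geom.frame_period_s} s) - the acquisition's hard floor.")
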