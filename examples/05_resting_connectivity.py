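"""Clean a synthetic resting series and recover a known inter-ROI correlation.

Two ROIs are generated with correlation 0.5 plus motion spikes; the
cleaning chain (detrend, motion regression, FD>0.5 scrubbing, 0.01-0.08 Hz
band-pass) recovers the coupling and reports Fisher-z values.
"""

import numpy as np

from riskdeck.cohort import simulate_resting_state
from riskdeck.rsfc import connectivity_matrix, framewise_displacement

target = np.eye(3)
target[0, 1] = target[1, 0] = 0.5

rng = np.random.default_rng(3)
series, motion = simulate_resting_state(
    target, spike_schedule=[60, 170], spike_magnitudes=[0.9, 1.1], rng=rng
)
fd = framewise_displacement(motion)
print(f"240-volume series, {np.sum(fd > 0.5)} volumes exceed FD 0.5 mm")

for c in connectivity_matrix(series, motion=motion):
    print(
        f"{c.roi_a} -- {c.roi_b}:  r = {c.r:+.3f}  z = {c.z:+.3f}  "
        f"({c.n_volumes} volumes used, {c.n_scrubbed} scrubbed)"
    )
print(
    "\nThe roi0--roi1 pair should sit near its generating value 0.5; the"
    "\nother pairs were generated independent, so their r hovers near 0."
)
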