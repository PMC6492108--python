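"""Recover a center-frequency drift from a b = 0 blip-up/blip-down pair.

Scanner frequency drift between the B0 scan and the EPI scans translates
the two polarities' images by equal and opposite amounts along the
phase-encode axis.  The drift is found by maximizing mutual information
between the two conjugate-phase reconstructions with a 10-iteration
Nelder-Mead search.
"""

import numpy as np

import epiunwarp as eu

TRUE_F0 = 47.0  # Hz, injected drift

scene = eu.make_scene(seed=4)
y_up, y_down = eu.simulate_pair(scene, f0_hz=TRUE_F0, snr=20.0, seed=4)
est = eu.estimate_frequency_offset(
    y_up, y_down, scene.coils_true, scene.b0_true, scene.geometry
)

shift_px = TRUE_F0 / scene.geometry.bw_per_pixel_hz
print(f"true drift:      {TRUE_F0:.2f} Hz  ({shift_px:.2f} px apparent shift)")
print(f"estimated drift: {est.f0_hz:.2f} Hz  after {est.n_iter} simplex iterations")
print(f"error:           {abs(est.f0_hz - TRUE_F0):.2f} Hz")
print("negative-MI trace:", np.array2string(est.objective_trace, precision=3))
print()
print("The trace is non-increasing and levels off after ~5 iterations; the")
print("residual error is a small fraction of one pixel's bandwidth.")
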