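"""The full comparison: uncorrected, single-polarity and joint reconstruction.

Simulates a noisy blip-up/blip-down pair of the 120 Hz scene, reconstructs
it every way the in vivo comparison does, and scores each variant's object
mask against the truth with the Dice coefficient.
"""

import numpy as np

import epiunwarp as eu

scene = eu.make_scene(seed=1)
table = eu.evaluate_scene(scene, snr=20.0, seed=1)

print(table[["dice", "n_overlap", "max_shift_px"]].to_string(
    float_format=lambda v: f"{v:.4f}"))
print()

y_up, y_down = eu.simulate_pair(scene, snr=20.0, seed=1)
result = eu.cg_reconstruct(
    eu.build_joint_system(y_up, y_down, scene.coils_true, scene.b0_true,
                          scene.geometry)
)
print(f"joint CG: {result.n_iter} iterations, "
      f"final normalized residual {result.residuals[-1]:.2e}, "
      f"converged={result.converged}")
print()
print("Uncorrected images lose several percent of the object to warping and")
print("pile-up; single-polarity correction with the exact field recovers the")
print("stretched regions but stays ill-posed in the pile-up band; the joint")
print("blip-up/blip-down solve recovers the full object (Dice ~1).")
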