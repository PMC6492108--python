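"""Diffusion-phase rescue: combine two dynamics with and without correction.

Tissue motion during diffusion gradients stamps each shot with a smooth
random phase.  Complex combination of two such shots cancels signal where
their phases differ by ~π; estimating the voxelwise relative phase from the
conjugate-phase reconstructions and removing it from one shot's k-space
preserves the signal.
"""

import numpy as np

import epiunwarp as eu
from epiunwarp.operators import EncodingOperator

scene = eu.make_scene(seed=2)
g = scene.geometry
d1 = eu.simulate_acquisition(scene, eu.Polarity.BLIP_UP, snr=20.0,
                             diffusion_phase="smooth_random", seed=11)
d2 = eu.simulate_acquisition(scene, eu.Polarity.BLIP_UP, snr=20.0,
                             diffusion_phase="smooth_random", seed=22)

op = EncodingOperator(g, scene.coils_true, scene.b0_true,
                      eu.Polarity.BLIP_UP, d1.sample_mask)
obj = scene.object_mask
truth_mean = np.abs(scene.truth_image.data)[obj].mean()


def interior_loss(y1):
    rec = eu.cg_reconstruct(eu.JointSystem([(op, y1.data), (op, d2.data)]))
    return 100.0 * (truth_mean - np.abs(rec.image.data)[obj].mean()) / truth_mean


phi = eu.compute_phase_map(
    eu.ComplexImage(op.adjoint_array(d1.data), g),
    eu.ComplexImage(op.adjoint_array(d2.data), g),
)
print(f"phase discrepancy range: [{phi.delta_phi_rad.min():.2f}, "
      f"{phi.delta_phi_rad.max():.2f}] rad")
print(f"object-interior magnitude loss, uncorrected: {interior_loss(d1):.1f}%")
print(f"object-interior magnitude loss, corrected:   "
      f"{interior_loss(eu.apply_phase_to_kspace(d1, phi)):.2f}%")
print()
print("Without correction the shots interfere destructively (tens of percent")
print("signal dropout); with correction the joint reconstruction preserves it.")
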