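"""Estimate a B0 map from simulated dual-echo data, smooth it, resample it.

The per-voxel field is the inter-echo phase divided by 2π ΔTE (here
ΔTE = 2.3 ms, unambiguous within ±217 Hz).  Noisy voxels are tamed by the
robust DCT-penalized smoother with GCV-chosen strength, and the field is
interpolated onto the EPI grid.
"""

import numpy as np

import epiunwarp as eu

rng = np.random.default_rng(0)

# ground truth on the B0-scan grid (2 mm isotropic, slightly larger matrix)
b0_grid = eu.GridGeometry(112, 112, pixel_mm=(2.0, 2.0))
truth = eu.make_b0_field(b0_grid, peak_hz=120.0, seed=1)

# simulate the dual-echo acquisition: magnitude + phase accrual + noise
dte = 2.3e-3
mag = 1.0 + rng.random(b0_grid.shape)
echo1 = mag * np.exp(1j * rng.uniform(-0.1, 0.1, b0_grid.shape))
echo2 = echo1 * np.exp(2j * np.pi * truth.delta_b0_hz * dte)
noise = 0.05 * (rng.standard_normal((2, *b0_grid.shape))
                + 1j * rng.standard_normal((2, *b0_grid.shape)))
d = eu.DualEchoSet(echo1=echo1 + noise[0], echo2=echo2 + noise[1],
                   te1_s=4.6e-3, te2_s=4.6e-3 + dte)

raw = eu.b0_from_dual_echo(d)
smoothed = eu.smooth_b0(raw, strength="auto")
epi = eu.resample_to_epi(smoothed, b0_grid, eu.default_geometry())

rmse_raw = np.sqrt(np.mean((raw.delta_b0_hz - truth.delta_b0_hz) ** 2))
rmse_sm = np.sqrt(np.mean((smoothed.delta_b0_hz - truth.delta_b0_hz) ** 2))
print(f"raw field RMSE vs truth:      {rmse_raw:.2f} Hz")
print(f"smoothed field RMSE vs truth: {rmse_sm:.2f} Hz")
print(f"resampled to EPI grid: {epi.delta_b0_hz.shape}")
print()
print("Smoothing removes the phase-noise floor without flattening the 120 Hz")
print("air-interface perturbation the reconstruction needs.")
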