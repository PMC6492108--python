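# epiunwarp

Model-based correction of susceptibility-induced geometric distortion,
signal pile-up, signal dropout and center-frequency-drift shifts in
single-shot EPI — the regime of prostate diffusion-weighted MRI, where the
tissue/rectal-air interface creates off-resonance fields of ~100+ Hz against
a phase-encode bandwidth of ~10 Hz/pixel.

The package is for MRI reconstruction researchers who have (or can
simulate) raw multicoil k-space from two acquisitions with opposite
phase-encode blip polarities plus a B0 field map, and who want the full
inverse-problem treatment rather than image-space unwarping: in severe
pile-up several true voxels collapse onto one measured voxel, which no
single-polarity method can undo, while the opposite polarity observes the
same region stretched — jointly the data determine the image.

## The model

With coil sensitivities $C_j$, field map $\Delta B_0(m,n)$ (Hz), global
center-frequency offset $\Delta f_0$ and per-line sample times $t_i(k)$
(sign set by the blip polarity $i$), the acquired k-space of coil $j$ is

$$Y_{ij}(k,l) = \sum_{m,n} C_j(m,n)\, x(m,n)\,
  e^{-i2\pi\left(\frac{mk}{M}+\frac{nl}{N}\right)}
  e^{-i2\pi\,(\Delta B_0(m,n)+\Delta f_0)\, t_i(k)} ,$$

compactly $Y_i = E_i x$. The pipeline has three steps:

1. **Offset calibration** — $\Delta f_0$ translates the two polarities'
   images by equal and opposite amounts, so it is estimated from the
   $b=0$ pair as the value maximizing the mutual information between the
   conjugate-phase reconstructions $x_{cp,i} = E_i^H Y_i$ (1-D Nelder–Mead,
   10 iterations).
2. **Diffusion-phase alignment** — shot-random motion-induced phase is the
   voxelwise relative phase $\Delta\Phi = \angle(x_{cp,1}\,\overline{x_{cp,2}})$,
   removed from the blip-up k-space by an image-domain unit-modulus multiply.
3. **Joint reconstruction** — the stacked normal equations
   $(E_1^H E_1 + E_2^H E_2)\,x = E_1^H \tilde Y_1 + E_2^H Y_2$ are solved by
   conjugate gradients from $x_0=0$, stopping when the normalized residual
   $r = \|E^H E x - E^H \tilde Y\|_2 / \|E^H \tilde Y\|_2$ drops below
   $\epsilon = 0.0025$.

A physics-based simulator (`make_scene`, `simulate_pair`) generates the
pelvis-like phantom, air-interface B0 field, coil maps and noisy partial-
Fourier k-space used throughout the tests, and a thin CLI (`epi-unwarp`)
exposes each step plus an end-to-end `run-all`.

## Worked example

```python
import epiunwarp as eu

scene = eu.make_scene(seed=1)                       # 96x96, 120 Hz field, 8 coils
table = eu.evaluate_scene(scene, snr=20.0, seed=1)  # simulate + reconstruct variants
print(table["dice"])
```

prints (object-mask Dice against the ground truth):

```
variant
uncorrected_up      0.9510
uncorrected_down    0.9633
corrected_up        0.9994
corrected_down      0.9930
joint               1.0000
```

The field displaces signal by up to ~11 pixels; uncorrected images lose the
warped and piled-up parts of the object, single-polarity model-based
correction with the exact field recovers the stretched regions but remains
ill-posed in the pile-up band, and the joint blip-up/blip-down solve
recovers the object completely. The scripts in `examples/` walk through
each capability (scene anatomy, field mapping from dual-echo data, offset
recovery, phase rescue, the comparison above) and print the numbers they
compute.

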