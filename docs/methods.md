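# Methods

## Encoding model and conventions

The forward model maps the distortion-free complex image `x` to each coil's
k-space through the coil sensitivity, a 2-D Fourier kernel, and an
off-resonance phase accrued over the sample time of each k-space location.
Off-resonance is the sum of the per-voxel field `ΔB0` (Hz) and a spatially
constant center-frequency offset `Δf0` (scanner drift between the B0 scan
and the EPI scans).

Conventions, fixed for bit-reproducibility:

- **DFT**: centered (DC at index `floor(n/2)`), unitary, negative exponent
  forward. With `ΔB0 ≡ 0`, `Δf0 = 0` and uniform single-coil sensitivity
  the operator pair is exactly the unitary FFT pair and joint reconstruction
  reduces to iterative SENSE.
- **Sample times**: readout dwell (~µs) is negligible against echo spacing
  (~ms), so `t` varies only with the phase-encode line index:
  `t(k) = s·(k − k_echo)·esp`, `s = +1` blip-up, `−1` blip-down, zero at the
  echo-center line. A constant effective field `f` therefore translates the
  image by exactly `f / bw` pixels along PE (`bw = 1/(n_pe·esp)`), with
  opposite sign for the two polarities.
- **Fast path**: per PE line `k` the operator is an elementwise phase
  `exp(−2πi ΔB0 t_k)` followed by one row of the PE-direction DFT; the
  kernel `K[k,m,n]` is precomputed (`O(n_pe² · n_ro)` memory, ~14 MB at
  96²) and applied with an einsum plus an FFT along readout. This is exact
  under the per-line timing model; a dense explicitly built encoding matrix
  provides the independent oracle on small grids (agreement ~1e-15).
  `Δf0` enters only as a per-line phase, so offset sweeps reuse the kernel.
- **Partial Fourier** (half-scan 0.75 by default): the lines skipped to
  shorten TE are those acquired earliest in the echo train, which lie at
  opposite k-space ends for the two traversal directions; masks are
  therefore polarity-mirrored and the joint system stays full-rank. No
  homodyne/POCS completion — CG treats unacquired lines as missing data.

## B0 estimation

With two echoes, a weighted least-squares fit of temporally unwrapped phase
over echo time degenerates to the weighted two-point phase difference
`ΔB0 = angle(echo2·conj(echo1)) / (2π ΔTE)`, exact to float precision for
noiseless voxels within `±1/(2ΔTE)` (±217 Hz at ΔTE = 2.3 ms). Frequencies
beyond that range alias back into the principal interval; no spatial
unwrapping is attempted (a documented limitation — rectal air itself gives
no signal to unwrap).

Smoothing is penalized least squares in the DCT domain (squared
second-difference penalty), with magnitude-product data weights,
iteratively reweighted bisquare residuals (3 outer iterations) for
robustness, and the penalty weight chosen by generalized cross-validation
over `log10 s ∈ [−4, 7]` unless fixed by the caller. The output is clamped
to the input's range, so constants are fixed points and the smoother never
widens the field's range. Resampling to the EPI grid is linear
interpolation in physical coordinates with concentric grids; target voxels
outside the source FOV get 0 Hz (no correction where there is no field
information).

## Center-frequency-offset estimation

The offset is searched by maximizing mutual information between the
blip-up and blip-down conjugate-phase reconstructions of the `b = 0` pair,
evaluated with effective field `ΔB0 + Δf0`. The MI estimator: magnitude
images are pre-smoothed with a 1-pixel Gaussian, clipped at the 99th
percentile, binned into 64 linear bins between each image's minimum and its
clip level, and MI = H(A)+H(B)−H(A,B) in nats with `0·log 0 = 0`. The
pre-smoothing is an estimator design choice: with ~2 samples per joint-
histogram bin at 96², the raw plug-in MI fluctuates by ~0.01 nats between
nearby offsets, enough to stall a derivative-free search on a plateau
bump; one pixel of smoothing suppresses the fluctuation without moving the
optimum (parameter-recovery simulations recover an injected 47 Hz drift to
<0.5 Hz in 10/10 seeds at SNR 20). For independent images the estimator's
finite-sample bias is ≈ (B−1)²/(2N) ≈ 0.215 nats — small against the ~1
nat of aligned images.

The search is 1-D Nelder–Mead (start 0 Hz, initial step 10 Hz, standard
reflection/expansion/contraction coefficients), capped at 10 simplex
iterations with the estimate taken from the final simplex; the recorded
objective trace is the best vertex per iteration and is non-increasing by
construction. In simulations the objective reaches its final value in ~5
iterations; the 10-iteration cap quantizes the estimate at the ~1 Hz level,
well under the 10.4 Hz bandwidth of one pixel.

## Diffusion phase correction

The inter-shot phase map is the voxelwise relative phase
`ΔΦ = angle(xcp1 · conj(xcp2))` — the product-with-conjugate reading of the
Hermitian inner product, the standard choice for relative phase (the
alternative reading, a scalar inner product, yields no spatial map and
cannot drive a voxelwise correction). Voxels whose magnitude product is
below 1e-6 of the maximum get ΔΦ = 0 (the angle of a near-zero complex
number is noise). The correction is applied to the blip-up k-space by
IFT → multiply `exp(−iΔΦ)` → FT, with blip-down as the phase reference;
unacquired partial-Fourier lines are re-zeroed after the round trip. ΔΦ is
used raw (no spatial smoothing) by default. One ΔΦ is computed per
(direction, pair).

## Joint CG reconstruction

The normal equations over the stacked polarities are solved by standard
conjugate gradients from `x0 = 0`, unpreconditioned and unregularized
(regularization only becomes interesting at much lower SNR than simulated
here). The CG residual is identically the normal-equation residual, so the
stopping quantity `r = ‖EᴴEx − EᴴỸ‖₂/‖EᴴỸ‖₂` is recorded each iteration
for free; iteration stops at `r < ε` (default 0.0025) or a safety cap of
30 iterations (typical convergence on the default scene: 14–16).

A note on `ε` and image error: on the 120 Hz scene the pile-up band makes
the single-polarity operators nearly singular and spreads the joint normal
operator's spectrum, so stopping at `r ≈ 2.5e-3` leaves a relative image
error of ~5e-3–1.4e-2 concentrated in the pile-up band. The solver's fixed
point is exact: running to `r < 1e-9` recovers the noiseless phantom to
~1e-8 relative error.

## Synthetic study conditions

The default scene mirrors the acquisition scale of a prostate DWI protocol:
96×96 matrix at 2×2 mm, phase-encode bandwidth 10.4 Hz/pixel (echo spacing
1.0 ms) along the anterior–posterior axis, half-scan 0.75, 8 receive coils
(desk-scale stand-in for a 32-channel array), b=0-style and
diffusion-phase-corrupted shots, SNR 20.

- **Phantom**: elliptical body (intensity ~1, ±10 % smooth texture),
  brighter central "prostate" ellipse (~12 % of the object area — the
  evaluation ROI), posterior zero-signal "rectal air" disc.
- **B0 field**: random second-order background polynomial bounded by
  ±20 Hz plus a derivative-of-Gaussian lobe pair centered on the air disc
  (the in-plane signature of a susceptibility dipole), amplitude-bisected
  so the total peak equals the requested value (120 Hz default). The lobe
  width (σ = 0.083·n_pe ≈ 8 px) is sized so the anterior lobe drives the
  PE field gradient past the 10.4 Hz/px bandwidth over the posterior ROI
  boundary — the displacement Jacobian crosses zero there, i.e. genuine
  pile-up, near-singular for blip-up — while the maximum first difference
  stays below 25 Hz/px (C¹-smooth at pixel scale).
- **Coils**: Gaussian profiles (σ = 0.55 normalized) on a ring of radius
  1.1 with jittered angles, random linear phase ramps, sum-of-squares
  normalized to mean 1 centrally; a single coil means a uniform unit map.
- **Noise**: i.i.d. complex Gaussian in k-space with per-component std
  `mean(|truth| in object)/SNR`; under the unitary DFT this makes the
  single-coil image-domain magnitude SNR equal the requested value.
- **Diffusion phase**: per-shot random polynomial of degree ≤3 in
  normalized coordinates, coefficients ~N(0, 0.8²) rad — smooth,
  multi-radian screens mimicking the physiological-motion mechanism
  without modeling motion itself.

Every artifact is a pure function of (parameters, seed). At infinite SNR
the simulator calls the same encoding operator used for reconstruction —
the inverse-crime transparency is deliberate and documented; it is broken
on demand by noise and by an exact dense-summation path with readout-dwell
timing (2-D sample times), which the reconstruction operators deliberately
ignore.

What passing tests on this scene do **not** show about real data: the true
field is never known exactly (B0 scan noise, motion and breathing drift
between scans), coil maps must themselves be estimated, EPI carries
Nyquist-ghost and eddy-current residuals not modeled here, the phantom's
geometry is far simpler than pelvic anatomy, and the evaluation masks come
from thresholding rather than expert contouring.

## Evaluation

Dice = 2|A∩B|/(|A|+|B|); two empty masks score 1, empty vs non-empty 0.
Masks are obtained by thresholding a reconstruction's magnitude at 50 % of
the truth ROI's mean intensity and keeping the largest connected component
— an automatable stand-in for manual contouring. Uncorrected variants are
the plain coil-combined inverse FFT with sum-of-squares normalization
(without it, coil shading — not distortion — would dominate the masks).
Single-polarity "corrected" variants run the same CG machinery on one
polarity's system with the exact field.

## Known limitations

- No spatial phase unwrapping, susceptibility-model or dipole-projection
  field extrapolation into signal-free regions.
- No motion between the blip-up and blip-down shots; no Nyquist-ghost or
  eddy-current correction; no ramp-sampling regridding; 2-D slices only.
- Partial-Fourier data are handled as missing lines in the joint solve,
  not homodyne-completed; single-polarity reconstructions of 0.75-scan
  data inherit the corresponding blur.
- The MI search is 1-D by design; spatially varying drift is out of scope.
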