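"""Physics-based synthetic acquisition: phantom, field, coils, k-space.

The default scene emulates an axial pelvis slice at the study's acquisition
scale: 96x96 matrix at 2x2 mm, phase-encode bandwidth 10.4 Hz/pixel along
the anterior-posterior axis, half-scan factor 0.75, 8 receive coils.  An
elliptical "body" contains a central "prostate" ellipse (the evaluation
ROI) and a posterior zero-signal "rectal air" disc.  The B0 field is a
smooth low-order background plus a dipole-like perturbation anchored at the
air disc, scaled so the peak off-resonance hits a requested value
(120 Hz by default — several pixels of displacement, with a compression
band over the posterior prostate boundary for the blip-up polarity).

Every artifact is a pure function of (parameters, seed).  Simulated
k-space at infinite SNR is produced by the same encoding operator used for
reconstruction; a dense exact-summation path with readout-dwell timing is
available to break that inverse-crime transparency deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .fourier import centered_index
from .grids import (
    B0Map,
    CoilMaps,
    ComplexImage,
    GridGeometry,
    MultiCoilKSpace,
    Polarity,
)
from .operators import EncodingOperator, build_sample_times

__all__ = [
    "PhantomScene",
    "default_geometry",
    "make_phantom",
    "make_b0_field",
    "make_coil_maps",
    "make_scene",
    "simulate_acquisition",
    "simulate_pair",
]

# Scene layout as fractions of the grid (PE = axis 0, anterior -> posterior).
_BODY_SEMI = (0.417, 0.344)
_PROSTATE_SEMI = (0.146, 0.115)
_PROSTATE_CENTER_PE = 0.0625
_AIR_CENTER_PE = 0.3125
_AIR_RADIUS = 0.094
# Dipole-lobe width (fraction of n_pe): chosen so that at the 120 Hz default
# the PE field gradient over the posterior ROI boundary reaches the
# phase-encode bandwidth per pixel, i.e. the blip-up displacement Jacobian
# crosses zero there — true signal pile-up, near-singular for one polarity.
_B0_SIGMA = 0.083
_B0_BACKGROUND_MAX_HZ = 20.0


def default_geometry(
    n: int = 96, bw_per_pixel_hz: float = 10.4, partial_fourier: float = 0.75
) -> GridGeometry:
    """Desk-scale default: n x n, 2 mm pixels, AP phase encode."""
    return GridGeometry.from_bandwidth(
        n_pe=n,
        n_ro=n,
        bw_per_pixel_hz=bw_per_pixel_hz,
        pixel_mm=(2.0, 2.0),
        partial_fourier=partial_fourier,
    )


@dataclass(frozen=True)
class PhantomScene:
    """Ground truth for one simulated slice."""

    truth_image: ComplexImage
    roi_mask: np.ndarray
    b0_true: B0Map
    coils_true: CoilMaps
    geometry: GridGeometry
    seed: int

    @property
    def object_mask(self) -> np.ndarray:
        return np.abs(self.truth_image.data) > 0


def _grid_pixels(geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    yy = centered_index(geometry.n_pe).astype(float)[:, None]
    xx = centered_index(geometry.n_ro).astype(float)[None, :]
    return yy, xx


def _ellipse(yy, xx, cy, cx, sy, sx) -> np.ndarray:
    return ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1.0


def make_phantom(geometry: GridGeometry, seed: int = 0) -> tuple[ComplexImage, np.ndarray]:
    """Pelvis-like piecewise-smooth phantom and its "prostate" ROI mask.

    Elliptical body of intensity ~1 with mild smooth texture, a brighter
    central prostate ellipse (~10-20% of the body area), and a zero-signal
    rectal-air disc posterior to it.
    """
    p, r = geometry.shape
    yy, xx = _grid_pixels(geometry)
    rng = np.random.default_rng(seed)

    body = _ellipse(yy, xx, 0.0, 0.0, _BODY_SEMI[0] * p, _BODY_SEMI[1] * r)
    roi = _ellipse(
        yy, xx, _PROSTATE_CENTER_PE * p, 0.0, _PROSTATE_SEMI[0] * p, _PROSTATE_SEMI[1] * r
    )
    air = (yy - _AIR_CENTER_PE * p) ** 2 + xx**2 <= (_AIR_RADIUS * min(p, r)) ** 2

    texture = gaussian_filter(rng.standard_normal((p, r)), sigma=0.04 * min(p, r))
    span = np.abs(texture).max() or 1.0
    texture = 0.1 * texture / span

    img = np.zeros((p, r))
    img[body] = 1.0
    img[roi] = 1.25
    img *= 1.0 + texture
    img[air] = 0.0
    roi &= ~air
    return ComplexImage(img.astype(complex), geometry), roi


def make_b0_field(geometry: GridGeometry, peak_hz: float = 120.0, seed: int = 0) -> B0Map:
    """Background polynomial plus an air-interface perturbation.

    The background is a random second-order polynomial bounded by ±20 Hz.
    The perturbation is a derivative-of-Gaussian lobe pair centered on the
    rectal-air disc — positive posterior lobe, negative anterior lobe — and
    is scaled so the total field's peak magnitude equals ``peak_hz``.  The
    anterior lobe puts a negative PE field gradient across the posterior
    prostate boundary, producing signal pile-up there for the blip-up
    polarity.
    """
    if peak_hz < 0:
        raise ValueError("peak_hz must be non-negative")
    p, r = geometry.shape
    yy, xx = _grid_pixels(geometry)
    yn, xn = yy / (p / 2.0), xx / (r / 2.0)
    rng = np.random.default_rng(seed)

    terms = [yn, xn, yn**2, yn * xn, xn**2]
    poly = sum(c * t for c, t in zip(rng.uniform(-1.0, 1.0, len(terms)), terms))
    poly_peak = rng.uniform(0.4, 1.0) * _B0_BACKGROUND_MAX_HZ
    poly = poly * (poly_peak / (np.abs(poly).max() or 1.0))
    if peak_hz == 0.0:
        return B0Map(delta_b0_hz=poly)

    sigma = _B0_SIGMA * p
    dy = yy - _AIR_CENTER_PE * p
    dx = xx
    pert = (dy / sigma) * np.exp(-(dy**2 + dx**2) / (2.0 * sigma**2))
    pert = pert / np.abs(pert).max()

    # bisect the perturbation amplitude so max |poly + a * pert| == peak_hz
    lo, hi = 0.0, 2.0 * peak_hz
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.abs(poly + mid * pert).max() < peak_hz:
            lo = mid
        else:
            hi = mid
    return B0Map(delta_b0_hz=poly + 0.5 * (lo + hi) * pert)


def make_coil_maps(geometry: GridGeometry, n_coils: int = 8, seed: int = 0) -> CoilMaps:
    """Smooth Gaussian-profile sensitivities on a ring of coil centers.

    ``n_coils = 1`` returns the uniform unit map.  The sum-of-squares
    sensitivity is normalized to mean 1 over the central field of view.
    """
    p, r = geometry.shape
    if n_coils == 1:
        return CoilMaps(maps=np.ones((1, p, r), dtype=complex))
    yy, xx = _grid_pixels(geometry)
    yn, xn = yy / (p / 2.0), xx / (r / 2.0)
    rng = np.random.default_rng(seed)
    maps = np.empty((n_coils, p, r), dtype=complex)
    jitter = rng.uniform(-0.2, 0.2, n_coils)
    for j in range(n_coils):
        theta = 2.0 * np.pi * j / n_coils + jitter[j]
        cy, cx = 1.1 * np.sin(theta), 1.1 * np.cos(theta)
        profile = np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / (2.0 * 0.55**2))
        ramp = rng.uniform(-1.5, 1.5) * yn + rng.uniform(-1.5, 1.5) * xn
        maps[j] = profile * np.exp(1j * (ramp + rng.uniform(-np.pi, np.pi)))
    center = (yn**2 + xn**2) <= 0.8**2
    sos = np.sum(np.abs(maps) ** 2, axis=0)
    maps /= np.sqrt(sos[center].mean())
    return CoilMaps(maps=maps)


def make_scene(
    geometry: GridGeometry | None = None,
    peak_hz: float = 120.0,
    n_coils: int = 8,
    seed: int = 0,
) -> PhantomScene:
    """Full ground-truth scene; the default is the "prostate120" preset."""
    if geometry is None:
        geometry = default_geometry()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    truth, roi = make_phantom(geometry, seed=sub[0])
    b0 = make_b0_field(geometry, peak_hz=peak_hz, seed=sub[1])
    coils = make_coil_maps(geometry, n_coils=n_coils, seed=sub[2])
    return PhantomScene(
        truth_image=truth,
        roi_mask=roi,
        b0_true=b0,
        coils_true=coils,
        geometry=geometry,
        seed=seed,
    )


def _phase_screen(geometry: GridGeometry, rng: np.random.Generator) -> np.ndarray:
    """Smooth shot-random phase from a degree-<=3 polynomial (radians)."""
    yy, xx = _grid_pixels(geometry)
    yn, xn = yy / (geometry.n_pe / 2.0), xx / (geometry.n_ro / 2.0)
    phi = np.zeros_like(yn * xn)
    for py in range(4):
        for px in range(4 - py):
            phi = phi + rng.normal(0.0, 0.8) * yn**py * xn**px
    return phi


def simulate_acquisition(
    scene: PhantomScene,
    polarity: Polarity,
    f0_hz: float = 0.0,
    snr: float = np.inf,
    diffusion_phase: str = "none",
    seed: int = 0,
    readout_dwell_s: float = 0.0,
) -> MultiCoilKSpace:
    """Simulate one shot's multicoil k-space.

    Applies an optional smooth random diffusion-phase screen to the truth,
    encodes it with the scene's field plus the requested center-frequency
    offset, adds complex Gaussian noise calibrated so the object-interior
    image-domain SNR equals ``snr``, and zeroes the partial-Fourier lines.
    ``readout_dwell_s > 0`` switches to dense exact summation with 2-D
    sample times (model mismatch against the per-line reconstruction
    operators; small grids only — cost is O((n_pe * n_ro)^2)).
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    if diffusion_phase not in ("none", "smooth_random"):
        raise ValueError("diffusion_phase must be 'none' or 'smooth_random'")
    geometry = scene.geometry
    rng = np.random.default_rng(seed)
    img = scene.truth_image.data
    if diffusion_phase == "smooth_random":
        img = img * np.exp(1j * _phase_screen(geometry, rng))
    b0 = scene.b0_true.with_offset(scene.b0_true.f0_offset_hz + f0_hz)
    mask = geometry.sample_mask(polarity)
    if readout_dwell_s > 0.0:
        y = _dense_simulate(img, scene.coils_true, b0, geometry, polarity, readout_dwell_s)
    else:
        op = EncodingOperator(geometry, scene.coils_true, b0, polarity, mask)
        y = op.forward_array(img)
    if np.isfinite(snr):
        support = scene.object_mask
        # per-component std sigma: the unitary DFT maps it to the same
        # image-domain std, so single-coil magnitude SNR ~= mean/sigma
        sigma = np.abs(scene.truth_image.data)[support].mean() / snr
        noise = sigma * (rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape))
        y = y + noise
    y[:, ~mask, :] = 0.0
    return MultiCoilKSpace(data=y, polarity=polarity, sample_mask=mask)


def _dense_simulate(
    img: np.ndarray,
    coils: CoilMaps,
    b0: B0Map,
    geometry: GridGeometry,
    polarity: Polarity,
    readout_dwell_s: float,
) -> np.ndarray:
    """Exact model sum with per-sample (k, l) times; oracle/mismatch path."""
    p, r = geometry.shape
    times = build_sample_times(geometry, polarity).times_s.copy()
    times += polarity.sign * (np.arange(r) - r // 2)[None, :] * readout_dwell_s
    mi, ni = centered_index(p), centered_index(r)
    f_pe = np.exp(-2j * np.pi * np.outer(mi, mi) / p) / np.sqrt(p)
    f_ro = np.exp(-2j * np.pi * np.outer(ni, ni) / r) / np.sqrt(r)
    offres = np.exp(
        -2j * np.pi * times[:, :, None, None] * b0.effective_hz()[None, None, :, :]
    )
    out = np.empty((coils.n_coils, p, r), dtype=complex)
    for j in range(coils.n_coils):
        w = coils.maps[j] * img
        out[j] = np.einsum("km,ln,klmn,mn->kl", f_pe, f_ro, offres, w, optimize=True)
    return out


def simulate_pair(
    scene: PhantomScene,
    f0_hz: float = 0.0,
    snr: float = np.inf,
    diffusion_phase: str = "none",
    seed: int = 0,
) -> tuple[MultiCoilKSpace, MultiCoilKSpace]:
    """Blip-up and blip-down shots with independent noise and phase screens."""
    up_seed, down_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    y_up = simulate_acquisition(
        scene, Polarity.BLIP_UP, f0_hz=f0_hz, snr=snr,
        diffusion_phase=diffusion_phase, seed=up_seed,
    )
    y_down = simulate_acquisition(
        scene, Polarity.BLIP_DOWN, f0_hz=f0_hz, snr=snr,
        diffusion_phase=diffusion_phase, seed=down_seed,
    )
    return y_up, y_down
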