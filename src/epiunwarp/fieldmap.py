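"""B0 field estimation from a dual-echo gradient-echo scan.

The per-voxel off-resonance frequency comes from the phase evolved between
two echoes: ``ΔB0 = angle(echo2 * conj(echo1)) / (2π ΔTE)``.  With only two
echoes the weighted least-squares fit over echo time degenerates to this
weighted two-point phase difference; frequencies outside ``±1/(2 ΔTE)``
alias back into the principal interval (a documented limitation — no
spatial unwrapping is attempted).

Noisy fits are tamed by a robust penalized-least-squares smoother operating
in the DCT domain (quadratic second-difference penalty, iteratively
reweighted bisquare residuals, generalized cross-validation for the
penalty weight), and the field is resampled onto the EPI grid by linear
interpolation in physical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize_scalar

from .grids import B0Map, GridGeometry

__all__ = ["DualEchoSet", "b0_from_dual_echo", "smooth_b0", "resample_to_epi"]


@dataclass(frozen=True)
class DualEchoSet:
    """Complex images at two echo times from a gradient-echo B0 scan."""

    echo1: np.ndarray
    echo2: np.ndarray
    te1_s: float
    te2_s: float

    def __post_init__(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo images must share a shape")
        if self.delta_te_s <= 0:
            raise ValueError("TE difference must be positive")

    @property
    def delta_te_s(self) -> float:
        return self.te2_s - self.te1_s


def b0_from_dual_echo(d: DualEchoSet) -> B0Map:
    """Per-voxel field in Hz from the inter-echo phase difference.

    The result lies in ``±1/(2 ΔTE)`` Hz.  Magnitude-product weights
    ``|echo1 * echo2|`` (normalized to max 1) are stored on the returned map
    for downstream smoothing.
    """
    prod = d.echo2 * np.conj(d.echo1)
    field = np.angle(prod) / (2.0 * np.pi * d.delta_te_s)
    w = np.abs(prod)
    peak = w.max()
    if peak > 0:
        w = w / peak
    return B0Map(delta_b0_hz=field, f0_offset_hz=0.0, weights=w)


def _dct_gamma(shape: tuple[int, ...], s: float) -> np.ndarray:
    """Smoothing gains 1/(1 + s Λ²) on the DCT basis of the 2-D Laplacian."""
    lam = np.zeros(shape)
    for axis, n in enumerate(shape):
        sl = [None] * len(shape)
        sl[axis] = slice(None)
        lam = lam + (2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n))[tuple(sl)]
    return 1.0 / (1.0 + s * lam**2)


def _solve_weighted(
    y: np.ndarray, w: np.ndarray, gamma: np.ndarray, x0: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """Fixed-point iteration for the weighted penalized LS smoother."""
    x = x0
    scale = np.ptp(y) or 1.0
    for _ in range(n_iter):
        x_new = idctn(gamma * dctn(w * (y - x) + x, norm="ortho"), norm="ortho")
        if np.max(np.abs(x_new - x)) < 1e-8 * scale:
            x = x_new
            break
        x = x_new
    return x


def _gcv_score(log10_s: float, y: np.ndarray, w: np.ndarray, x0: np.ndarray) -> float:
    gamma = _dct_gamma(y.shape, 10.0**log10_s)
    x = _solve_weighted(y, w, gamma, x0, n_iter=30)
    n = y.size
    n_eff = max(w.sum(), 1.0)
    rss = float(np.sum(w * (y - x) ** 2))
    tr_h = float(gamma.sum())
    denom = max(1.0 - tr_h / n, 1e-12)
    return (rss / n_eff) / denom**2


def smooth_b0(
    b0: B0Map,
    weights: np.ndarray | None = None,
    strength: float | str | None = "auto",
    robust: bool = True,
) -> B0Map:
    """Robust penalized-least-squares smoothing of a field map.

    Parameters
    ----------
    weights:
        Per-voxel data-fidelity weights in [0, 1]; defaults to the weights
        stored on the map (if any), else uniform.
    strength:
        Penalty weight ``s``.  ``"auto"``/``None`` selects ``s`` by
        generalized cross-validation; ``0`` returns the input unchanged;
        a positive float fixes ``s``.
    robust:
        Iteratively down-weight outlier voxels with bisquare weights.

    The output is clamped to the input's [min, max] range, so constant
    fields are exact fixed points and the smoother never widens the range.
    """
    y = np.asarray(b0.delta_b0_hz, dtype=float)
    if isinstance(strength, str):
        if strength != "auto":
            raise ValueError("strength must be a number, 'auto' or None")
        strength = None
    if strength is not None and strength < 0:
        raise ValueError("smoothing strength must be non-negative")
    if strength == 0:
        return replace(b0, delta_b0_hz=y.copy())
    if weights is None:
        weights = b0.weights if b0.weights is not None else np.ones_like(y)
    w_user = np.clip(np.asarray(weights, dtype=float), 0.0, None)
    if w_user.max() > 0:
        w_user = w_user / w_user.max()

    x = y.copy()
    w_rob = np.ones_like(y)
    n_robust = 3 if robust else 1
    log10_s = None
    for _ in range(n_robust):
        w = w_user * w_rob
        if strength is None:
            res = minimize_scalar(
                _gcv_score,
                bounds=(-4.0, 7.0),
                args=(y, w, x),
                method="bounded",
                options={"xatol": 0.1},
            )
            log10_s = float(res.x)
            s = 10.0**log10_s
        else:
            s = float(strength)
        gamma = _dct_gamma(y.shape, s)
        x = _solve_weighted(y, w, gamma, x)
        if robust:
            r = y - x
            mad = np.median(np.abs(r - np.median(r)))
            sigma = 1.4826 * mad if mad > 0 else (np.std(r) or 1.0)
            u = r / (4.685 * sigma)
            w_rob = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    x = np.clip(x, y.min(), y.max())
    return replace(b0, delta_b0_hz=x)


def resample_to_epi(
    b0: B0Map, source_geom: GridGeometry, target_geom: GridGeometry
) -> B0Map:
    """Resample a field map between grids by linear interpolation in mm.

    The grids are assumed concentric (shared physical center); target voxels
    outside the source field of view are filled with 0 Hz (no correction
    where no field information exists).
    """
    for axis in range(2):
        half_src = source_geom.fov_mm[axis] / 2.0
        half_tgt = target_geom.fov_mm[axis] / 2.0
        if half_src + half_tgt <= abs(half_src - half_tgt):  # pragma: no cover
            raise ValueError("source and target fields of view do not overlap")
    coords = []
    src_shape = (source_geom.n_pe, source_geom.n_ro)
    tgt_shape = (target_geom.n_pe, target_geom.n_ro)
    for axis in range(2):
        n_t, n_s = tgt_shape[axis], src_shape[axis]
        pix_t = target_geom.pixel_mm[axis]
        pix_s = source_geom.pixel_mm[axis]
        phys = (np.arange(n_t) - (n_t - 1) / 2.0) * pix_t
        coords.append(phys / pix_s + (n_s - 1) / 2.0)
    grid = np.meshgrid(*coords, indexing="ij")
    if b0.delta_b0_hz.shape != src_shape:
        raise ValueError("field map shape does not match source geometry")
    out = map_coordinates(
        b0.delta_b0_hz, np.stack(grid), order=1, mode="constant", cval=0.0
    )
    return B0Map(delta_b0_hz=out, f0_offset_hz=b0.f0_offset_hz)
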