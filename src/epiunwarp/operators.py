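"""Off-resonance EPI encoding operator E and its adjoint.

The forward model maps an image ``x`` to the k-space of coil ``j``:

    Y_j(k, l) = sum_{m,n} C_j(m,n) x(m,n)
                exp(-2πi ((m-c)(k-c)/P + (n-c')(l-c')/R))
                exp(-2πi (ΔB0(m,n) + Δf0) t(k))

with ``P = n_pe``, ``R = n_ro``, centered unitary DFT kernels, and the
per-sample time ``t(k)`` depending only on the phase-encode line index
(readout dwell is microseconds against millisecond echo spacing, so
intra-line timing is neglected).  The two blip polarities differ only in the
sign of ``t``, which makes a constant effective field translate the image by
``±f/bw`` pixels — equal and opposite between polarities.

The fast path evaluates the PE direction with a precomputed kernel
``K[k,m,n] = exp(-2πi ΔB0(m,n) t_k) F[k,m]`` (exact under per-line timing)
and the readout direction with an FFT; :func:`dense_encoding_matrix` builds
the same operator as an explicit matrix for small-grid oracle checks.
"""

from __future__ import annotations

import numpy as np

from .fourier import centered_dft_matrix, cfft, cifft
from .grids import (
    B0Map,
    CoilMaps,
    ComplexImage,
    DimensionError,
    GridGeometry,
    InvalidGeometryError,
    MultiCoilKSpace,
    Polarity,
    SampleTimeMap,
)

__all__ = [
    "build_sample_times",
    "EncodingOperator",
    "forward_encode",
    "adjoint_encode",
    "conjugate_phase",
    "pixel_shift_map",
    "dense_encoding_matrix",
]


def build_sample_times(geometry: GridGeometry, polarity: Polarity) -> SampleTimeMap:
    """Per-sample acquisition times for one blip polarity.

    ``t(k, l) = s (k - k_echo) * echo_spacing`` with ``s = +1`` for blip-up
    and ``-1`` for blip-down; the echo-center line is the zero of time.
    """
    if geometry.echo_spacing_s <= 0:
        raise InvalidGeometryError("echo spacing must be positive")
    line = polarity.sign * (np.arange(geometry.n_pe) - geometry.k_echo) * geometry.echo_spacing_s
    times = np.broadcast_to(line[:, None], geometry.shape).copy()
    return SampleTimeMap(times_s=times, polarity=polarity)


class EncodingOperator:
    """One-polarity multicoil encoding operator with precomputed kernels.

    The global frequency offset enters only as a per-line phase
    ``exp(-2πi f0 t_k)``, so evaluations at different offsets (needed by the
    mutual-information search) reuse the ΔB0 kernel.
    """

    def __init__(
        self,
        geometry: GridGeometry,
        coils: CoilMaps,
        b0: B0Map,
        polarity: Polarity,
        sample_mask: np.ndarray | None = None,
    ) -> None:
        if coils.maps.shape[1:] != geometry.shape:
            raise DimensionError("coil maps do not match geometry")
        if b0.delta_b0_hz.shape != geometry.shape:
            raise DimensionError("B0 map does not match geometry")
        self.geometry = geometry
        self.coils = coils
        self.b0 = b0
        self.polarity = polarity
        self.times = build_sample_times(geometry, polarity)
        t = self.times.line_times_s
        self._t = t
        # K[k, m, n]: PE-direction DFT kernel with off-resonance phase accrual
        f_pe = centered_dft_matrix(geometry.n_pe)
        self._kernel = (
            np.exp(-2j * np.pi * t[:, None, None] * b0.delta_b0_hz[None, :, :])
            * f_pe[:, :, None]
        )
        if sample_mask is None:
            sample_mask = np.ones(geometry.n_pe, dtype=bool)
        self.sample_mask = np.asarray(sample_mask, dtype=bool)

    def _offset_phase(self, extra_f0_hz: float) -> np.ndarray:
        f0 = self.b0.f0_offset_hz + extra_f0_hz
        return np.exp(-2j * np.pi * f0 * self._t)

    def forward_array(self, x: np.ndarray, extra_f0_hz: float = 0.0) -> np.ndarray:
        """Image (n_pe, n_ro) -> multicoil k-space (J, n_pe, n_ro)."""
        if x.shape != self.geometry.shape:
            raise DimensionError("image shape does not match operator geometry")
        xt = self.coils.maps * x[None, :, :]
        hybrid = np.einsum("jmn,kmn->jkn", xt, self._kernel)
        hybrid *= self._offset_phase(extra_f0_hz)[None, :, None]
        y = cfft(hybrid, axis=-1)
        y[:, ~self.sample_mask, :] = 0.0
        return y

    def adjoint_array(self, y: np.ndarray, extra_f0_hz: float = 0.0) -> np.ndarray:
        """Multicoil k-space (J, n_pe, n_ro) -> coil-combined image (n_pe, n_ro)."""
        if y.shape != (self.coils.n_coils, *self.geometry.shape):
            raise DimensionError("k-space shape does not match operator")
        ym = np.where(self.sample_mask[None, :, None], y, 0.0)
        hybrid = cifft(ym, axis=-1)
        hybrid *= np.conj(self._offset_phase(extra_f0_hz))[None, :, None]
        xt = np.einsum("jkn,kmn->jmn", hybrid, np.conj(self._kernel))
        return np.sum(np.conj(self.coils.maps) * xt, axis=0)

    def normal_array(self, x: np.ndarray) -> np.ndarray:
        """E^H E applied to an image."""
        return self.adjoint_array(self.forward_array(x))

    def forward(self, x: ComplexImage, extra_f0_hz: float = 0.0) -> MultiCoilKSpace:
        return MultiCoilKSpace(
            data=self.forward_array(x.data, extra_f0_hz),
            polarity=self.polarity,
            sample_mask=self.sample_mask,
        )

    def adjoint(self, y: MultiCoilKSpace, extra_f0_hz: float = 0.0) -> ComplexImage:
        if y.polarity is not self.polarity:
            raise ValueError("k-space polarity does not match operator polarity")
        return ComplexImage(self.adjoint_array(y.data, extra_f0_hz), self.geometry)


def forward_encode(
    x: ComplexImage,
    coils: CoilMaps,
    b0: B0Map,
    times: SampleTimeMap,
    sample_mask: np.ndarray | None = None,
) -> MultiCoilKSpace:
    """Apply the encoding model E to an image (one blip polarity)."""
    op = EncodingOperator(x.geometry, coils, b0, times.polarity, sample_mask)
    return op.forward(x)


def adjoint_encode(
    y: MultiCoilKSpace,
    coils: CoilMaps,
    b0: B0Map,
    times: SampleTimeMap,
    geometry: GridGeometry,
) -> ComplexImage:
    """Apply E^H: the conjugate-phase, coil-combined image of multicoil k-space."""
    op = EncodingOperator(geometry, coils, b0, times.polarity, y.sample_mask)
    return op.adjoint(y)


def conjugate_phase(
    y: MultiCoilKSpace,
    coils: CoilMaps,
    b0: B0Map,
    geometry: GridGeometry,
    extra_f0_hz: float = 0.0,
) -> ComplexImage:
    """Conjugate-phase reconstruction x_cp = sum_j E_j^H Y_j."""
    op = EncodingOperator(geometry, coils, b0, y.polarity, y.sample_mask)
    return ComplexImage(op.adjoint_array(y.data, extra_f0_hz), geometry)


def pixel_shift_map(
    b0: B0Map, geometry: GridGeometry, polarity: Polarity = Polarity.BLIP_UP
) -> np.ndarray:
    """Apparent PE displacement in pixels, ``(ΔB0 + Δf0) / bw_per_pixel``.

    Positive values displace signal toward +PE for blip-up; blip-down negates.
    """
    bw = geometry.bw_per_pixel_hz
    if not np.isfinite(bw) or bw <= 0:
        raise InvalidGeometryError("bandwidth per pixel must be positive")
    return polarity.sign * b0.effective_hz() / bw


def dense_encoding_matrix(
    geometry: GridGeometry,
    coils: CoilMaps,
    b0: B0Map,
    times: SampleTimeMap,
    sample_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Explicit (J*P*R, P*R) matrix of the encoding operator.

    Direct evaluation of the model sum, independent of the FFT fast path;
    intended for small grids (<= ~32x32) as a test oracle.
    """
    p, r = geometry.shape
    j = coils.n_coils
    mi = np.arange(p) - p // 2
    ni = np.arange(r) - r // 2
    # Fourier kernel along PE: (k, m), readout: (l, n)
    f_pe = np.exp(-2j * np.pi * np.outer(mi, mi) / p) / np.sqrt(p)
    f_ro = np.exp(-2j * np.pi * np.outer(ni, ni) / r) / np.sqrt(r)
    t = times.line_times_s
    offres = np.exp(
        -2j * np.pi * t[:, None, None] * b0.effective_hz()[None, :, :]
    )  # (k, m, n)
    # E[j, k, l, m, n] = C_j(m,n) F_pe[k,m] F_ro[l,n] offres[k,m,n]
    e = (
        coils.maps[:, None, None, :, :]
        * f_pe[None, :, None, :, None]
        * f_ro[None, None, :, None, :]
        * offres[None, :, None, :, :]
    )
    if sample_mask is not None:
        e[:, ~np.asarray(sample_mask, bool), :, :, :] = 0.0
    return e.reshape(j * p * r, p * r)
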