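"""Centered unitary discrete Fourier transforms.

Every Fourier operation in this package uses one fixed convention: unitary
normalization, negative exponent on the forward transform, and the DC sample
at index ``floor(n/2)`` in both image and k-space.  Keeping the convention in
one module makes operator/adjoint pairs and their dense-matrix oracles agree
to machine precision.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import fft, fftshift, ifft, ifftshift


def cfft(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered unitary forward DFT along one axis."""
    return fftshift(fft(ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis)


def cifft(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered unitary inverse DFT along one axis."""
    return fftshift(ifft(ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis)


def cfft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT over the last two axes."""
    return cfft(cfft(x, axis=-1), axis=-2)


def cifft2(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D inverse DFT over the last two axes."""
    return cifft(cifft(x, axis=-1), axis=-2)


def centered_dft_matrix(n: int) -> np.ndarray:
    """Dense matrix of the centered unitary DFT, ``F[k, m] = e^{-2πi(m-c)(k-c)/n}/√n``.

    ``c = n // 2`` so that ``F @ x`` equals :func:`cfft` applied to ``x``.
    """
    idx = np.arange(n) - n // 2
    return np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)


def centered_index(n: int) -> np.ndarray:
    """Signed sample indices ``m - floor(n/2)`` used in the encoding exponent."""
    return np.arange(n) - n // 2
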