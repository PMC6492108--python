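"""Diffusion-phase alignment between blip-up and blip-down data.

Tissue motion during the diffusion gradients imprints a smooth, shot-random
phase on each acquisition.  Combining the two polarities' complex data with
mismatched phase cancels signal; the fix is the voxelwise relative phase of
the two conjugate-phase reconstructions, removed from the blip-up k-space
(blip-down serves as the phase reference) by an image-domain unit-modulus
multiply.
"""

from __future__ import annotations

import numpy as np

from .fourier import cfft2, cifft2
from .grids import ComplexImage, DimensionError, MultiCoilKSpace, PhaseMap

__all__ = ["compute_phase_map", "apply_phase_to_kspace"]

#: relative-magnitude floor below which the phase estimate is noise
MAGNITUDE_FLOOR = 1e-6


def compute_phase_map(
    xcp1: ComplexImage, xcp2: ComplexImage, floor: float = MAGNITUDE_FLOOR
) -> PhaseMap:
    """Voxelwise phase discrepancy ΔΦ = angle(xcp1 · conj(xcp2)).

    Voxels whose magnitude product falls below ``floor`` times the maximum
    product get ΔΦ = 0: the angle of a near-zero complex number is noise.
    """
    if xcp1.data.shape != xcp2.data.shape:
        raise DimensionError("conjugate-phase images must share a shape")
    prod = xcp1.data * np.conj(xcp2.data)
    mag = np.abs(prod)
    phi = np.angle(prod)
    phi[mag < floor * mag.max()] = 0.0
    return PhaseMap(delta_phi_rad=phi)


def apply_phase_to_kspace(y1: MultiCoilKSpace, phi: PhaseMap) -> MultiCoilKSpace:
    """Remove ΔΦ from each coil of a k-space set.

    Per coil: inverse Fourier transform to image space, multiply by
    exp(-i ΔΦ), Fourier transform back.  Unacquired partial-Fourier lines
    are re-zeroed after the round trip so the sampling mask stays exact.
    """
    if phi.delta_phi_rad.shape != y1.data.shape[1:]:
        raise DimensionError("phase map does not match k-space grid")
    img = cifft2(y1.data)
    img *= np.exp(-1j * phi.delta_phi_rad)[None, :, :]
    out = cfft2(img)
    out[:, ~y1.sample_mask, :] = 0.0
    return MultiCoilKSpace(data=out, polarity=y1.polarity, sample_mask=y1.sample_mask)
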