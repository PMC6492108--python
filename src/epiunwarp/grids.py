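"""Acquisition geometry and the in-memory containers shared across the package.

Arrays are stored phase-encode-major: axis 0 runs over phase-encode (PE)
lines, axis 1 over readout points, regardless of the physical orientation
recorded in :attr:`GridGeometry.pe_axis`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Polarity",
    "GridGeometry",
    "SampleTimeMap",
    "ComplexImage",
    "CoilMaps",
    "B0Map",
    "MultiCoilKSpace",
    "PhaseMap",
    "InvalidGeometryError",
    "DimensionError",
]


class InvalidGeometryError(ValueError):
    """Raised for non-physical acquisition geometry."""


class DimensionError(ValueError):
    """Raised when array shapes are mutually inconsistent."""


class Polarity(str, Enum):
    """Phase-encode blip polarity of an EPI shot."""

    BLIP_UP = "blip_up"
    BLIP_DOWN = "blip_down"

    @property
    def sign(self) -> int:
        return 1 if self is Polarity.BLIP_UP else -1

    @property
    def opposite(self) -> "Polarity":
        return Polarity.BLIP_DOWN if self is Polarity.BLIP_UP else Polarity.BLIP_UP


@dataclass(frozen=True)
class GridGeometry:
    """Matrix size, spacing and EPI timing for one 2-D slice.

    Parameters
    ----------
    n_pe, n_ro:
        Number of phase-encode lines and readout points.
    pixel_mm:
        Physical spacing ``(pe, ro)`` in millimetres.
    echo_spacing_s:
        Time between consecutive phase-encode lines, seconds.  The bandwidth
        per pixel along PE is ``1 / (n_pe * echo_spacing_s)``.
    pe_axis:
        Physical orientation of the phase-encode axis ("row" or "col");
        metadata only — arrays are always stored PE-major.
    partial_fourier:
        Fraction of PE lines acquired (half-scan factor), in (0.5, 1].
    """

    n_pe: int
    n_ro: int
    pixel_mm: tuple[float, float] = (2.0, 2.0)
    echo_spacing_s: float = 1.0e-3
    pe_axis: str = "row"
    partial_fourier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pe < 2 or self.n_ro < 2:
            raise InvalidGeometryError("n_pe and n_ro must both be >= 2")
        if self.echo_spacing_s <= 0:
            raise InvalidGeometryError("echo spacing must be positive")
        if not 0.5 < self.partial_fourier <= 1.0:
            raise InvalidGeometryError("partial_fourier must lie in (0.5, 1.0]")
        if self.pe_axis not in ("row", "col"):
            raise InvalidGeometryError("pe_axis must be 'row' or 'col'")
        if len(self.pixel_mm) != 2 or min(self.pixel_mm) <= 0:
            raise InvalidGeometryError("pixel_mm must be two positive spacings")

    @classmethod
    def from_bandwidth(
        cls,
        n_pe: int,
        n_ro: int,
        bw_per_pixel_hz: float,
        pixel_mm: tuple[float, float] = (2.0, 2.0),
        pe_axis: str = "row",
        partial_fourier: float = 1.0,
    ) -> "GridGeometry":
        """Build a geometry from the PE bandwidth per pixel in Hz."""
        if bw_per_pixel_hz <= 0:
            raise InvalidGeometryError("bandwidth per pixel must be positive")
        return cls(
            n_pe=n_pe,
            n_ro=n_ro,
            pixel_mm=pixel_mm,
            echo_spacing_s=1.0 / (bw_per_pixel_hz * n_pe),
            pe_axis=pe_axis,
            partial_fourier=partial_fourier,
        )

    @property
    def bw_per_pixel_hz(self) -> float:
        """Phase-encode bandwidth per pixel, ``1 / (n_pe * echo_spacing_s)``."""
        return 1.0 / (self.n_pe * self.echo_spacing_s)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pe, self.n_ro)

    @property
    def k_echo(self) -> int:
        """Index of the k-space-center (echo) PE line."""
        return self.n_pe // 2

    @property
    def n_acquired(self) -> int:
        """Number of PE lines acquired under the half-scan factor."""
        return int(math.ceil(self.partial_fourier * self.n_pe))

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.n_pe * self.pixel_mm[0], self.n_ro * self.pixel_mm[1])

    def sample_mask(self, polarity: Polarity) -> np.ndarray:
        """Boolean acquired-line indicator for one blip polarity.

        Half scan skips the lines acquired earliest in the echo train; the
        two polarities traverse k-space in opposite directions, so the
        skipped block sits at opposite k-space ends.  The echo-center line
        is always acquired.
        """
        mask = np.zeros(self.n_pe, dtype=bool)
        if polarity is Polarity.BLIP_UP:
            mask[self.n_pe - self.n_acquired :] = True
        else:
            mask[: self.n_acquired] = True
        return mask


@dataclass(frozen=True)
class SampleTimeMap:
    """Acquisition time (s) of every k-space sample for one blip polarity."""

    times_s: np.ndarray
    polarity: Polarity

    @property
    def line_times_s(self) -> np.ndarray:
        """Per-PE-line times; readout-direction timing is neglected."""
        return self.times_s[:, 0]


@dataclass(frozen=True)
class ComplexImage:
    """A complex 2-D image tied to its grid geometry."""

    data: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.data.shape != self.geometry.shape:
            raise DimensionError(
                f"image shape {self.data.shape} != geometry {self.geometry.shape}"
            )


@dataclass(frozen=True)
class CoilMaps:
    """Complex receive sensitivities, one map per coil, on the image grid."""

    maps: np.ndarray  # (J, n_pe, n_ro)

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise DimensionError("coil maps must be a (J, n_pe, n_ro) array, J >= 1")
        if not np.any(np.sum(np.abs(self.maps) ** 2, axis=0) > 0):
            raise ValueError("combined coil sensitivity is zero everywhere")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def sum_of_squares(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass(frozen=True)
class B0Map:
    """Per-voxel off-resonance in Hz plus a scalar center-frequency offset.

    The field seen by the encoding operators is ``delta_b0_hz + f0_offset_hz``
    everywhere; ``f0_offset_hz`` models global scanner frequency drift.
    """

    delta_b0_hz: np.ndarray
    f0_offset_hz: float = 0.0
    weights: np.ndarray | None = None  # optional fit reliability, for smoothing

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta_b0_hz)):
            raise ValueError("B0 map contains non-finite values")
        if not np.isfinite(self.f0_offset_hz):
            raise ValueError("f0 offset must be finite")

    def effective_hz(self) -> np.ndarray:
        return self.delta_b0_hz + self.f0_offset_hz

    def with_offset(self, f0_offset_hz: float) -> "B0Map":
        return replace(self, f0_offset_hz=float(f0_offset_hz))


@dataclass(frozen=True)
class MultiCoilKSpace:
    """Complex k-space samples per coil for one blip polarity.

    ``sample_mask`` marks acquired PE lines (partial Fourier); unacquired
    lines must be exactly zero.
    """

    data: np.ndarray  # (J, n_pe, n_ro)
    polarity: Polarity
    sample_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise DimensionError("k-space must be a (J, n_pe, n_ro) array")
        if self.sample_mask is None:
            object.__setattr__(self, "sample_mask", np.ones(self.data.shape[1], bool))
        mask = np.asarray(self.sample_mask, dtype=bool)
        if mask.shape != (self.data.shape[1],):
            raise DimensionError("sample_mask length must equal n_pe")
        object.__setattr__(self, "sample_mask", mask)
        if np.any(self.data[:, ~mask, :] != 0):
            raise ValueError("unacquired PE lines must be exactly zero")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class PhaseMap:
    """Per-voxel phase correction in radians, principal interval (-π, π]."""

    delta_phi_rad: np.ndarray

    def __post_init__(self) -> None:
        phi = self.delta_phi_rad
        if not np.all(np.isfinite(phi)):
            raise ValueError("phase map contains non-finite values")
        if np.any(phi <= -np.pi) or np.any(phi > np.pi):
            raise ValueError("phase map values must lie in (-pi, pi]")
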