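"""Joint blip-up/blip-down model-based reconstruction.

The two polarities' encoding operators and (phase-corrected) k-space data
are stacked into one least-squares problem and the normal equations

    (E1^H E1 + E2^H E2) x = E1^H Y1 + E2^H Y2

are solved by conjugate gradients from x0 = 0, unpreconditioned and
unregularized.  Convergence is declared when the normalized residual
``r = ||E^H E x - E^H Y|| / ||E^H Y||`` drops below a small ε
(default 0.0025), with a safety cap on the iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import B0Map, CoilMaps, ComplexImage, GridGeometry, MultiCoilKSpace, Polarity
from .offset import OffsetConfig, OffsetEstimate, estimate_frequency_offset
from .operators import EncodingOperator
from .phase import apply_phase_to_kspace, compute_phase_map

__all__ = [
    "ReconConfig",
    "ReconResult",
    "JointSystem",
    "build_joint_system",
    "cg_reconstruct",
    "reconstruct_dwi_series",
    "DwiSeriesResult",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when the requested pipeline lacks a required input."""


@dataclass(frozen=True)
class ReconConfig:
    epsilon: float = 0.0025          # normalized-residual stopping threshold
    max_iter: int = 30               # CG safety cap
    use_phase_correction: bool = True
    use_offset_correction: bool = True
    offset: OffsetConfig = field(default_factory=OffsetConfig)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass(frozen=True)
class ReconResult:
    image: ComplexImage
    residuals: np.ndarray  # normalized residual per CG iteration
    n_iter: int
    converged: bool


class JointSystem:
    """Stacked normal-equation system over one or more encoding operators.

    Exposes the matvec ``x -> sum_i E_i^H E_i x`` and the right-hand side
    ``sum_i E_i^H Y_i``.  The usual case stacks one blip-up and one
    blip-down term; the dynamic-pair phase-correction experiment stacks two
    same-polarity terms.
    """

    def __init__(self, terms: list[tuple[EncodingOperator, np.ndarray]]) -> None:
        if not terms:
            raise ValueError("joint system needs at least one (operator, data) term")
        self.terms = terms
        self.geometry = terms[0][0].geometry
        for op, y in terms:
            if op.geometry.shape != self.geometry.shape:
                raise ValueError("all operators must share a grid")
            if y.shape != (op.coils.n_coils, *op.geometry.shape):
                raise ValueError("data shape does not match its operator")

    def rhs(self) -> np.ndarray:
        out = np.zeros(self.geometry.shape, dtype=complex)
        for op, y in self.terms:
            out += op.adjoint_array(y)
        return out

    def normal(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.geometry.shape, dtype=complex)
        for op, _ in self.terms:
            out += op.adjoint_array(op.forward_array(x))
        return out


def build_joint_system(
    y_up_pc: MultiCoilKSpace,
    y_down: MultiCoilKSpace,
    coils: CoilMaps,
    b0: B0Map,
    geometry: GridGeometry,
) -> JointSystem:
    """Stack a (phase-corrected) blip-up set with a blip-down set."""
    if y_up_pc.polarity is not Polarity.BLIP_UP or y_down.polarity is not Polarity.BLIP_DOWN:
        raise ValueError("build_joint_system needs one blip-up and one blip-down set")
    op_up = EncodingOperator(geometry, coils, b0, Polarity.BLIP_UP, y_up_pc.sample_mask)
    op_down = EncodingOperator(geometry, coils, b0, Polarity.BLIP_DOWN, y_down.sample_mask)
    return JointSystem([(op_up, y_up_pc.data), (op_down, y_down.data)])


def cg_reconstruct(system: JointSystem, cfg: ReconConfig | None = None) -> ReconResult:
    """Conjugate gradients on the stacked normal equations.

    The CG residual is exactly the normal-equation residual, so the
    normalized stopping quantity comes free each iteration.
    """
    if cfg is None:
        cfg = ReconConfig()
    b = system.rhs()
    b_norm = float(np.linalg.norm(b))
    geometry = system.geometry
    if b_norm == 0.0:
        return ReconResult(
            image=ComplexImage(np.zeros(geometry.shape, complex), geometry),
            residuals=np.array([0.0]),
            n_iter=0,
            converged=True,
        )
    x = np.zeros(geometry.shape, dtype=complex)
    r = b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    residuals: list[float] = []
    n_iter = 0
    for _ in range(cfg.max_iter):
        ap = system.normal(p)
        alpha = rs / float(np.vdot(p, ap).real)
        x += alpha * p
        r -= alpha * ap
        rs_new = float(np.vdot(r, r).real)
        n_iter += 1
        res = np.sqrt(rs_new) / b_norm
        residuals.append(res)
        if res < cfg.epsilon:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return ReconResult(
        image=ComplexImage(x, geometry),
        residuals=np.asarray(residuals),
        n_iter=n_iter,
        converged=bool(residuals[-1] < cfg.epsilon),
    )


@dataclass(frozen=True)
class DwiSeriesResult:
    """Per-direction corrected reconstructions and their magnitude average."""

    offset: OffsetEstimate | None
    b0_used: B0Map
    per_direction: list[ReconResult]
    magnitudes: np.ndarray        # (n_dir, n_pe, n_ro)
    mean_magnitude: np.ndarray    # (n_pe, n_ro)


def reconstruct_dwi_series(
    dwi_pairs: list[tuple[MultiCoilKSpace, MultiCoilKSpace]],
    coils: CoilMaps,
    b0: B0Map,
    geometry: GridGeometry,
    cfg: ReconConfig | None = None,
    b0_pair: tuple[MultiCoilKSpace, MultiCoilKSpace] | None = None,
) -> DwiSeriesResult:
    """Run the full three-step framework over a diffusion series.

    Step 1 (optional): estimate the center-frequency offset from the b = 0
    blip-up/blip-down pair and fold it into the field map.  Then per
    diffusion direction: conjugate-phase reconstruct both polarities,
    estimate and remove the diffusion phase discrepancy (step 2), and solve
    the stacked system by CG (step 3).  Outputs per-direction magnitudes and
    their mean (trace-weighted image when directions are isotropic).
    """
    if cfg is None:
        cfg = ReconConfig()
    offset: OffsetEstimate | None = None
    b0_used = b0
    if cfg.use_offset_correction:
        if b0_pair is None:
            raise ConfigurationError("offset correction requires a b = 0 blip pair")
        offset = estimate_frequency_offset(
            b0_pair[0], b0_pair[1], coils, b0, geometry, cfg.offset
        )
        b0_used = b0.with_offset(b0.f0_offset_hz + offset.f0_hz)

    results: list[ReconResult] = []
    for y_up, y_down in dwi_pairs:
        op_up = EncodingOperator(geometry, coils, b0_used, Polarity.BLIP_UP, y_up.sample_mask)
        op_down = EncodingOperator(
            geometry, coils, b0_used, Polarity.BLIP_DOWN, y_down.sample_mask
        )
        y_up_used = y_up
        if cfg.use_phase_correction:
            xcp1 = ComplexImage(op_up.adjoint_array(y_up.data), geometry)
            xcp2 = ComplexImage(op_down.adjoint_array(y_down.data), geometry)
            phi = compute_phase_map(xcp1, xcp2)
            y_up_used = apply_phase_to_kspace(y_up, phi)
        system = JointSystem([(op_up, y_up_used.data), (op_down, y_down.data)])
        results.append(cg_reconstruct(system, cfg))

    magnitudes = np.stack([np.abs(r.image.data) for r in results])
    return DwiSeriesResult(
        offset=offset,
        b0_used=b0_used,
        per_direction=results,
        magnitudes=magnitudes,
        mean_magnitude=magnitudes.mean(axis=0),
    )
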