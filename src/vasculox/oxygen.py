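"""Steady-state tissue oxygenation by iterated Green's-function diffusion.

The diffusion equation's Green's function is a Gaussian, so one explicit
time step of length t is a convolution of the pO₂ field with a Gaussian
kernel of per-axis standard deviation σ = √(2·D_O·t). The discrete kernel
is sampled at voxel centres, truncated, and renormalised to unit sum so
the discrete operator conserves mass exactly (this absorbs the analytic
normalisation constant k). Between diffusion steps, tissue consumption is
subtracted following Michaelis–Menten kinetics, C = C₀·pO₂/(pO₂ + K_M),
and vessel voxels are re-clamped to their fixed intravascular values
(Dirichlet sources). Iteration continues until the total tissue pO₂
stabilises.

The Gaussian factorises across axes, so the convolution is carried out as
three 1-D passes with zero-padded boundaries; this is numerically
identical (to rounding) to dense convolution with the 3-D kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .grids import OxygenField, VesselGrid

__all__ = [
    "PhysParams",
    "DiffusionKernel",
    "assign_vessel_po2",
    "diffusion_kernel",
    "diffusion_step",
    "consumption_rate",
    "apply_consumption",
    "solve_steady_state",
    "SteadyStateResult",
]


@dataclass(frozen=True)
class PhysParams:
    """Physical constants of the oxygen transport model.

    D_O : oxygen diffusion coefficient in tissue, μm² s⁻¹
    C_0 : oxygen demand at unlimited supply, mmHg s⁻¹
    K_M : Michaelis constant (pO₂ at which consumption is C_0/2), mmHg
    t   : time step, s
    p_arterial, p_venous : intravascular pO₂ at the feeding point and at
        the most distant leaf, mmHg
    """

    D_O: float = 2000.0
    C_0: float = 15.0
    K_M: float = 1.0
    t: float = 0.1
    p_arterial: float = 100.0
    p_venous: float = 40.0

    def __post_init__(self) -> None:
        for name in ("D_O", "C_0", "K_M", "t", "p_arterial", "p_venous"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.p_arterial <= self.p_venous:
            raise ValueError("p_arterial must exceed p_venous")

    @property
    def sigma_um(self) -> float:
        """Per-axis standard deviation of one diffusion step, √(2·D_O·t)."""
        return float(np.sqrt(2.0 * self.D_O * self.t))

    @property
    def k(self) -> float:
        """The analytic normalisation constant 1000·(4·D_O·t·π)^(−3/2),
        μm⁻³ s^{3/2}. Inert once the discrete kernel is renormalised to
        unit sum; recorded for completeness."""
        return 1000.0 * (4.0 * self.D_O * self.t * np.pi) ** -1.5


def assign_vessel_po2(vgrid: VesselGrid, phys: PhysParams) -> OxygenField:
    """Assign intravascular pO₂: arterial at the feeding point, falling
    linearly with centreline path distance to venous at the most distant
    vessel voxel. Tissue voxels start at zero."""
    d = vgrid.path_distance[vgrid.mask]
    source = np.zeros(vgrid.shape)
    if d.size:
        d_max = float(d.max())
        if d_max == 0.0:
            source[vgrid.mask] = phys.p_arterial
        else:
            source[vgrid.mask] = (phys.p_arterial
                                  - (phys.p_arterial - phys.p_venous) * d / d_max)
    return OxygenField(values=source.copy(), mask=vgrid.mask, source=source,
                       spacing=vgrid.spacing, origin=vgrid.origin)


@dataclass(frozen=True)
class DiffusionKernel:
    """Discrete Gaussian propagator for one time step.

    ``axis_kernel`` is the normalised 1-D factor; ``array`` its 3-D outer
    product (sum exactly renormalised to 1).
    """

    axis_kernel: np.ndarray
    sigma_um: float
    spacing: float

    @property
    def array(self) -> np.ndarray:
        k = self.axis_kernel
        arr = k[:, None, None] * k[None, :, None] * k[None, None, :]
        return arr / arr.sum()


def diffusion_kernel(phys: PhysParams, spacing: float,
                     truncation_sigmas: float = 4.0) -> DiffusionKernel:
    """Sample the Gaussian Green's function at voxel centres.

    Truncated at ``truncation_sigmas``·σ per axis and renormalised to unit
    sum. A σ below half a voxel means the chosen time step produces no
    resolvable diffusion on this grid and is rejected.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    sigma = phys.sigma_um
    if sigma < spacing / 2.0:
        raise ValueError(
            f"diffusion length σ = {sigma:.2f} μm is below half the voxel "
            f"size {spacing} μm: no measurable diffusion per step. "
            "Increase the time step t or refine the spacing.")
    half = int(np.ceil(truncation_sigmas * sigma / spacing))
    x = np.arange(-half, half + 1) * spacing
    w = np.exp(-x ** 2 / (4.0 * phys.D_O * phys.t))
    w /= w.sum()
    return DiffusionKernel(axis_kernel=w, sigma_um=sigma, spacing=spacing)


def diffusion_step(field: OxygenField, kernel: DiffusionKernel) -> OxygenField:
    """One diffusion step: Gaussian convolution with zero-padded boundaries,
    then vessel voxels re-clamped to their fixed source values."""
    if kernel.spacing != field.spacing:
        raise ValueError("kernel spacing does not match the field")
    out = field.values
    for axis in range(3):
        out = convolve1d(out, kernel.axis_kernel, axis=axis,
                         mode="constant", cval=0.0)
    out[field.mask] = field.source[field.mask]
    return OxygenField(out, field.mask, field.source,
                       field.spacing, field.origin)


def consumption_rate(po2, phys: PhysParams):
    """Michaelis–Menten consumption C = C₀·pO₂/(pO₂ + K_M), mmHg s⁻¹.
    Monotone in pO₂ and saturating at C₀."""
    po2 = np.asarray(po2, dtype=float)
    return phys.C_0 * po2 / (po2 + phys.K_M)


def apply_consumption(field: OxygenField, phys: PhysParams) -> OxygenField:
    """Subtract one time step of tissue consumption, clamped at zero
    (the explicit update t·C can overshoot near pO₂ = 0). Vessel voxels
    are not consumers."""
    out = field.values.copy()
    tissue = ~field.mask
    v = out[tissue]
    out[tissue] = np.maximum(0.0, v - phys.t * phys.C_0 * v / (v + phys.K_M))
    return OxygenField(out, field.mask, field.source,
                       field.spacing, field.origin)


@dataclass
class SteadyStateResult:
    field: OxygenField
    n_iterations: int
    converged: bool
    history: np.ndarray  # total tissue pO₂ per iteration


def solve_steady_state(field: OxygenField, phys: PhysParams,
                       tolerance: float = 1e-4, max_iter: int = 5000,
                       kernel: DiffusionKernel | None = None) -> SteadyStateResult:
    """Alternate diffusion and consumption until the total tissue pO₂ is
    stationary.

    Convergence requires the relative change of the summed tissue pO₂ to
    stay below ``tolerance`` for three consecutive iterations. Failure to
    converge within ``max_iter`` returns the last field with a warning and
    ``converged=False``.
    """
    if kernel is None:
        kernel = diffusion_kernel(phys, field.spacing)
    if not field.mask.any():
        # no sources: consumption drains everything; the zero field is the fixed point
        zero = OxygenField(np.zeros(field.shape), field.mask, field.source,
                           field.spacing, field.origin)
        return SteadyStateResult(zero, 0, True, np.zeros(1))

    tissue = ~field.mask
    cur = field.copy()
    prev_total = float(cur.values[tissue].sum())
    history = [prev_total]
    streak = 0
    for it in range(1, max_iter + 1):
        cur = diffusion_step(cur, kernel)
        cur = apply_consumption(cur, phys)
        total = float(cur.values[tissue].sum())
        history.append(total)
        rel = abs(total - prev_total) / max(abs(prev_total), 1e-300)
        prev_total = total
        streak = streak + 1 if rel < tolerance else 0
        if streak >= 3:
            return SteadyStateResult(cur, it, True, np.asarray(history))
    warnings.warn(f"steady state not reached within {max_iter} iterations "
                  f"(last relative change {rel:.2e})", stacklevel=2)
    return SteadyStateResult(cur, max_iter, False, np.asarray(history))
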