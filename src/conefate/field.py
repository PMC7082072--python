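"""Deterministic T3 diffusion field.

2D forward-Euler finite-difference solver on the (length x width) strip with
constant-concentration (Dirichlet) dorsal/ventral ends and zero-flux sides.
The 5 um tissue depth enters only through the voxel volume used for
molecule <-> concentration conversion during cell exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np


@dataclass
class T3Field:
    conc: np.ndarray  # (ny, nx), relative concentration; row 0 = dorsal
    grid_spacing_um: float
    c_dorsal: float
    c_ventral: float
    dirichlet_ends: bool = True
    depth_um: float = 5.0
    molecules_per_um3: float = 10.0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=np.float64)
        if self.conc.ndim != 2:
            raise ValueError("conc must be 2D")
        if (self.conc < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def molecules_per_voxel_unit(self) -> float:
        """Molecules in one voxel at unit relative concentration."""
        return self.molecules_per_um3 * self.grid_spacing_um**2 * self.depth_um

    def total_molecules(self) -> float:
        return float(self.conc.sum() * self.molecules_per_voxel_unit)

    def copy(self) -> "T3Field":
        return T3Field(self.conc.copy(), self.grid_spacing_um, self.c_dorsal,
                       self.c_ventral, self.dirichlet_ends, self.depth_um,
                       self.molecules_per_um3)


def make_field(length_um: float, width_um: float, grid_spacing_um: float,
               c_dorsal: float, c_ventral: float, depth_um: float = 5.0,
               molecules_per_um3: float = 10.0, steady: bool = True) -> T3Field:
    """Field over the strip, initialized at the analytic steady gradient.

    The steady state of the 1D problem with pinned ends is the linear ramp
    c(y) = c_dorsal + (c_ventral - c_dorsal) * y / L, evaluated at voxel
    centers.
    """
    ny = max(int(round(length_um / grid_spacing_um)), 2)
    nx = max(int(round(width_um / grid_spacing_um)), 1)
    y = (np.arange(ny) + 0.5) * grid_spacing_um
    ramp = c_dorsal + (c_ventral - c_dorsal) * y / length_um
    conc = np.repeat(ramp[:, None], nx, axis=1) if steady else np.zeros((ny, nx))
    f = T3Field(conc, grid_spacing_um, c_dorsal, c_ventral, True, depth_um, molecules_per_um3)
    if steady:
        _pin_ends(f)
    return f


def _pin_ends(field: T3Field) -> None:
    field.conc[0, :] = field.c_dorsal
    field.conc[-1, :] = field.c_ventral


def step_field(field: T3Field, D: float, dt: float) -> T3Field:
    """One forward-Euler diffusion step (in place; returns the field).

    Refuses a time step violating the explicit stability bound
    dt <= h^2 / (4 D) of the 2D 5-point stencil. Side boundaries (and the
    ends too, when ``dirichlet_ends`` is off) are zero-flux via ghost-cell
    reflection; with reflection everywhere the scheme conserves total mass
    exactly.
    """
    h = field.grid_spacing_um
    if D < 0:
        raise ValueError("D must be >= 0")
    if D > 0 and dt > h * h / (4.0 * D):
        raise ValueError(f"dt={dt} violates the stability bound h^2/(4D)={h * h / (4 * D):g}")
    c = field.conc
    padded = np.pad(c, 1, mode="edge")  # reflecting ghost cells
    lap = (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * c
    ) / (h * h)
    c += D * dt * lap
    if field.dirichlet_ends:
        _pin_ends(field)
    np.clip(c, 0.0, None, out=c)
    return field


def exchange_T3(
    field: T3Field,
    t3_free: np.ndarray,
    voxel_of_cell: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    k_in: float,
    k_out: float,
) -> np.ndarray:
    """Stochastic molecule exchange between cells and their local voxels.

    Each cell takes up T3 at rate ``k_in * c_local`` (Poisson count over
    ``dt``) and releases each held molecule with probability
    ``1 - exp(-k_out dt)``. Net molecule changes are debited/credited to the
    voxels via the voxel volume; uptake is capped so no voxel is driven
    below zero (total molecules are conserved exactly).

    Modifies ``field.conc`` and returns the updated integer ``t3_free``.
    """
    mol_per_unit = field.molecules_per_voxel_unit
    flat = field.conc.ravel()
    c_local = flat[voxel_of_cell]

    # exact one-step transition of the linear uptake/release process: each
    # held molecule survives with prob e^(-k_out dt); arrivals are Poisson
    # with the integrated intensity, so the stationary mean is exactly
    # k_in c / k_out independent of the step size
    p_rel = -np.expm1(-k_out * dt)
    lam = k_in * c_local * (p_rel / k_out if k_out > 0 else dt)
    uptake = rng.poisson(np.maximum(lam, 0.0))
    release = rng.binomial(t3_free.astype(np.int64), p_rel)

    n_vox = flat.size
    up_sum = np.bincount(voxel_of_cell, weights=uptake, minlength=n_vox)
    rel_sum = np.bincount(voxel_of_cell, weights=release, minlength=n_vox)
    available = flat * mol_per_unit + rel_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(up_sum > available, available / np.maximum(up_sum, 1e-300), 1.0)
    if (factor < 1.0).any():
        uptake = np.floor(uptake * factor[voxel_of_cell]).astype(np.int64)
        up_sum = np.bincount(voxel_of_cell, weights=uptake, minlength=n_vox)

    flat += (rel_sum - up_sum) / mol_per_unit
    np.clip(flat, 0.0, None, out=flat)
    field.conc = flat.reshape(field.conc.shape)
    return t3_free + uptake.astype(np.int64) - release.astype(np.int64)
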