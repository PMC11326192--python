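"""Voxel density grids and bead-to-density rendering.

A :class:`DensityGrid` is a regular, isotropically spaced voxel volume in a
fixed laboratory frame, standing in for an electron-tomography map.  Bead
models are rendered into this frame as sums of isotropic Gaussians (one per
bead, sigma = bead radius, amplitude proportional to the bead's mass weight,
truncated at 3 sigma) and compared with target maps by Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structure import BeadModel

__all__ = ["DensityGrid", "simulate_density", "cross_correlation", "GeometryError"]

GAUSS_TRUNCATION_SIGMAS = 3.0


class GeometryError(ValueError):
    """Two grids do not share origin, spacing and dimensions."""


@dataclass(eq=False)
class DensityGrid:
    """Voxel volume: node ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``."""

    origin: np.ndarray
    spacing: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"density data must be 3-D, got shape {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.spacing = float(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def empty_like(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing, np.zeros(self.shape))

    def same_geometry(self, other: "DensityGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def allclose(self, other: "DensityGrid", atol: float = 1e-8) -> bool:
        return self.same_geometry(other, tol=atol) and bool(
            np.allclose(self.data, other.data, atol=atol)
        )


def add_bead_density(
    grid: DensityGrid,
    center: np.ndarray,
    radius: float,
    weight: float,
    sign: float = 1.0,
) -> None:
    """Accumulate (or with ``sign=-1`` remove) one bead's Gaussian in place.

    Evaluation is truncated at ``GAUSS_TRUNCATION_SIGMAS`` bead radii, so each
    update touches only a local block of voxels.
    """
    center = np.asarray(center, dtype=float)
    sigma = float(radius)
    cutoff = GAUSS_TRUNCATION_SIGMAS * sigma
    lo = np.maximum(np.ceil((center - cutoff - grid.origin) / grid.spacing), 0).astype(int)
    hi = np.minimum(
        np.floor((center + cutoff - grid.origin) / grid.spacing),
        np.asarray(grid.shape) - 1,
    ).astype(int)
    if np.any(hi < lo):
        return
    axes = [
        grid.origin[a] + grid.spacing * np.arange(lo[a], hi[a] + 1) - center[a]
        for a in range(3)
    ]
    r2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    block = weight * np.exp(-r2 / (2.0 * sigma * sigma))
    block[r2 > cutoff * cutoff] = 0.0
    grid.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += sign * block


def simulate_density(model: "BeadModel", template: DensityGrid) -> DensityGrid:
    """Render a bead model onto the template geometry.

    Linear in the bead set: each bead contributes an isotropic Gaussian of
    standard deviation equal to its radius and amplitude proportional to its
    mass weight.  An empty model yields the all-zero grid.
    """
    out = template.empty_like()
    for bead in model.beads:
        add_bead_density(out, bead.center, bead.radius, bead.weight)
    return out


def cross_correlation(
    model_density: DensityGrid,
    target: DensityGrid,
    floor: float | None = None,
) -> float:
    """Pearson correlation between two grids over (optionally floored) voxels.

    With ``floor`` set, only voxels where either grid exceeds it are compared.
    A constant grid has no defined correlation; 0.0 is returned with a warning.
    """
    if not model_density.same_geometry(target):
        raise GeometryError("density grids differ in origin, spacing or dimensions")
    a = model_density.data.ravel()
    b = target.data.ravel()
    if floor is not None:
        mask = (a > floor) | (b > floor)
        a, b = a[mask], b[mask]
    if a.size < 2 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn("constant grid in cross_correlation; returning 0.0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
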