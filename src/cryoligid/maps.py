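"""Density-map containers, MRC2014 I/O, grid geometry and map-derived masks.

The voxel grid is stored with a fixed internal axis convention: ``values[i, j, k]``
indexes the x, y, z axes in that order, world coordinates are in Angstroms, and
the center of voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * voxel_size``.
MRC files with permuted axis order (MAPC/MAPR/MAPS) are normalised on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DensityMap",
    "BinaryMask",
    "MapFormatError",
    "GeometryError",
    "DegenerateMapError",
    "read_mrc",
    "write_mrc",
    "soft_mask_from_map",
    "atom_mask",
]


class MapFormatError(ValueError):
    """The file is not a parseable MRC/CCP4 volume."""


class GeometryError(ValueError):
    """Grid geometry is invalid (non-positive voxel size, shape mismatch...)."""


class DegenerateMapError(ValueError):
    """The map has no dynamic range for the requested operation."""


@dataclass
class DensityMap:
    """A 3D scalar field on a regular orthogonal grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar map values in arbitrary map units.
    voxel_size : array-like of 3 floats
        Grid step along x, y, z in Angstroms; must be positive.
    origin : array-like of 3 floats
        World position (A) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if not np.all(self.voxel_size > 0):
            raise GeometryError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    # -- coordinate transforms -------------------------------------------------

    def world_to_voxel(self, point) -> np.ndarray:
        """Fractional grid index of a world-space point (voxel centers -> ints)."""
        return (np.asarray(point, dtype=np.float64) - self.origin) / self.voxel_size

    def voxel_to_world(self, index) -> np.ndarray:
        """World-space position of a (possibly fractional) grid index."""
        return self.origin + np.asarray(index, dtype=np.float64) * self.voxel_size

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of world coordinates of every voxel center, C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)

    def congruent(self, other: "DensityMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size, self.origin)


@dataclass
class BinaryMask:
    """Boolean selection of voxels, congruent with a parent :class:`DensityMap`."""

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if self.values.ndim != 3:
            raise GeometryError("mask must be a 3D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.values))

    def congruent(self, grid) -> bool:
        return (
            self.shape == grid.shape
            and np.allclose(self.voxel_size, grid.voxel_size)
            and np.allclose(self.origin, grid.origin)
        )

    def require_congruent(self, grid) -> None:
        if not self.congruent(grid):
            raise GeometryError("mask and map grids are not congruent")

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self.require_congruent(other)
        return BinaryMask(self.values & other.values, self.voxel_size, self.origin)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self.require_congruent(other)
        return BinaryMask(self.values | other.values, self.voxel_size, self.origin)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.values, self.voxel_size, self.origin)


# -- MRC2014 I/O ---------------------------------------------------------------


def read_mrc(path) -> DensityMap:
    """Read an MRC/CCP4 volume into the internal axis convention.

    Axis order is normalised so values[i, j, k] runs along x, y, z. The origin
    is taken from the ORIGIN header words when any is nonzero, else from
    NXSTART/NYSTART/NZSTART times the voxel size.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC map {path!r}: {exc}") from exc
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True, dtype=np.float64)
    cell = ccp4.grid.unit_cell
    nx, ny, nz = values.shape
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if not np.all(voxel > 0):
        raise GeometryError(f"non-positive voxel size in {path!r}: {voxel}")
    header_origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.any(header_origin != 0):
        origin = header_origin
    else:
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"map {path!r} contains non-finite values")
    return DensityMap(values, voxel, origin)


def write_mrc(density_map: DensityMap, path) -> None:
    """Write an MRC2014 file such that ``read_mrc`` restores values and geometry."""
    if not np.all(np.isfinite(density_map.values)):
        raise GeometryError("refusing to write a map with non-finite values")
    nx, ny, nz = density_map.shape
    vx, vy, vz = density_map.voxel_size
    grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.values, dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(word, float(value))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write MRC map to {path!r}: {exc}") from exc


# -- masks ---------------------------------------------------------------------


def soft_mask_from_map(
    density_map: DensityMap,
    sigma_fraction: float = 0.02,
    level_fraction: float = 0.05,
) -> BinaryMask:
    """Threshold a Gaussian-smoothed map at a fraction of its smoothed maximum.

    The smoothing kernel sigma is ``sigma_fraction`` times each axis's dimension
    in voxels (so anisotropic boxes get anisotropic kernels), and the mask keeps
    voxels of the filtered map above ``level_fraction`` times its maximum. The
    threshold is relative, so the mask is invariant under positive rescaling.
    """
    values = density_map.values
    if np.ptp(values) == 0:
        raise DegenerateMapError("map has zero dynamic range; cannot build soft mask")
    sigma = [sigma_fraction * dim for dim in density_map.shape]
    smoothed = ndimage.gaussian_filter(values, sigma=sigma)
    level = level_fraction * smoothed.max()
    return BinaryMask(smoothed > level, density_map.voxel_size, density_map.origin)


def atom_mask(density_map: DensityMap, model, radius: float) -> BinaryMask:
    """Voxels whose center lies within ``radius`` (A) of any atom of ``model``.

    ``model`` is a MolecularModel or anything with a ``coordinates`` (N, 3)
    array. Raises GeometryError if no atom produces any selected voxel and the
    radius is positive but every atom lies outside the grid extent.
    """
    coords = np.asarray(model.coordinates if hasattr(model, "coordinates") else model)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("model must provide a nonempty (N, 3) coordinate array")
    centers = density_map.voxel_centers()
    tree = cKDTree(coords)
    dist, _ = tree.query(centers, k=1)
    selected = (dist <= radius).reshape(density_map.shape)
    if not selected.any():
        lo = density_map.origin - density_map.voxel_size / 2
        hi = density_map.voxel_to_world(np.array(density_map.shape) - 0.5)
        inside = np.all((coords >= lo) & (coords <= hi), axis=1)
        if not inside.any():
            raise GeometryError("no atom of the model lies within the map extent")
    return BinaryMask(selected, density_map.voxel_size, density_map.origin)
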