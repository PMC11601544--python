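"""Gaussian-atom density simulation, masked real-space correlation, and the
correlation penalty for ligands riding on receptor background density.

The simulated density of a model is a sum of isotropic 3D Gaussians, one per
atom, with variance combining a resolution term and the atomic B-factor,

    sigma^2 = (resolution / pi)^2 / 2 + B / (8 pi^2),

and amplitude proportional to atomic number times occupancy. Correlations are
Pearson (mean-subtracted) over an explicit voxel mask. The ligand correlation
penalty compensates for background receptor density inflating the fit of
large ligands at low resolution: when adding the ligand to the model raises
the local map correlation by less than 0.15, the shortfall is penalised as

    penalty = 0                           if dlig_dens >= 0.15
    penalty = 0.15 - (2/3) * dlig_dens    otherwise (capped at 0.15)

where dlig_dens is the with-ligand minus without-ligand correlation computed
over the same ligand-neighborhood mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import BinaryMask, DegenerateMapError, DensityMap, atom_mask

__all__ = [
    "CorrelationResult",
    "PenaltyResult",
    "ELEMENT_WEIGHTS",
    "simulate_density",
    "masked_correlation",
    "pose_and_ligand_correlations",
    "delta_lig_dens",
    "density_penalty",
    "PENALTY_FREE_DELTA",
    "PENALTY_SLOPE",
    "POSE_MASK_RADIUS",
    "LIGAND_NEIGHBORHOOD_RADIUS",
]

#: dlig_dens at or above which no penalty applies
PENALTY_FREE_DELTA = 0.15
#: slope of the penalty below the penalty-free threshold
PENALTY_SLOPE = 2.0 / 3.0
#: mask radius (A) around model atoms for the pose/ligand correlations p and l
POSE_MASK_RADIUS = 3.0
#: radius (A) around ligand atoms of the shared mask used for dlig_dens
LIGAND_NEIGHBORHOOD_RADIUS = 5.0

#: per-element Gaussian amplitudes (atomic numbers); fallback is carbon
ELEMENT_WEIGHTS = {
    "H": 1, "D": 1, "T": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11,
    "MG": 12, "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25,
    "FE": 26, "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35,
    "I": 53,
}


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation restricted to a voxel mask."""

    value: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("a masked correlation needs at least 2 voxels")
        if abs(self.value) > 1 + 1e-9:
            raise ValueError(f"correlation out of range: {self.value}")


@dataclass(frozen=True)
class PenaltyResult:
    delta_lig_dens: float
    penalty: float


def _atom_sigma(resolution: float, b_factor: float) -> float:
    variance = (resolution / np.pi) ** 2 / 2.0 + max(b_factor, 0.0) / (8.0 * np.pi**2)
    return float(np.sqrt(variance))


def simulate_density(model, template: DensityMap, resolution: float) -> DensityMap:
    """Simulate model density on the template's grid at the given resolution (A).

    Linear in the model: density(A+B) = density(A) + density(B). Each atom's
    Gaussian is normalised to unit integral and scaled by its element weight
    times occupancy, then evaluated within a 4.5-sigma cutoff box.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    values = np.zeros(template.shape, dtype=np.float64)
    voxel = template.voxel_size
    shape = np.array(template.shape)
    axes_idx = [np.arange(n, dtype=np.float64) for n in shape]
    for atom in model.atoms:
        sigma = _atom_sigma(resolution, atom.b_factor)
        weight = ELEMENT_WEIGHTS.get(atom.element.upper(), 6) * atom.occupancy
        if weight == 0:
            continue
        amp = weight / (2.0 * np.pi * sigma**2) ** 1.5
        center = template.world_to_voxel(atom.position)
        half = 4.5 * sigma / voxel
        lo = np.maximum(np.ceil(center - half).astype(int), 0)
        hi = np.minimum(np.floor(center + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        # separable 1D Gaussian factors over the local box
        factors = [
            np.exp(-((axes_idx[d][lo[d]:hi[d]] - center[d]) * voxel[d]) ** 2
                   / (2.0 * sigma**2))
            for d in range(3)
        ]
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.einsum(
            "i,j,k->ijk", factors[0], factors[1], factors[2]
        )
    return DensityMap(values, template.voxel_size, template.origin)


def masked_correlation(
    map_a: DensityMap, map_b: DensityMap, mask: BinaryMask
) -> CorrelationResult:
    """Pearson correlation of two congruent maps over the masked voxels."""
    if not map_a.congruent(map_b):
        raise ValueError("maps are not congruent")
    mask.require_congruent(map_a)
    sel = mask.values
    n = int(np.count_nonzero(sel))
    if n < 2:
        raise DegenerateMapError(f"mask selects {n} voxels; need at least 2")
    a = map_a.values[sel]
    b = map_b.values[sel]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise DegenerateMapError("constant values within mask; correlation undefined")
    value = float(np.clip((a @ b) / denom, -1.0, 1.0))
    return CorrelationResult(value=value, n_voxels=n)


def pose_and_ligand_correlations(
    density_map: DensityMap,
    receptor,
    ligand,
    resolution: float,
    mask_radius: float = POSE_MASK_RADIUS,
) -> tuple[float, float]:
    """The Eq.-style features p and l.

    p: correlation of the experimental map with the simulated receptor+ligand
    density over a mask around all pose atoms. l: same for the ligand alone
    over a mask around the ligand atoms.
    """
    pose = receptor + ligand
    pose_sim = simulate_density(pose, density_map, resolution)
    pose_mask = atom_mask(density_map, pose, mask_radius)
    p = masked_correlation(density_map, pose_sim, pose_mask).value
    lig_sim = simulate_density(ligand, density_map, resolution)
    lig_mask = atom_mask(density_map, ligand, mask_radius)
    l = masked_correlation(density_map, lig_sim, lig_mask).value
    return p, l


def delta_lig_dens(
    density_map: DensityMap,
    receptor,
    ligand,
    resolution: float,
    neighborhood_radius: float = LIGAND_NEIGHBORHOOD_RADIUS,
) -> float:
    """Map-correlation gain from including the ligand in the model.

    Both correlations — receptor+ligand vs receptor-only simulated density
    against the experimental map — are evaluated over the same mask of voxels
    within ``neighborhood_radius`` of any ligand atom, so the difference
    isolates the ligand's own contribution.
    """
    mask = atom_mask(density_map, ligand, neighborhood_radius)
    with_lig = simulate_density(receptor + ligand, density_map, resolution)
    without_lig = simulate_density(receptor, density_map, resolution)
    corr_with = masked_correlation(density_map, with_lig, mask).value
    try:
        corr_without = masked_correlation(density_map, without_lig, mask).value
    except DegenerateMapError:
        # the receptor contributes no density in the ligand neighborhood; a
        # constant model density carries no signal, so it correlates at 0
        corr_without = 0.0
    return corr_with - corr_without


def density_penalty(delta: float) -> float:
    """Penalty subtracted from the ligand correlation for weak density support.

    Zero at or above a correlation gain of 0.15; below that it rises linearly
    with slope 2/3 and is capped at the 0.15 maximum (the cap only engages for
    negative gains, outside the formula's natural domain).
    """
    if not np.isfinite(delta):
        raise ValueError(f"delta_lig_dens must be finite, got {delta}")
    if delta >= PENALTY_FREE_DELTA:
        return 0.0
    return float(min(PENALTY_FREE_DELTA, PENALTY_FREE_DELTA - PENALTY_SLOPE * delta))


def penalty_result(delta: float) -> PenaltyResult:
    return PenaltyResult(delta_lig_dens=delta, penalty=density_penalty(delta))
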