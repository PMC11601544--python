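"""Detection of ligand-sized unmodeled density regions ("blobs").

The cascade: mask the receptor, take the mean and standard deviation of map
values inside the mask, convert every outside voxel to a Z-score on those
statistics, threshold at Z > 0.5, group the surviving voxels into
26-connected components, then keep only blobs that are plausibly an
unmodeled ligand — more than 70 voxels, more than 90% of their surface
voxels within 4 A of a receptor atom, and every voxel further than 5 A from
a chain break or terminus (density near a cut usually belongs to unmodeled
chain, not a ligand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .maps import BinaryMask, DegenerateMapError, DensityMap, atom_mask
from .models import MolecularModel, chain_breaks_and_termini
from .scoring import DEFAULT_CONSTANTS, ScoreRow, ScoringConstants, score_candidates

__all__ = [
    "BlobFinderParams",
    "Blob",
    "voxel_z_map",
    "grow_blobs",
    "blob_surface_contact",
    "filter_blobs",
    "find_blobs",
    "screen_blob",
    "blobs_to_frame",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class BlobFinderParams:
    voxel_z_threshold: float = 0.5       # strict >
    min_voxels: int = 70                 # strict >
    min_surface_contact_fraction: float = 0.90  # strict >
    contact_radius: float = 4.0          # A, surface voxel to receptor atom
    min_break_distance: float = 5.0      # A, blob voxel to break/terminus anchor
    receptor_mask_radius: float = 3.0    # A, mask for the voxel statistics

    def __post_init__(self) -> None:
        if min(self.voxel_z_threshold, self.contact_radius,
               self.min_break_distance, self.receptor_mask_radius) <= 0:
            raise ValueError("blob-finder thresholds must be positive")
        if not 0 < self.min_surface_contact_fraction <= 1:
            raise ValueError("surface-contact fraction must be in (0, 1]")


@dataclass
class Blob:
    """One connected above-threshold region with its filter statistics."""

    voxel_indices: np.ndarray            # (n, 3) integer grid indices
    centroid: np.ndarray                 # A, world coordinates
    mean_voxel_z: float
    surface_contact_fraction: float = np.nan
    min_break_distance: float = np.nan
    passes_filters: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


def voxel_z_map(density_map: DensityMap, receptor_mask: BinaryMask) -> DensityMap:
    """Z-score map of the voxels outside the receptor mask.

    Statistics (mean, SD) come from the in-mask voxels; outside voxels are
    standardised on them. In-mask voxels are marked excluded with a -inf
    sentinel so they can never exceed a peak threshold.
    """
    receptor_mask.require_congruent(density_map)
    inside = receptor_mask.values
    n_in = int(np.count_nonzero(inside))
    if n_in == 0:
        raise DegenerateMapError("receptor mask selects no voxels")
    if n_in == inside.size:
        raise DegenerateMapError("receptor mask covers the whole map")
    in_values = density_map.values[inside]
    mean = float(in_values.mean())
    sd = float(in_values.std(ddof=0))
    if sd == 0:
        raise DegenerateMapError("constant in-mask values; Z-scores undefined")
    z = (density_map.values - mean) / sd
    z[inside] = -np.inf  # excluded from peak detection
    out = DensityMap.__new__(DensityMap)  # bypass finite-value invariant for sentinel
    out.values = z
    out.voxel_size = density_map.voxel_size.copy()
    out.origin = density_map.origin.copy()
    return out


def grow_blobs(z_map: DensityMap, params: BlobFinderParams) -> list[Blob]:
    """26-connected components of voxels with Z above the peak threshold."""
    peaks = z_map.values > params.voxel_z_threshold
    labels, n_labels = ndimage.label(peaks, structure=_CONNECTIVITY_26)
    blobs = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        centroid = z_map.voxel_to_world(idx.mean(axis=0))
        mean_z = float(z_map.values[tuple(idx.T)].mean())
        blobs.append(Blob(voxel_indices=idx, centroid=centroid, mean_voxel_z=mean_z))
    return blobs


def _surface_voxels(blob: Blob, shape) -> np.ndarray:
    """Blob voxels with at least one 6-face neighbor outside the blob."""
    member = set(map(tuple, blob.voxel_indices))
    surface = []
    for vox in blob.voxel_indices:
        for step in _FACE_NEIGHBORS:
            nb = vox + step
            if tuple(nb) not in member or np.any(nb < 0) or np.any(nb >= shape):
                surface.append(vox)
                break
    return np.array(surface, dtype=int)


def blob_surface_contact(
    blob: Blob,
    receptor: MolecularModel,
    params: BlobFinderParams,
    grid: DensityMap,
) -> float:
    """Fraction of the blob's surface voxels within contact_radius of the receptor."""
    surface = _surface_voxels(blob, grid.shape)
    if len(surface) == 0:  # cannot happen on a finite grid, but be explicit
        return 0.0
    centers = grid.voxel_to_world(surface)
    coords = receptor.coordinates
    if len(coords) == 0:
        return 0.0
    dist, _ = cKDTree(coords).query(centers, k=1)
    return float(np.mean(dist <= params.contact_radius))


def filter_blobs(
    blobs: list[Blob],
    receptor: MolecularModel,
    params: BlobFinderParams,
    grid: DensityMap,
) -> list[Blob]:
    """Apply the volume / surface-contact / break-distance cascade.

    Fills each blob's statistics and ``passes_filters``; returns the list
    sorted by (n_voxels desc, surface_contact_fraction desc).
    """
    anchors = chain_breaks_and_termini(receptor)
    anchor_tree = cKDTree(anchors)
    for blob in blobs:
        blob.surface_contact_fraction = blob_surface_contact(
            blob, receptor, params, grid
        )
        centers = grid.voxel_to_world(blob.voxel_indices)
        dist, _ = anchor_tree.query(centers, k=1)
        blob.min_break_distance = float(dist.min())
        reasons = []
        if not blob.n_voxels > params.min_voxels:
            reasons.append("volume")
        if not blob.surface_contact_fraction > params.min_surface_contact_fraction:
            reasons.append("surface_contact")
        if not blob.min_break_distance > params.min_break_distance:
            reasons.append("break_distance")
        blob.rejection_reasons = reasons
        blob.passes_filters = not reasons
    blobs.sort(key=lambda b: (-b.n_voxels, -b.surface_contact_fraction))
    return blobs


def find_blobs(
    density_map: DensityMap,
    receptor: MolecularModel,
    params: BlobFinderParams = BlobFinderParams(),
) -> list[Blob]:
    """Full cascade: receptor mask -> Z map -> components -> filters."""
    mask = atom_mask(density_map, receptor, params.receptor_mask_radius)
    z_map = voxel_z_map(density_map, mask)
    blobs = grow_blobs(z_map, params)
    return filter_blobs(blobs, receptor, params, density_map)


def screen_blob(
    density_map: DensityMap,
    receptor: MolecularModel,
    blob: Blob,
    candidates,
    global_resolution: float,
    localres_map=None,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> tuple[list[ScoreRow], bool]:
    """Screen a candidate library against one passing blob.

    Each candidate pose is recentered on the blob centroid (its identity and
    geometry matter, its original placement does not) and scored with the
    standard ranking. The report flag is raised when the top identity's
    combined Z clears the blob reporting threshold — a blob whose best
    explanation still scores far below expectation is likely not a ligand.
    """
    if not candidates:
        raise ValueError("need at least one candidate to screen a blob")
    recentered = []
    for cand in candidates:
        pose_center = cand.pose.heavy().coordinates.mean(axis=0)
        shifted = cand.pose.translated(np.asarray(blob.centroid) - pose_center)
        recentered.append(
            type(cand)(
                identity=cand.identity, pose=shifted, delta_g=cand.delta_g
            )
        )
    rows = score_candidates(
        density_map, receptor, recentered, global_resolution,
        localres_map=localres_map, constants=constants,
    )
    ranked = [r for r in rows if r.status == "ok"]
    report_flag = bool(ranked) and ranked[0].z_combined > constants.blob_report_z
    return rows, report_flag


def blobs_to_frame(blobs: list[Blob]) -> pd.DataFrame:
    records = [
        {
            "n_voxels": b.n_voxels,
            "centroid_x": b.centroid[0],
            "centroid_y": b.centroid[1],
            "centroid_z": b.centroid[2],
            "mean_voxel_z": b.mean_voxel_z,
            "surface_contact_fraction": b.surface_contact_fraction,
            "min_break_distance": b.min_break_distance,
            "passes_filters": b.passes_filters,
            "rejection_reasons": ";".join(b.rejection_reasons),
        }
        for b in blobs
    ]
    return pd.DataFrame.from_records(records)
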