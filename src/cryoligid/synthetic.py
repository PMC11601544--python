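"""Deterministic synthetic scenarios for screening and blob detection.

Everything here is a pure function of its seed. The generator emulates the
study conditions the scoring layer is meant for: a small receptor of
point atoms traced as C-alpha-like chains, rigid point-cloud ligands whose
identities differ by heavy-atom count and geometry, Gaussian-atom simulated
maps with additive i.i.d. voxel noise, and planted above-threshold blobs for
the unassigned-density finder. Decoy candidates are engineered directly in
the quantities the scorer measures: their ΔG is displaced from its
size-expected value by a margin in units of |sigma_dg|, and their poses are
jittered until their measured ligand map correlation falls a target deficit
below the true identity's.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .density import POSE_MASK_RADIUS, masked_correlation, simulate_density
from .maps import BinaryMask, DensityMap, atom_mask
from .models import AtomRecord, LigandCandidate, MolecularModel
from .scoring import DEFAULT_CONSTANTS, expected_dg

__all__ = [
    "ScenarioSpec",
    "make_receptor",
    "make_ligand",
    "make_candidates",
    "make_screen_scenario",
    "make_blob_scenario",
]

_LIGAND_ELEMENTS = ("C", "C", "C", "N", "O")  # rough organic composition


@dataclass(frozen=True)
class ScenarioSpec:
    """Conditions of one synthetic identification screen."""

    seed: int
    voxel_size: float = 1.0          # A
    resolution: float = 3.0          # A, mid-range for ligand-bound cryoEM maps
    noise_sd: float = 0.1            # fraction of the peak simulated density
    n_decoys: int = 4
    decoy_l_deficit: float = 0.13    # ~3 sigma_dens: clearly resolvable identities
    dg_margin_sigma: float = 1.0     # ΔG separation, units of |sigma_dg|
    dg_noise_sigma: float = 0.1      # i.i.d. ΔG scatter, units of |sigma_dg|
    true_identity: str = "LIG"
    n_receptor_atoms: int = 60
    true_heavy_atoms: int = 20
    decoy_heavy_atoms: tuple[int, int] = (8, 30)
    grid_pad: float = 7.0            # A of margin around the models
    site_clearance: float = 14.0     # A, ligand site to nearest receptor atom

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _chain_walk(rng, n_atoms: int, start, radius: float = 13.0) -> np.ndarray:
    """Self-curling 3.8 A-step walk confined to a ball (keeps grids small)."""
    positions = [np.asarray(start, dtype=float)]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for _ in range(n_atoms - 1):
        direction = direction + 0.6 * rng.normal(size=3)
        pos = positions[-1]
        if np.linalg.norm(pos) > radius:  # steer back toward the origin
            direction = direction - 1.5 * pos / np.linalg.norm(pos)
        direction /= np.linalg.norm(direction)
        positions.append(pos + 3.8 * direction)
    return np.array(positions)


def make_receptor(
    seed: int,
    n_atoms: int = 60,
    n_chains: int = 2,
    numbering_gap: tuple[int, int] | None = None,
) -> MolecularModel:
    """Reproducible pseudo-protein: C-alpha traces in ``n_chains`` chains.

    One atom per residue, 3.8 A steps. ``numbering_gap=(after_residue,
    skipped)`` inserts a residue-numbering jump in the first chain, creating
    an internal chain break for the terminus/break detector.
    """
    if n_atoms < 10:
        raise ValueError("need at least 10 atoms for a pseudo-protein")
    rng = np.random.default_rng(seed)
    per_chain = [n_atoms // n_chains] * n_chains
    per_chain[0] += n_atoms - sum(per_chain)
    atoms: list[AtomRecord] = []
    for c, n_chain in enumerate(per_chain):
        chain_id = chr(ord("A") + c)
        start = rng.normal(scale=4.0, size=3)
        coords = _chain_walk(rng, n_chain, start)
        res = 1
        for i, pos in enumerate(coords):
            if (
                c == 0
                and numbering_gap is not None
                and i > 0
                and res == numbering_gap[0] + 1
            ):
                res += numbering_gap[1]
            atoms.append(
                AtomRecord(
                    element="C",
                    position=tuple(pos),
                    b_factor=20.0,
                    chain_id=chain_id,
                    residue_index=res,
                    residue_name="ALA",
                    atom_name="CA",
                )
            )
            res += 1
    return MolecularModel(atoms)


def make_ligand(
    rng,
    n_heavy: int,
    center=(0.0, 0.0, 0.0),
    identity: str = "LIG",
    min_spacing: float = 1.4,
) -> MolecularModel:
    """Compact rigid point cloud of ``n_heavy`` organic atoms around ``center``."""
    center = np.asarray(center, dtype=float)
    radius = 1.2 * max(n_heavy, 2) ** (1.0 / 3.0) + 1.0
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_heavy:
        attempts += 1
        if attempts > 20000:
            min_spacing *= 0.9  # relax if the sphere packs too tightly
            attempts = 0
        trial = rng.normal(scale=radius / 2.0, size=3)
        if np.linalg.norm(trial) > radius:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - trial, axis=1)) < min_spacing:
            continue
        placed.append(trial)
    atoms = [
        AtomRecord(
            element=_LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)],
            position=tuple(center + pos),
            b_factor=20.0,
            chain_id="X",
            residue_index=1,
            residue_name=identity[:3].upper() or "LIG",
            atom_name=f"{_LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)]}{i + 1}",
            is_hetero=True,
        )
        for i, pos in enumerate(placed)
    ]
    return MolecularModel(atoms)


def _assign_dg(rng, a: int, margin_sigma: float, noise_sigma: float, favorable: bool) -> float:
    """ΔG displaced half the margin off its size expectation, plus scatter."""
    sigma_abs = abs(DEFAULT_CONSTANTS.sigma_dg)
    sign = -1.0 if favorable else 1.0
    return (
        expected_dg(a)
        + sign * (margin_sigma / 2.0) * sigma_abs
        + rng.normal(scale=noise_sigma * sigma_abs)
    )


def make_candidates(
    seed: int,
    n_decoys: int,
    a_range: tuple[int, int] = (8, 30),
    true_heavy_atoms: int = 20,
    dg_margin_sigma: float = 1.0,
    dg_noise_sigma: float = 0.1,
    true_identity: str = "LIG",
    center=(0.0, 0.0, 0.0),
) -> list[LigandCandidate]:
    """One true identity plus decoys with margin-separated ΔG assignments.

    ``dg_margin_sigma = m`` places the true ΔG m/2 |sigma_dg| below and each
    decoy m/2 above its own size expectation, so z_dg(true) - z_dg(decoy)
    averages m. At m = 0 all candidates are statistically exchangeable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    true_pose = make_ligand(rng, true_heavy_atoms, center, identity=true_identity)
    candidates = [
        LigandCandidate(
            identity=true_identity,
            pose=true_pose,
            delta_g=_assign_dg(rng, true_heavy_atoms, dg_margin_sigma,
                               dg_noise_sigma, favorable=True),
        )
    ]
    for d in range(n_decoys):
        a = int(rng.integers(a_range[0], a_range[1] + 1))
        pose = make_ligand(rng, a, center, identity=f"DC{d + 1}")
        candidates.append(
            LigandCandidate(
                identity=f"DC{d + 1}",
                pose=pose,
                delta_g=_assign_dg(rng, a, dg_margin_sigma, dg_noise_sigma,
                                   favorable=False),
            )
        )
    return candidates


def _grid_for(models, voxel_size: float, pad: float) -> DensityMap:
    coords = np.vstack([m.coordinates for m in models])
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    return DensityMap(np.zeros(shape), np.full(3, voxel_size), origin=lo)


def _ligand_correlation(density_map, pose, resolution) -> float:
    sim = simulate_density(pose, density_map, resolution)
    mask = atom_mask(density_map, pose, POSE_MASK_RADIUS)
    return masked_correlation(density_map, sim, mask).value


def _resize_pose(rng, pose: MolecularModel, n_heavy: int) -> MolecularModel:
    """Copy of ``pose`` with its atom count adjusted to ``n_heavy``.

    Fewer atoms: a random subset. More atoms: extra atoms duplicated from
    random existing ones with a small offset. Starting decoys from the true
    pose puts their baseline correlation at the true identity's, so the
    jitter calibration can dial in the requested deficit.
    """
    atoms = list(pose.atoms)
    if n_heavy < len(atoms):
        keep = sorted(rng.choice(len(atoms), size=n_heavy, replace=False))
        atoms = [atoms[i] for i in keep]
    else:
        for i in range(n_heavy - len(atoms)):
            src = atoms[int(rng.integers(len(atoms)))]
            offset = rng.normal(scale=0.7, size=3)
            atoms.append(
                AtomRecord(**{**vars(src),
                              "position": tuple(np.asarray(src.position) + offset),
                              "atom_name": f"Q{i + 1}"})
            )
    return MolecularModel(atoms)


def _calibrate_decoy_pose(
    density_map, base_pose: MolecularModel, rng, target_l: float, resolution: float,
    tol: float = 0.015, max_jitter: float = 8.0,
) -> MolecularModel:
    """Jitter the pose until its measured ligand correlation hits ``target_l``.

    Coordinates move along fixed random unit displacements scaled by a common
    amplitude; the amplitude is bisected against the actually measured
    correlation, which decreases (monotonically in practice) with amplitude.
    """
    directions = rng.normal(size=(len(base_pose), 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    base = base_pose.coordinates

    def pose_at(amplitude: float) -> MolecularModel:
        shifted = base + amplitude * directions
        return MolecularModel(
            [
                AtomRecord(**{**vars(a), "position": tuple(q)})
                for a, q in zip(base_pose.atoms, shifted)
            ]
        )

    lo, hi = 0.0, max_jitter
    best_pose, best_err = base_pose, abs(_ligand_correlation(density_map, base_pose, resolution) - target_l)
    for _ in range(12):
        mid = (lo + hi) / 2.0
        candidate = pose_at(mid)
        l_mid = _ligand_correlation(density_map, candidate, resolution)
        err = abs(l_mid - target_l)
        if err < best_err:
            best_pose, best_err = candidate, err
        if err <= tol:
            break
        if l_mid > target_l:
            lo = mid
        else:
            hi = mid
    return best_pose


def make_screen_scenario(spec: ScenarioSpec):
    """Full identification screen: map, receptor, candidate library, truth.

    The map is the simulated density of receptor plus the true identity's
    pose, with additive Gaussian voxel noise of ``noise_sd`` times the peak.
    Decoy poses start from the true pose (resized to their heavy-atom count)
    and are jittered until their ligand correlation sits ~``decoy_l_deficit``
    below the true identity's. Returns ``(map, receptor, candidates,
    ground_truth)`` with ground_truth = {"identity", "pocket_center",
    "l_true"}.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    receptor = make_receptor(spec.seed, spec.n_receptor_atoms)
    # ligand site: offset outward from the receptor until the ligand region
    # (pose radius + correlation mask) is clear of receptor density, so the
    # ligand-only correlation is exactly 1 on a noiseless map
    coords = receptor.coordinates
    mid = coords[len(coords) // 2]
    outward = mid - coords.mean(axis=0)
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    tree = cKDTree(coords)
    offset = 4.5
    while tree.query(mid + offset * outward)[0] < spec.site_clearance:
        offset += 0.5
        if offset > 60.0:
            raise RuntimeError("could not place a clear ligand site")
    pocket = mid + offset * outward

    candidates = make_candidates(
        spec.seed,
        spec.n_decoys,
        a_range=spec.decoy_heavy_atoms,
        true_heavy_atoms=spec.true_heavy_atoms,
        dg_margin_sigma=spec.dg_margin_sigma,
        dg_noise_sigma=spec.dg_noise_sigma,
        true_identity=spec.true_identity,
        center=pocket,
    )
    true_pose = candidates[0].pose

    template = _grid_for([receptor, true_pose], spec.voxel_size, spec.grid_pad)
    clean = simulate_density(receptor + true_pose, template, spec.resolution)
    noise = rng.normal(scale=spec.noise_sd * clean.values.max(),
                       size=clean.shape) if spec.noise_sd > 0 else 0.0
    density_map = DensityMap(clean.values + noise, template.voxel_size,
                             template.origin)

    l_true = _ligand_correlation(density_map, true_pose, spec.resolution)
    if spec.decoy_l_deficit > 0:
        target = l_true - spec.decoy_l_deficit
        for cand in candidates[1:]:
            base = _resize_pose(rng, true_pose, cand.a)
            cand.pose = _calibrate_decoy_pose(
                density_map, base, rng, target, spec.resolution
            )
    else:
        # null construction: identical poses, identities differ only in label/ΔG
        for cand in candidates[1:]:
            cand.pose = MolecularModel(list(true_pose.atoms))

    ground_truth = {
        "identity": spec.true_identity,
        "pocket_center": pocket,
        "l_true": l_true,
    }
    return density_map, receptor, candidates, ground_truth


def _compact_region(allowed: np.ndarray, seed_index: tuple[int, int, int],
                    n_voxels: int) -> np.ndarray:
    """Grow a 26-connected, near-spherical region of n_voxels inside ``allowed``."""
    allowed_set = set(map(tuple, np.argwhere(allowed)))
    if seed_index not in allowed_set:
        raise ValueError("seed voxel is not in the allowed region")
    seed_arr = np.asarray(seed_index, dtype=float)
    heap = [(0.0, seed_index)]
    chosen: list[tuple[int, int, int]] = []
    visited = {seed_index}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while heap and len(chosen) < n_voxels:
        _, vox = heapq.heappop(heap)
        chosen.append(vox)
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if nb in allowed_set and nb not in visited:
                visited.add(nb)
                heapq.heappush(heap, (float(np.linalg.norm(np.asarray(nb) - seed_arr)), nb))
    if len(chosen) < n_voxels:
        raise ValueError(
            f"allowed region supports only {len(chosen)} of {n_voxels} voxels"
        )
    return np.array(chosen, dtype=int)


def make_blob_scenario(
    seed: int,
    blob_voxels: int,
    attached: bool = True,
    near_terminus: bool = False,
    n_receptor_atoms: int = 60,
    voxel_size: float = 1.0,
    resolution: float = 3.0,
    noise_sd: float = 0.0,
    planted_z: float = 3.0,
    mask_radius: float = 3.0,
    contact_radius: float = 4.0,
    break_clearance: float = 6.5,
):
    """Receptor map with one planted above-threshold region of known size.

    The planted voxels sit outside the receptor mask; ``attached`` confines
    them to the shell within ``contact_radius`` of receptor atoms (full
    surface contact), otherwise to free space beyond it (zero contact).
    ``near_terminus`` seeds the region within 5 A of a chain-terminus anchor;
    otherwise every planted voxel keeps > ``break_clearance`` A from all
    anchors. Planted values are in-mask mean + ``planted_z`` in-mask SDs.
    Returns ``(map, receptor, truth)`` with truth = {"indices", "n_voxels",
    "centroid"}.
    """
    from .models import chain_breaks_and_termini  # local import avoids cycle

    if blob_voxels < 1:
        raise ValueError("blob_voxels must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 33]))
    receptor = make_receptor(seed, n_receptor_atoms)
    template = _grid_for([receptor], voxel_size, pad=9.0)
    clean = simulate_density(receptor, template, resolution)

    mask = atom_mask(template, receptor, mask_radius)
    centers = template.voxel_centers()
    atom_tree = cKDTree(receptor.coordinates)
    dist_atoms, _ = atom_tree.query(centers, k=1)
    dist_atoms = dist_atoms.reshape(template.shape)
    anchors = chain_breaks_and_termini(receptor)
    dist_anchor, _ = cKDTree(anchors).query(centers, k=1)
    dist_anchor = dist_anchor.reshape(template.shape)

    outside = ~mask.values
    if attached:
        allowed = outside & (dist_atoms > mask_radius + 0.15) & (
            dist_atoms <= contact_radius - 0.1
        )
    else:
        allowed = outside & (dist_atoms > contact_radius + 1.0)
        # keep detached blobs inside the grid interior
        interior = np.zeros(template.shape, dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        allowed &= interior
    if near_terminus:
        seed_pool = allowed & (dist_anchor <= 4.5)
    else:
        allowed &= dist_anchor > break_clearance
        seed_pool = allowed
    pool_idx = np.argwhere(seed_pool)
    if len(pool_idx) == 0:
        raise ValueError("no voxel satisfies the placement constraints")
    seed_vox = tuple(pool_idx[rng.integers(len(pool_idx))])
    indices = _compact_region(allowed, seed_vox, blob_voxels)

    in_values = clean.values[mask.values]
    mean, sd = float(in_values.mean()), float(in_values.std(ddof=0))
    values = clean.values.copy()
    values[tuple(indices.T)] = mean + planted_z * sd
    if noise_sd > 0:
        values = values + rng.normal(scale=noise_sd * clean.values.max(),
                                     size=values.shape)
    density_map = DensityMap(values, template.voxel_size, template.origin)
    truth = {
        "indices": indices,
        "n_voxels": blob_voxels,
        "centroid": template.voxel_to_world(indices.mean(axis=0)),
    }
    return density_map, receptor, truth
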