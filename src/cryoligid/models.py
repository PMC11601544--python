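"""Coordinate-model I/O and the structural quantities scoring needs.

Receptor and ligand models are flat, ordered atom lists with chain
segmentation — no chemistry (bonds, protonation) is perceived. PDB and mmCIF
files are parsed with gemmi; both formats yield identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "MolecularModel",
    "LigandCandidate",
    "EmptyModelError",
    "NotAPolymerError",
    "read_model",
    "write_pdb",
    "read_candidate_table",
    "heavy_atom_count",
    "chain_breaks_and_termini",
    "center_of_mass",
]

#: elements counted as hydrogen for heavy-atom purposes
_HYDROGEN = {"H", "D", "T"}

#: backbone atom names used as break/terminus anchors, in preference order
_BACKBONE = ("CA", "C", "N", "P", "C1'")

#: maximum peptide-bond C->N distance before a chain counts as broken (A)
PEPTIDE_BREAK_DISTANCE = 2.0


class EmptyModelError(ValueError):
    """The file or selection yields no atoms."""


class NotAPolymerError(ValueError):
    """The model has no backbone atoms to anchor termini and breaks."""


@dataclass(frozen=True)
class AtomRecord:
    element: str
    position: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    chain_id: str = "A"
    residue_index: int = 1
    residue_name: str = "UNK"
    atom_name: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclass
class MolecularModel:
    """Ordered atom list; chains are the partition of atoms by chain_id."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError("a MolecularModel needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def __add__(self, other: "MolecularModel") -> "MolecularModel":
        return MolecularModel(self.atoms + other.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.chain_id, []).append(atom)
        return out

    def select(self, predicate) -> "MolecularModel":
        kept = [a for a in self.atoms if predicate(a)]
        if not kept:
            raise EmptyModelError("selection yields no atoms")
        return MolecularModel(kept)

    def heavy(self) -> "MolecularModel":
        return self.select(lambda a: not a.is_hydrogen)

    def translated(self, shift) -> "MolecularModel":
        shift = np.asarray(shift, dtype=np.float64)
        return MolecularModel(
            [replace(a, position=tuple(np.asarray(a.position) + shift)) for a in self.atoms]
        )


@dataclass
class LigandCandidate:
    """One library identity: a label, a docked pose, and its estimated ΔG.

    ``delta_g`` is the externally computed binding-affinity estimate in
    Rosetta-style energy units (more negative = more favorable). The
    heavy-atom count ``a`` is derived from the pose.
    """

    identity: str
    pose: MolecularModel
    delta_g: float
    source_path: str | None = None

    @property
    def a(self) -> int:
        return heavy_atom_count(self.pose)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_g):
            raise ValueError(f"non-finite delta_g for candidate {self.identity!r}")
        if self.a < 1:
            raise ValueError(f"candidate {self.identity!r} has no heavy atoms")


# -- I/O -----------------------------------------------------------------------


def read_model(path, strip_hetero: bool = False) -> MolecularModel:
    """Parse a PDB or mmCIF file into a MolecularModel (first model only).

    With ``strip_hetero`` all HETATM records (waters, ligands, ions) are
    dropped, producing a receptor-only model. Unknown elements are inferred
    from the atom name by gemmi's PDB reader.
    """
    structure = gemmi.read_structure(str(path))
    atoms: list[AtomRecord] = []
    for chain in structure[0]:
        for residue in chain:
            hetero = residue.het_flag == "H"
            if strip_hetero and hetero:
                continue
            for atom in residue:
                element = atom.element.name if atom.element.name else "C"
                atoms.append(
                    AtomRecord(
                        element=element,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        b_factor=atom.b_iso,
                        occupancy=atom.occ,
                        chain_id=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        is_hetero=hetero,
                    )
                )
    if not atoms:
        raise EmptyModelError(f"no atoms read from {path!r} (strip_hetero={strip_hetero})")
    return MolecularModel(atoms)


def write_pdb(model: MolecularModel, path) -> None:
    """Write the model as fixed-column PDB (coordinates at PDB's 1e-3 A precision)."""
    structure = gemmi.Structure()
    structure.name = "model"
    gmodel = gemmi.Model("1")
    for chain_id, records in model.chains.items():
        chain = gemmi.Chain(chain_id)
        # group into residues first: gemmi's add_residue stores a copy
        grouped: list[list[AtomRecord]] = []
        for rec in records:
            if (
                grouped
                and grouped[-1][0].residue_index == rec.residue_index
                and grouped[-1][0].residue_name == rec.residue_name
            ):
                grouped[-1].append(rec)
            else:
                grouped.append([rec])
        for recs in grouped:
            residue = gemmi.Residue()
            residue.name = recs[0].residue_name
            residue.seqid = gemmi.SeqId(recs[0].residue_index, " ")
            residue.het_flag = "H" if recs[0].is_hetero else "A"
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.atom_name or rec.element
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.position)
                atom.b_iso = rec.b_factor
                atom.occ = rec.occupancy
                residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_candidate_table(path, base_dir=None) -> list[LigandCandidate]:
    """Read a candidate table (TSV/CSV: identity, pose_path, delta_g).

    Relative pose paths resolve against ``base_dir`` (default: the table's
    directory).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep)
    required = {"identity", "pose_path", "delta_g"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"candidate table {path} lacks columns: {sorted(missing)}")
    if table.empty:
        raise EmptyModelError(f"candidate table {path} has no rows")
    base = Path(base_dir) if base_dir is not None else path.parent
    candidates = []
    for row in table.itertuples(index=False):
        pose_path = Path(row.pose_path)
        if not pose_path.is_absolute():
            pose_path = base / pose_path
        candidates.append(
            LigandCandidate(
                identity=str(row.identity),
                pose=read_model(pose_path),
                delta_g=float(row.delta_g),
                source_path=str(pose_path),
            )
        )
    return candidates


# -- derived structural quantities --------------------------------------------


def heavy_atom_count(model: MolecularModel) -> int:
    """Number of non-hydrogen atoms (D and T count as hydrogen)."""
    return sum(1 for a in model.atoms if not a.is_hydrogen)


def center_of_mass(model: MolecularModel, heavy_only: bool = True) -> np.ndarray:
    """Unweighted centroid of the (optionally heavy-only) atom positions, in A."""
    selected = model.heavy() if heavy_only else model
    return selected.coordinates.mean(axis=0)


def _backbone_anchor(records: list[AtomRecord]) -> AtomRecord | None:
    for name in _BACKBONE:
        for rec in records:
            if rec.atom_name == name:
                return rec
    return None


def chain_breaks_and_termini(
    model: MolecularModel,
    max_peptide_bond: float = PEPTIDE_BREAK_DISTANCE,
) -> np.ndarray:
    """Backbone-anchor positions of every chain terminus and internal break.

    Each chain contributes its first and last residue; consecutive residues
    additionally contribute both flanking residues of an internal break, where
    a break is a non-consecutive residue numbering step or a peptide C->N
    distance above ``max_peptide_bond`` (A). Returns an (N, 3) array of unique
    anchor positions.
    """
    anchors: list[np.ndarray] = []
    found_backbone = False
    for records in model.chains.values():
        # group atoms into residues, preserving order
        residues: list[tuple[int, list[AtomRecord]]] = []
        for rec in records:
            if rec.is_hetero:
                continue
            if residues and residues[-1][0] == rec.residue_index:
                residues[-1][1].append(rec)
            else:
                residues.append((rec.residue_index, [rec]))
        res_anchors = [(idx, _backbone_anchor(recs)) for idx, recs in residues]
        res_anchors = [(idx, a) for idx, a in res_anchors if a is not None]
        if not res_anchors:
            continue
        found_backbone = True
        anchors.append(np.asarray(res_anchors[0][1].position))
        anchors.append(np.asarray(res_anchors[-1][1].position))
        for (idx_a, recs_a), (idx_b, recs_b) in zip(residues, residues[1:]):
            broken = idx_b != idx_a + 1
            if not broken:
                carbonyl = next((r for r in recs_a if r.atom_name == "C"), None)
                amide = next((r for r in recs_b if r.atom_name == "N"), None)
                if carbonyl is not None and amide is not None:
                    gap = np.linalg.norm(
                        np.asarray(carbonyl.position) - np.asarray(amide.position)
                    )
                    broken = gap > max_peptide_bond
            if broken:
                for recs in (recs_a, recs_b):
                    anchor = _backbone_anchor(recs)
                    if anchor is not None:
                        anchors.append(np.asarray(anchor.position))
    if not found_backbone:
        raise NotAPolymerError("model has no polymer backbone atoms")
    return np.unique(np.array(anchors, dtype=np.float64), axis=0)
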