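"""Model/Results interface over the scoring and blob-detection pipelines.

`LigandScreen` is built from the data of one identification problem — a
density map, a receptor model, a candidate library and a resolution — and
its `fit()` runs the full scoring pipeline, returning a `ScreenResults`
carrying the ranked per-identity table, probabilities, flags and a
`summary()`. `UnassignedDensityFinder` plays the same role for the blob
cascade.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .blobs import (
    Blob,
    BlobFinderParams,
    blobs_to_frame,
    find_blobs,
    screen_blob,
)
from .maps import DensityMap, read_mrc
from .models import MolecularModel, read_candidate_table, read_model
from .scoring import (
    DEFAULT_CONSTANTS,
    ScoreRow,
    ScoringConstants,
    rows_to_frame,
    score_candidates,
)

__all__ = ["LigandScreen", "ScreenResults", "UnassignedDensityFinder", "BlobResults"]

REPORT_SCHEMA_VERSION = 1


def _json_ready(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


class LigandScreen:
    """A ligand-identification problem: which library identity is in the map?

    Parameters
    ----------
    density_map : DensityMap
        The experimental (or simulated) map.
    receptor : MolecularModel
        The fitted receptor, without the ligand under investigation.
    candidates : list of LigandCandidate
        Library identities with docked poses and estimated binding
        affinities (ΔG, more negative = more favorable).
    global_resolution : float
        Map global resolution in A.
    localres_map : DensityMap, optional
        Per-voxel local-resolution map; when given, the pocket-local average
        is used as the resolution feature unless distrusted.
    constants : ScoringConstants, optional
        Override block for all empirical scoring constants.
    """

    def __init__(
        self,
        density_map: DensityMap,
        receptor: MolecularModel,
        candidates,
        global_resolution: float,
        localres_map: DensityMap | None = None,
        constants: ScoringConstants = DEFAULT_CONSTANTS,
    ) -> None:
        if global_resolution <= 0:
            raise ValueError("global_resolution must be positive")
        if not candidates:
            raise ValueError("need at least one candidate")
        self.density_map = density_map
        self.receptor = receptor
        self.candidates = list(candidates)
        self.global_resolution = float(global_resolution)
        self.localres_map = localres_map
        self.constants = constants

    @classmethod
    def from_files(
        cls,
        map_path,
        receptor_path,
        candidates_path,
        global_resolution: float,
        localres_map_path=None,
        constants: ScoringConstants = DEFAULT_CONSTANTS,
    ) -> "LigandScreen":
        """Build a screen from MRC / PDB-mmCIF / candidate-table paths."""
        return cls(
            density_map=read_mrc(map_path),
            receptor=read_model(receptor_path, strip_hetero=True),
            candidates=read_candidate_table(candidates_path),
            global_resolution=global_resolution,
            localres_map=read_mrc(localres_map_path) if localres_map_path else None,
            constants=constants,
        )

    def fit(self) -> "ScreenResults":
        rows = score_candidates(
            self.density_map,
            self.receptor,
            self.candidates,
            self.global_resolution,
            localres_map=self.localres_map,
            constants=self.constants,
        )
        return ScreenResults(self, rows)


class ScreenResults:
    """Ranked identification results with probabilities and quality flags."""

    def __init__(self, model: LigandScreen, rows: list[ScoreRow]) -> None:
        self.model = model
        self.rows = rows

    @property
    def table(self) -> pd.DataFrame:
        return rows_to_frame(self.rows)

    @property
    def ranked(self) -> list[ScoreRow]:
        return [r for r in self.rows if r.status == "ok"]

    @property
    def top(self) -> ScoreRow:
        ranked = self.ranked
        if not ranked:
            raise ValueError("no candidate was scored successfully")
        return ranked[0]

    @property
    def probabilities(self) -> dict[str, float]:
        return {r.identity: r.probability for r in self.ranked}

    def summary(self) -> str:
        lines = [
            "Ligand identification screen",
            "============================",
            f"candidates: {len(self.rows)}  "
            f"scored: {len(self.ranked)}  "
            f"resolution: {self.model.global_resolution:.2f} A",
        ]
        if self.ranked:
            top = self.top
            lines += [
                f"top identity: {top.identity}  "
                f"probability: {top.probability:.3f}  "
                f"combined Z: {top.z_combined:+.2f}",
                f"flags: {', '.join(sorted(top.flags)) or 'none'}",
                "",
                f"{'rank':>4} {'identity':<10} {'prob':>7} {'Zcomb':>7} "
                f"{'Zdens':>7} {'ZdG':>7} {'l_corr':>7} {'penalty':>7}",
            ]
            for r in self.ranked:
                lines.append(
                    f"{r.rank:>4} {r.identity:<10} {r.probability:>7.3f} "
                    f"{r.z_combined:>+7.2f} {r.z_dens:>+7.2f} {r.z_dg:>+7.2f} "
                    f"{r.l_corrected:>7.3f} {r.penalty:>7.3f}"
                )
        failed = [r for r in self.rows if r.status != "ok"]
        for r in failed:
            lines.append(f"  FAILED {r.identity}: {r.status_detail}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "constants": asdict(self.model.constants),
            "global_resolution": self.model.global_resolution,
            "rows": [
                {**{k: v for k, v in vars(r).items() if k != "flags"},
                 "flags": sorted(r.flags)}
                for r in self.rows
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_ready)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


class UnassignedDensityFinder:
    """Detect ligand-sized unmodeled density given a map and fitted receptor."""

    def __init__(
        self,
        density_map: DensityMap,
        receptor: MolecularModel,
        params: BlobFinderParams = BlobFinderParams(),
    ) -> None:
        self.density_map = density_map
        self.receptor = receptor
        self.params = params

    @classmethod
    def from_files(cls, map_path, receptor_path,
                   params: BlobFinderParams = BlobFinderParams()):
        return cls(read_mrc(map_path), read_model(receptor_path, strip_hetero=True),
                   params)

    def fit(self) -> "BlobResults":
        blobs = find_blobs(self.density_map, self.receptor, self.params)
        return BlobResults(self, blobs)


class BlobResults:
    """Detected blobs with per-filter statistics."""

    def __init__(self, model: UnassignedDensityFinder, blobs: list[Blob]) -> None:
        self.model = model
        self.blobs = blobs

    @property
    def passing(self) -> list[Blob]:
        return [b for b in self.blobs if b.passes_filters]

    @property
    def table(self) -> pd.DataFrame:
        return blobs_to_frame(self.blobs)

    def summary(self) -> str:
        lines = [
            "Unassigned-density search",
            "=========================",
            f"blobs above threshold: {len(self.blobs)}  passing: {len(self.passing)}",
        ]
        for b in self.blobs:
            verdict = "PASS" if b.passes_filters else (
                "reject: " + ",".join(b.rejection_reasons)
            )
            lines.append(
                f"  {b.n_voxels:>5} voxels  contact {b.surface_contact_fraction:.2f}  "
                f"break dist {b.min_break_distance:.1f} A  {verdict}"
            )
        return "\n".join(lines)

    def screen(self, blob: Blob, candidates, global_resolution: float, **kwargs):
        """Score a candidate library against one blob (poses recentered on it)."""
        return screen_blob(
            self.model.density_map, self.model.receptor, blob, candidates,
            global_resolution, **kwargs,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "params": asdict(self.model.params),
            "blobs": [
                {
                    "n_voxels": b.n_voxels,
                    "centroid": list(b.centroid),
                    "mean_voxel_z": b.mean_voxel_z,
                    "surface_contact_fraction": b.surface_contact_fraction,
                    "min_break_distance": b.min_break_distance,
                    "passes_filters": b.passes_filters,
                    "rejection_reasons": b.rejection_reasons,
                }
                for b in self.blobs
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_ready)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text
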