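"""Resolution and pose-correlation features feeding the expected-density model.

The local resolution r is the mean of the strictly positive voxels of a
local-resolution map (e.g. from MonoRes) within 5 A of the ligand's center of
mass; zero voxels are unestimated and excluded. Implausibly good local
averages — more than 1 A better (numerically smaller) than the global
resolution — are distrusted and replaced by the global value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .maps import DensityMap

__all__ = [
    "ResolutionSource",
    "MapFeatures",
    "NoLocalSignal",
    "local_resolution_at",
    "resolve_resolution",
]

#: averaging radius (A) around the ligand center of mass
LOCAL_RESOLUTION_RADIUS = 5.0
#: a local average this much better (smaller, A) than global triggers fallback
LOCAL_TRUST_MARGIN = 1.0


class ResolutionSource(str, Enum):
    LOCAL_AVERAGE = "local_average"
    GLOBAL_FALLBACK = "global_fallback"


class NoLocalSignal(Exception):
    """No positive local-resolution voxel within the averaging radius."""


@dataclass(frozen=True)
class MapFeatures:
    """The (r, p) feature pair of the expected-density model."""

    r: float
    p: float
    global_resolution: float
    r_source: ResolutionSource

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"resolution must be positive, got {self.r}")
        if abs(self.p) > 1 + 1e-9:
            raise ValueError(f"pose correlation out of range: {self.p}")


def local_resolution_at(
    localres_map: DensityMap,
    center,
    radius: float = LOCAL_RESOLUTION_RADIUS,
) -> float:
    """Mean positive local-resolution value within ``radius`` A of ``center``.

    Raises :class:`NoLocalSignal` when no strictly positive voxel falls inside
    the sphere (the caller should fall back to the global resolution).
    """
    center = np.asarray(center, dtype=np.float64)
    centers = localres_map.voxel_centers()
    within = np.linalg.norm(centers - center, axis=1) <= radius
    values = localres_map.values.reshape(-1)[within]
    values = values[values > 0]
    if values.size == 0:
        raise NoLocalSignal(
            f"no positive local-resolution voxel within {radius} A of {center}"
        )
    return float(values.mean())


def resolve_resolution(
    local_average: float | None,
    global_resolution: float,
    trust_margin: float = LOCAL_TRUST_MARGIN,
    distrust_both_directions: bool = False,
) -> tuple[float, ResolutionSource]:
    """Choose between the pocket-local average and the global resolution.

    Returns the global value when the local average is missing or is more
    than ``trust_margin`` A smaller (better) than the global resolution —
    local-resolution estimators commonly produce spuriously low values near
    ligands. With ``distrust_both_directions`` any |local - global| >
    trust_margin triggers the fallback. Always returns one of the two inputs.
    """
    if global_resolution <= 0:
        raise ValueError(f"global resolution must be positive, got {global_resolution}")
    if local_average is None:
        return global_resolution, ResolutionSource.GLOBAL_FALLBACK
    deviation = (
        abs(local_average - global_resolution)
        if distrust_both_directions
        else global_resolution - local_average
    )
    if deviation > trust_margin:
        return global_resolution, ResolutionSource.GLOBAL_FALLBACK
    return float(local_average), ResolutionSource.LOCAL_AVERAGE
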