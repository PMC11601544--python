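"""The identity-scoring core: expected-value models, Z-scores, softmax
probabilities and the ranked per-identity report.

Two empirical linear models predict what a correctly identified ligand should
look like. Expected binding affinity depends only on heavy-atom count a,

    dg_expected = -12.4442 - 0.4918 a,

and expected ligand density correlation on local resolution r (A), pose map
correlation p, and a,

    dens_expected = 0.4535 - 0.01904 r + 0.5543 p - 0.0006722 a.

Observed values are converted to Z-scores with empirically set standard
deviations (sigma_dg = -10.533, kept signed so a more-favorable-than-expected
ΔG scores positive; sigma_dens = 0.043152). The combined Z averages the two
components and divides by 0.5, which reduces exactly to their sum. Identity
probabilities come from a softmax over combined Z-scores with per-identity
exponent scales

    k_i = exp(0.1 Zmax) + exp(0.3 (l_i - 0.6)),

where Zmax is the largest combined Z in the screen and l_i the identity's raw
ligand map correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .density import (
    delta_lig_dens,
    density_penalty,
    pose_and_ligand_correlations,
)
from .features import NoLocalSignal, local_resolution_at, resolve_resolution
from .models import LigandCandidate, center_of_mass

__all__ = [
    "ScoringConstants",
    "ScoreRow",
    "expected_dg",
    "expected_density",
    "z_scores",
    "softmax_probabilities",
    "score_candidates",
    "rows_to_frame",
]


@dataclass(frozen=True)
class ScoringConstants:
    """All empirical constants of the scoring layer, overridable as a block."""

    dg_intercept: float = -12.4442       # energy units
    dg_slope: float = -0.4918            # energy units per heavy atom
    dens_intercept: float = 0.4535
    dens_r_coef: float = -0.01904        # per A of local resolution
    dens_p_coef: float = 0.5543
    dens_a_coef: float = -0.0006722      # per heavy atom
    sigma_dg: float = -10.533            # signed; see z_scores
    sigma_dens: float = 0.043152
    softmax_zmax_scale: float = 0.1
    softmax_l_scale: float = 0.3
    softmax_l_offset: float = 0.6
    z_quality_threshold: float = -1.0    # component Zs below this flag low quality
    high_confidence_probability: float = 0.60
    blob_report_z: float = -0.5          # top-identity combined-Z gate for blobs
    overfit_max_heavy_atoms: int = 10    # small molecules can overfit density
    use_corrected_l_in_softmax: bool = False
    absolute_sigma_dg: bool = False      # |sigma| with negated numerator (identical)

    def __post_init__(self) -> None:
        if self.sigma_dens <= 0:
            raise ValueError("sigma_dens must be positive")
        if self.sigma_dg == 0:
            raise ValueError("sigma_dg must be nonzero")


DEFAULT_CONSTANTS = ScoringConstants()


@dataclass
class ScoreRow:
    """Every derived quantity for one candidate identity."""

    identity: str
    a: int
    delta_g: float
    l_raw: float = np.nan
    delta_lig_dens: float = np.nan
    penalty: float = np.nan
    l_corrected: float = np.nan
    p: float = np.nan
    r: float = np.nan
    r_source: str = ""
    dg_expected: float = np.nan
    dens_expected: float = np.nan
    z_dg: float = np.nan
    z_dens: float = np.nan
    z_combined: float = np.nan
    k: float = np.nan
    probability: float = np.nan
    rank: int = 0
    flags: set[str] = field(default_factory=set)
    status: str = "ok"
    status_detail: str = ""


def expected_dg(a: int | float, constants: ScoringConstants = DEFAULT_CONSTANTS) -> float:
    """Expected binding affinity (energy units) for a ligand of a heavy atoms."""
    if a < 0:
        raise ValueError(f"heavy-atom count must be non-negative, got {a}")
    return constants.dg_intercept + constants.dg_slope * a


def expected_density(
    r: float,
    p: float,
    a: int | float,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> float:
    """Expected ligand map correlation given resolution r, pose correlation p
    and heavy-atom count a."""
    if r < 0 or a < 0 or abs(p) > 1 + 1e-9:
        raise ValueError(f"invalid feature domain: r={r}, p={p}, a={a}")
    return (
        constants.dens_intercept
        + constants.dens_r_coef * r
        + constants.dens_p_coef * p
        + constants.dens_a_coef * a
    )


def z_scores(
    delta_g: float,
    l_corrected: float,
    dg_expected_value: float,
    dens_expected_value: float,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """Component and combined Z-scores for one identity.

    The ΔG sigma is used with its printed negative sign, so a ΔG more
    favorable (more negative) than expected yields a positive z_dg; both
    component Zs are then "higher is better". The combined Z — the mean of
    the two components divided by 0.5 — equals their sum.
    """
    inputs = (delta_g, l_corrected, dg_expected_value, dens_expected_value)
    if not np.all(np.isfinite(inputs)):
        raise ValueError(f"non-finite z-score inputs: {inputs}")
    if constants.absolute_sigma_dg:
        z_dg = (dg_expected_value - delta_g) / abs(constants.sigma_dg)
    else:
        z_dg = (delta_g - dg_expected_value) / constants.sigma_dg
    z_dens = (l_corrected - dens_expected_value) / constants.sigma_dens
    z_combined = (z_dg + z_dens) / 2.0 / 0.5
    return z_dg, z_dens, z_combined


def softmax_probabilities(
    z_combined: np.ndarray,
    l_values: np.ndarray,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Identity probabilities from combined Z-scores and ligand correlations.

    Returns ``(probabilities, k)``. Exponents are shifted by their maximum
    before exponentiation; the result is mathematically unchanged.
    """
    z = np.asarray(z_combined, dtype=np.float64)
    l_values = np.asarray(l_values, dtype=np.float64)
    if z.size == 0:
        raise ValueError("softmax needs at least one identity")
    if z.shape != l_values.shape:
        raise ValueError("z and l vectors must be congruent")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(l_values))):
        raise ValueError("non-finite softmax inputs")
    z_max = z.max()
    k = np.exp(constants.softmax_zmax_scale * z_max) + np.exp(
        constants.softmax_l_scale * (l_values - constants.softmax_l_offset)
    )
    exponents = k * z
    shifted = np.exp(exponents - exponents.max())
    return shifted / shifted.sum(), k


def score_candidates(
    density_map,
    receptor,
    candidates: list[LigandCandidate],
    global_resolution: float,
    localres_map=None,
    constants: ScoringConstants = DEFAULT_CONSTANTS,
) -> list[ScoreRow]:
    """Score and rank a candidate library against a map and receptor.

    Per candidate: extract (r, p) features, compute the raw ligand
    correlation, the with/without-ligand correlation difference and its
    penalty, the expected values, and the Z-scores; then assign softmax
    probabilities jointly and rank by probability (ties: combined Z, then
    identity label). Candidates whose pose evaluation fails are reported with
    ``status='failed'`` and excluded from the softmax rather than poisoning it.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows: list[ScoreRow] = []
    for cand in candidates:
        row = ScoreRow(identity=cand.identity, a=cand.a, delta_g=cand.delta_g)
        try:
            ligand_heavy = cand.pose.heavy()
            try:
                local_avg = (
                    local_resolution_at(localres_map, center_of_mass(cand.pose))
                    if localres_map is not None
                    else None
                )
            except NoLocalSignal:
                local_avg = None
            row.r, source = resolve_resolution(local_avg, global_resolution)
            row.r_source = source.value
            row.p, row.l_raw = pose_and_ligand_correlations(
                density_map, receptor, ligand_heavy, resolution=row.r
            )
            row.delta_lig_dens = delta_lig_dens(
                density_map, receptor, ligand_heavy, resolution=row.r
            )
            row.penalty = density_penalty(row.delta_lig_dens)
            row.l_corrected = row.l_raw - row.penalty
            row.dg_expected = expected_dg(row.a, constants)
            row.dens_expected = expected_density(row.r, row.p, row.a, constants)
            row.z_dg, row.z_dens, row.z_combined = z_scores(
                row.delta_g, row.l_corrected, row.dg_expected, row.dens_expected,
                constants,
            )
        except Exception as exc:  # degenerate pose/map combinations
            row.status = "failed"
            row.status_detail = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    scored = [r for r in rows if r.status == "ok"]
    if scored:
        l_for_softmax = np.array(
            [r.l_corrected if constants.use_corrected_l_in_softmax else r.l_raw
             for r in scored]
        )
        probs, ks = softmax_probabilities(
            np.array([r.z_combined for r in scored]), l_for_softmax, constants
        )
        for row, prob, k in zip(scored, probs, ks):
            row.probability = float(prob)
            row.k = float(k)
        scored.sort(key=lambda r: (-r.probability, -r.z_combined, r.identity))
        top = scored[0]
        for rank, row in enumerate(scored, start=1):
            row.rank = rank
            if (
                row.z_dens < constants.z_quality_threshold
                or row.z_dg < constants.z_quality_threshold
            ):
                row.flags.add("below_z_quality")
            if row.a <= constants.overfit_max_heavy_atoms and row.z_dens > 0:
                row.flags.add("overfit_suspect")
        if top.probability > constants.high_confidence_probability:
            top.flags.add("high_confidence")
    failed = [r for r in rows if r.status == "failed"]
    return scored + failed


def rows_to_frame(rows: list[ScoreRow]) -> pd.DataFrame:
    """Tabulate ScoreRows (flags joined with ';') for TSV/JSON reporting."""
    records = []
    for row in rows:
        rec = {k: v for k, v in vars(row).items() if k != "flags"}
        rec["flags"] = ";".join(sorted(row.flags))
        records.append(rec)
    return pd.DataFrame.from_records(records)
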