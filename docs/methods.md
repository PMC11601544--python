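# Methods

## Problem and model

Cryo-EM maps of ligand-bound complexes often resolve a ligand's envelope
without resolving its identity. Given a map, a fitted receptor model and a
library of candidate identities — each with a docked pose and an externally
estimated binding affinity ΔG (Rosetta-style energy units, lower = more
favorable) — `cryoligid` decides which identity the density most plausibly
belongs to, and, independently, finds ligand-sized regions of unmodeled
density worth investigating.

The scoring core rests on two empirical linear models of what a *correct*
identification should look like. With a ligand of `a` heavy atoms, the
expected binding affinity is

    dg_expected = -12.4442 - 0.4918 a                                  (energy units)

and, with local resolution `r` (Å) and whole-pose map correlation `p`,
the expected ligand density correlation is

    dens_expected = 0.4535 - 0.01904 r + 0.5543 p - 0.0006722 a.

Observed values are standardised with empirically set spreads,
σ_ΔG = −10.533 and σ_dens = 0.043152. σ_ΔG is kept with its negative sign so
z_dg = (ΔG − dg_expected)/σ_ΔG is *positive* when ΔG is more favorable than
expected; both component Z-scores are then "higher is better". (A config
switch uses |σ_ΔG| with a negated numerator — mathematically identical.)
The combined score averages the two components and divides by 0.5, which
reduces exactly to z_dg + z_dens; the implementation computes the sum and a
test pins the equivalence.

Identity probabilities are a softmax over combined Z-scores with
per-identity exponent scales

    k_i = exp(0.1 Z_max) + exp(0.3 (l_i - 0.6)),
    P_i = exp(k_i Z_i) / Σ_j exp(k_j Z_j),

where Z_max is the largest combined Z in the screen and l_i the identity's
raw ligand map correlation. Z_max is read as the maximum of the *combined*
Z-scores (they are the ranked quantities), and l_i as the pre-penalty
correlation ("the map correlation of the docked ligand identity"); both
readings are isolated behind config switches
(`use_corrected_l_in_softmax`). Exponents are shifted by their maximum
before exponentiation, which cannot change the result but prevents
overflow; at extreme Z separations (|ΔZ| ≳ 350) the losing identity's
probability underflows to exactly 0 in float64, which we accept.

Large ligands at low resolution can score deceptively high ligand
correlations purely from receptor background density. The guard is
Δlig_dens — the map correlation of the model *with* minus *without* the
ligand, both over the same mask of voxels within 5 Å of any ligand atom —
and the penalty

    penalty = 0                         if Δlig_dens >= 0.15
    penalty = 0.15 - (2/3) Δlig_dens    otherwise,

subtracted from the ligand correlation before Z-scoring. The function is
deliberately discontinuous at 0.15 (left limit 0.05). For negative
Δlig_dens, outside the formula's natural domain, the penalty is capped at
its stated 0.15 maximum. When the receptor contributes no density at all in
the ligand neighborhood the without-ligand correlation is undefined
(constant model values); a constant density carries no signal, so that
correlation is taken as 0.

## Features

`r` is the mean of the strictly positive voxels of a local-resolution map
(e.g. MonoRes output) within 5 Å of the ligand's center of mass — zero
voxels mean "not estimated" and are excluded. A local average more than
1 Å *better* (numerically smaller) than the global resolution is
distrusted and replaced by the global value: local-resolution estimators
commonly produce spuriously low values near ligands. The opposite reading
(distrust any |local − global| > 1 Å) is available via
`distrust_both_directions`. The center of mass is the unweighted heavy-atom
centroid, the common convention in density tools; at a 5 Å averaging radius
the difference from a mass-weighted center is negligible.

`p` and `l` are Pearson correlations (mean-subtracted — "correlation"
unqualified is read as Pearson) of the experimental map against simulated
model density, over masks of voxels within 3.0 Å of the respective model's
atoms. Simulated density is a sum of isotropic per-atom Gaussians with

    sigma^2 = (resolution/pi)^2 / 2 + B/(8 pi^2),

amplitude = atomic number × occupancy, evaluated inside a 4.5 σ cutoff box.
This is the standard resolution-lowered Gaussian-atom approximation; its
exact form is plumbing, since every check that uses it is self-consistent
(the same simulator generates and evaluates).

## Unassigned-density finder

The receptor is masked at 3.0 Å around its atoms (the masking radius is a
package choice; `soft_mask_from_map` — Gaussian filter with per-axis sigma
0.02 × that axis's dimension in voxels, thresholded at 0.05 × the filtered
maximum — is offered as an alternative masking mode). Mean and SD of the
in-mask voxel values standardise every outside voxel; voxels with Z > 0.5
are peaks, grouped into blobs by 26-connectivity. A blob is reported when

* it has more than 70 voxels (strict),
* more than 90% of its surface voxels (6-face boundary definition — the
  stricter surface gives a well-defined lattice boundary) lie within 4 Å of
  a receptor atom, and
* every blob voxel is further than 5 Å from a chain break or terminus
  anchor — density hugging a cut usually belongs to unmodeled chain. The
  distance is the minimum over *all* blob voxels, the conservative reading.

Chain breaks are detected as non-consecutive residue numbering or a peptide
C→N distance above 2.0 Å; anchors are the backbone atoms (CA preferred) of
each chain's first/last residues and of both residues flanking a break.
Blobs are ordered lexicographically by (voxel count, surface-contact
fraction); no combining formula is imposed. Screening a blob recenters each
candidate pose on the blob centroid and runs the standard ranking; the
top identity is flagged for reporting when its combined Z exceeds −0.5.

## Quality flags

`below_z_quality`: either component Z below −1.0 — identifications where
both binding affinity and density correlation fall within one SD of
expectation are the trustworthy regime. `overfit_suspect`: ≤ 10 heavy atoms
with z_dens > 0 — small molecules can overfit density and inflate their
correlation. `high_confidence`: top probability above 0.60.

## Synthetic scenarios

The generator (`cryoligid.synthetic`) produces everything the tests and
checks consume, as a pure function of its seed. A screen scenario consists
of:

* a pseudo-protein of 60 C-alpha-like atoms in two chains (3.8 Å steps,
  confined random walk), optionally with an engineered numbering gap;
* a ligand site placed ≥ 14 Å from the nearest receptor atom, so that on a
  noiseless map the true pose's ligand-mask correlation is exactly 1 — the
  cost is that the site is not a realistic buried pocket, so the scenario
  exercises the penalty machinery only through dedicated close-contact
  fixtures, not through the screens;
* a true ligand of 20 heavy atoms (compact rigid point cloud; identities
  differ by atom count and geometry only — docking and chemistry are out of
  scope) and 4 decoys with 8–30 heavy atoms;
* the map: simulated density of receptor + true pose at 3.0 Å resolution on
  a 1.0 Å grid, plus i.i.d. Gaussian voxel noise with SD 0.1 × the peak.
  Real cryo-EM noise is neither i.i.d. nor white; projection simulation and
  reconstruction are not modelled, so passing screens demonstrate the
  scoring logic, not robustness to realistic noise;
* ΔG assignments: each candidate's own size expectation ± half the margin
  (default 1 |σ_ΔG|, sign favorable for the true identity) plus i.i.d.
  scatter of 0.1 |σ_ΔG| — so a margin of m separates z_dg by m on average,
  and at m = 0 candidates are exchangeable;
* decoy poses: the true pose resized to the decoy's atom count, then
  jittered along fixed random directions with an amplitude bisected against
  the *measured* ligand correlation until it sits ~0.13 (≈ 3 σ_dens) below
  the true identity's. A decoy whose atom count differs substantially from
  the truth may fit strictly worse than the target — fewer or extra atoms
  cannot explain the density — in which case the deficit exceeds the
  request, never undershoots it. At zero deficit decoys share the true pose
  exactly, so the null ranking is driven by the ΔG scatter alone.

Blob scenarios plant a compact 26-connected region of exactly N voxels in
the shell 3.2–3.9 Å from receptor atoms (attached; full surface contact) or
beyond 5 Å (detached), either clear of (> 6.5 Å) or adjacent to (≤ 4.5 Å)
a terminus anchor, with values set to the in-mask mean + 3 in-mask SDs. At
zero noise the finder recovers the planted geometry voxel-for-voxel.

## Numerical and design choices

* Grids are indexed (x, y, z) with voxel centers at origin + index × voxel
  size; MRC axis permutations are normalised on read. MRC I/O goes through
  gemmi and round-trips values (bit-exact in float32), anisotropic voxel
  sizes and ORIGIN headers.
* Pearson correlations are clipped to [−1, 1] against rounding; masks with
  < 2 voxels or constant values raise rather than return NaN.
* Candidates whose pose evaluation fails (e.g. outside the map) are
  reported with a failure status and excluded from the softmax, so one bad
  pose cannot poison the normalisation.
* Ties in the ranking break by combined Z, then identity label, making
  reports byte-deterministic.
* All empirical constants live in a single frozen `ScoringConstants` block,
  overridable programmatically or via TOML on the CLI; the blob filters
  likewise in `BlobFinderParams`.

## Problem sizes

The test suite and the acceptance script run on the generator's default
conditions: ~50×50×45 voxel grids, 60-atom receptors, 5-identity libraries,
50 seeded screens for the recovery checks and 21 planted blob sizes
(60–80 voxels) for the volume-filter check. These sizes were chosen so a
full check runs on a laptop-class single core in a few minutes while
keeping every decision path (penalty branches, fallbacks, filter flips)
exercised.

## Known limitations

* ΔG estimation, docking, ligand chemistry (protonation, charges,
  conformers) and the regression-coefficient training are out of scope; the
  constants are fixed as given (but configurable).
* Local-resolution maps are consumed, not computed (no MonoRes/blocres).
* The simulator has no Fourier-space scattering factors, solvent model or
  sharpening; correlations against *experimental* maps will be
  systematically lower than against self-consistent simulated maps.
* Blob detection assumes a single unmodeled ligand per region; glycans,
  metals and multi-ligand pockets are not distinguished.
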