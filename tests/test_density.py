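import numpy as np
import pytest

import cryoligid as cl
from cryoligid.density import _atom_sigma
from cryoligid.maps import DegenerateMapError


def atom(pos, element="C", b=0.0):
    return cl.AtomRecord(element=element, position=tuple(pos), b_factor=b)


@pytest.fixture
def template():
    return cl.DensityMap(np.zeros((24, 24, 24)), voxel_size=1.0)


class TestSimulateDensity:
    def test_single_atom_peaks_at_nearest_voxel(self, template):
        model = cl.MolecularModel([atom((10.3, 11.6, 12.1))])
        sim = cl.simulate_density(model, template, resolution=3.0)
        assert np.unravel_index(sim.values.argmax(), sim.shape) == (10, 12, 12)

    def test_two_distant_atoms_give_two_equal_maxima(self, template):
        model = cl.MolecularModel([atom((6, 6, 6)), atom((17, 17, 17))])
        sim = cl.simulate_density(model, template, resolution=3.0)
        assert np.isclose(sim.values[6, 6, 6], sim.values[17, 17, 17], rtol=1e-6)

    def test_integral_matches_gaussian_normalization(self):
        # fine grid so the voxel sum approximates the analytic integral
        fine = cl.DensityMap(np.zeros((60, 60, 60)), voxel_size=0.25)
        model = cl.MolecularModel([atom((7.5, 7.5, 7.5), element="O")])
        sim = cl.simulate_density(model, fine, resolution=2.0)
        integral = sim.values.sum() * 0.25**3
        from cryoligid.density import ELEMENT_WEIGHTS
        assert np.isclose(integral, ELEMENT_WEIGHTS["O"], rtol=0.01)

    def test_linearity_in_the_model(self, template):
        a = cl.MolecularModel([atom((8, 8, 8)), atom((10, 9, 8))])
        b = cl.MolecularModel([atom((15, 14, 16), element="N", b=30.0)])
        sim_a = cl.simulate_density(a, template, resolution=3.0)
        sim_b = cl.simulate_density(b, template, resolution=3.0)
        sim_ab = cl.simulate_density(a + b, template, resolution=3.0)
        np.testing.assert_allclose(
            sim_ab.values, sim_a.values + sim_b.values, atol=1e-12
        )

    def test_b_factor_broadens_the_gaussian(self):
        assert _atom_sigma(3.0, 40.0) > _atom_sigma(3.0, 0.0)

    def test_non_positive_resolution_rejected(self, template):
        with pytest.raises(ValueError):
            cl.simulate_density(
                cl.MolecularModel([atom((5, 5, 5))]), template, resolution=0.0
            )


class TestMaskedCorrelation:
    def test_self_correlation_is_one(self, cube_map):
        mask = cl.BinaryMask(np.ones(cube_map.shape, dtype=bool),
                             cube_map.voxel_size, cube_map.origin)
        assert cl.masked_correlation(cube_map, cube_map, mask).value == pytest.approx(1.0)

    def test_affine_invariance(self, cube_map):
        shifted = cl.DensityMap(3.0 + 2.0 * cube_map.values,
                                cube_map.voxel_size, cube_map.origin)
        mask = cl.BinaryMask(np.ones(cube_map.shape, dtype=bool),
                             cube_map.voxel_size, cube_map.origin)
        assert cl.masked_correlation(cube_map, shifted, mask).value == pytest.approx(1.0)

    def test_hand_computed_three_cube(self):
        a = cl.DensityMap(np.arange(27, dtype=float).reshape(3, 3, 3), voxel_size=1.0)
        b = cl.DensityMap((np.arange(27, dtype=float) ** 2).reshape(3, 3, 3),
                          voxel_size=1.0)
        mask = cl.BinaryMask(np.ones((3, 3, 3), dtype=bool), a.voxel_size, a.origin)
        x, y = np.arange(27.0), np.arange(27.0) ** 2
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert cl.masked_correlation(a, b, mask).value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_pearson(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 17, size=3))
        a = cl.DensityMap(rng.normal(size=shape), voxel_size=1.0)
        b = cl.DensityMap(rng.normal(size=shape), voxel_size=1.0)
        sel = rng.random(shape) < 0.5
        sel.flat[:2] = True  # ensure at least 2 voxels
        mask = cl.BinaryMask(sel, a.voxel_size, a.origin)
        got = cl.masked_correlation(a, b, mask).value
        # independent brute-force loop over the masked voxels
        xs, ys = [], []
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if sel[i, j, k]:
                        xs.append(a.values[i, j, k])
                        ys.append(b.values[i, j, k])
        xs, ys = np.array(xs), np.array(ys)
        num = ((xs - xs.mean()) * (ys - ys.mean())).sum()
        den = np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        assert got == pytest.approx(num / den, abs=1e-10)

    def test_constant_values_rejected(self, cube_map):
        const = cl.DensityMap(np.ones(cube_map.shape), cube_map.voxel_size,
                              cube_map.origin)
        mask = cl.BinaryMask(np.ones(cube_map.shape, dtype=bool),
                             cube_map.voxel_size, cube_map.origin)
        with pytest.raises(DegenerateMapError):
            cl.masked_correlation(cube_map, const, mask)


class TestPoseAndLigandCorrelations:
    @pytest.fixture
    def scene(self, template):
        receptor = cl.MolecularModel([atom((8 + 2 * i, 9, 10)) for i in range(4)])
        ligand = cl.MolecularModel([atom((12, 14, 13)), atom((13, 15, 13)),
                                    atom((12, 15, 14), element="O")])
        return receptor, ligand

    def test_self_consistent_map_gives_unit_correlations(self, template, scene):
        receptor, ligand = scene
        truth = cl.simulate_density(receptor + ligand, template, resolution=3.0)
        p, l = cl.pose_and_ligand_correlations(truth, receptor, ligand, 3.0)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert l == pytest.approx(1.0, abs=1e-9)

    def test_missing_ligand_density_lowers_l(self, template, scene):
        receptor, ligand = scene
        with_lig = cl.simulate_density(receptor + ligand, template, 3.0)
        without = cl.simulate_density(receptor, template, 3.0)
        _, l_with = cl.pose_and_ligand_correlations(with_lig, receptor, ligand, 3.0)
        _, l_without = cl.pose_and_ligand_correlations(without, receptor, ligand, 3.0)
        assert l_without < l_with - 0.3

    def test_shuffled_map_destroys_correlation(self, template, scene, rng):
        receptor, ligand = scene
        truth = cl.simulate_density(receptor + ligand, template, 3.0)
        shuffled = truth.values.reshape(-1).copy()
        rng.shuffle(shuffled)
        noise_map = cl.DensityMap(shuffled.reshape(truth.shape),
                                  truth.voxel_size, truth.origin)
        _, l = cl.pose_and_ligand_correlations(noise_map, receptor, ligand, 3.0)
        assert abs(l) < 0.5

    def test_rigid_translation_invariance(self, scene):
        receptor, ligand = scene
        template = cl.DensityMap(np.zeros((24, 24, 24)), voxel_size=1.0)
        truth = cl.simulate_density(receptor + ligand, template, 3.0)
        p0, l0 = cl.pose_and_ligand_correlations(truth, receptor, ligand, 3.0)
        shift = np.array([2.0, -1.0, 3.0])  # whole voxels: exact invariance
        moved = cl.DensityMap(truth.values, truth.voxel_size,
                              truth.origin + shift)
        p1, l1 = cl.pose_and_ligand_correlations(
            moved, receptor.translated(shift), ligand.translated(shift), 3.0
        )
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert l1 == pytest.approx(l0, abs=1e-9)


class TestDeltaLigDens:
    @pytest.fixture
    def scene(self, template):
        receptor = cl.MolecularModel([atom((8 + 2 * i, 9, 10)) for i in range(4)])
        ligand = cl.MolecularModel([atom((12, 15, 14)), atom((13, 16, 14)),
                                    atom((12, 16, 15), element="N")])
        return receptor, ligand

    def test_ligand_density_present_gives_large_positive_delta(self, template, scene):
        receptor, ligand = scene
        truth = cl.simulate_density(receptor + ligand, template, 3.0)
        delta = cl.delta_lig_dens(truth, receptor, ligand, 3.0)
        assert delta > 0.15

    def test_no_ligand_density_gives_non_positive_delta(self, template, scene):
        receptor, ligand = scene
        receptor_only = cl.simulate_density(receptor, template, 3.0)
        delta = cl.delta_lig_dens(receptor_only, receptor, ligand, 3.0)
        assert delta <= 0.05


class TestDensityPenalty:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.20, 0.0), (0.15, 0.0), (0.0, 0.15), (0.09, 0.09),
         (0.1499, 0.15 - (2 / 3) * 0.1499), (-0.5, 0.15)],
    )
    def test_branch_values(self, delta, expected):
        assert cl.density_penalty(delta) == pytest.approx(expected, abs=1e-12)

    def test_discontinuity_at_threshold(self):
        # left limit is 0.05, branch value is 0
        eps = 1e-9
        assert cl.density_penalty(0.15) == 0.0
        assert cl.density_penalty(0.15 - eps) == pytest.approx(0.05, abs=1e-6)

    def test_non_increasing_below_threshold(self):
        deltas = np.linspace(0.0, 0.1499, 50)
        penalties = [cl.density_penalty(d) for d in deltas]
        assert all(a >= b for a, b in zip(penalties, penalties[1:]))
        assert all(0 <= p <= 0.15 for p in penalties)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cl.density_penalty(float("nan"))
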