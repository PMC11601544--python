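import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cryoligid as cl
from cryoligid.scoring import DEFAULT_CONSTANTS, softmax_probabilities

# independent high-precision evaluation (sympy, 30 digits) of the K = 2 case
# z = (1, 0), l = (0.7, 0.7):
#   k = exp(1/10) + exp(3/100)     = 2.13562545202916448...
#   p1 = 1 / (1 + exp(-k))         = 0.894317869618560776...
K2_ORACLE_K = 2.13562545202916448
K2_ORACLE_P1 = 0.894317869618560776


class TestExpectedValues:
    @pytest.mark.parametrize("a, expected", [
        (0, -12.4442),
        (10, -17.3622),
        (30, -27.1982),
    ])
    def test_expected_dg(self, a, expected):
        assert cl.expected_dg(a) == pytest.approx(expected, abs=1e-10)

    def test_expected_dg_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cl.expected_dg(-1)

    @pytest.mark.parametrize("r, p, a, expected", [
        (0.0, 0.0, 0, 0.4535),
        (3.0, 0.8, 30, 0.4535 - 0.01904 * 3 + 0.5543 * 0.8 - 0.0006722 * 30),
    ])
    def test_expected_density(self, r, p, a, expected):
        assert cl.expected_density(r, p, a) == pytest.approx(expected, abs=1e-12)

    def test_expected_density_worked_value(self):
        assert cl.expected_density(3.0, 0.8, 30) == pytest.approx(0.819654, abs=1e-6)

    def test_expected_density_decreases_with_resolution(self):
        assert cl.expected_density(4.0, 0.8, 20) < cl.expected_density(3.0, 0.8, 20)


class TestZScores:
    def test_at_the_mean_all_zero(self):
        z = cl.z_scores(-20.0, 0.7, -20.0, 0.7)
        assert z == (pytest.approx(0, abs=1e-12),) * 3

    def test_one_density_sigma_is_unit_z(self):
        dg_e = cl.expected_dg(20)
        dens_e = 0.70
        z_dg, z_dens, z_comb = cl.z_scores(
            dg_e, dens_e + DEFAULT_CONSTANTS.sigma_dens, dg_e, dens_e
        )
        assert z_dens == pytest.approx(1.0, abs=1e-9)
        assert z_comb == pytest.approx(1.0, abs=1e-9)

    def test_favorable_dg_scores_positive(self):
        # one |sigma_dg| more favorable (more negative) than expected
        dg_e = cl.expected_dg(20)
        z_dg, _, _ = cl.z_scores(dg_e - 10.533, 0.7, dg_e, 0.7)
        assert z_dg == pytest.approx(1.0, abs=1e-9)

    def test_absolute_sigma_convention_is_identical(self):
        alt = cl.ScoringConstants(absolute_sigma_dg=True)
        dg_e = cl.expected_dg(15)
        for offset in (-8.0, 0.0, 5.0):
            z_default = cl.z_scores(dg_e + offset, 0.7, dg_e, 0.7)
            z_alt = cl.z_scores(dg_e + offset, 0.7, dg_e, 0.7, constants=alt)
            assert z_default == pytest.approx(z_alt, abs=1e-12)

    def test_combined_equals_sum_of_components(self, rng):
        for _ in range(20):
            dg, l = rng.normal(-25, 8), rng.uniform(0.2, 0.95)
            z_dg, z_dens, z_comb = cl.z_scores(dg, l, -22.0, 0.7)
            assert z_comb == pytest.approx(z_dg + z_dens, abs=1e-12)

    def test_monotonicity(self):
        _, z1, _ = cl.z_scores(-20.0, 0.70, -20.0, 0.6)
        _, z2, _ = cl.z_scores(-20.0, 0.75, -20.0, 0.6)
        assert z2 > z1
        za, _, _ = cl.z_scores(-25.0, 0.7, -20.0, 0.6)
        zb, _, _ = cl.z_scores(-30.0, 0.7, -20.0, 0.6)
        assert zb > za  # lower (better) ΔG scores higher


class TestSoftmax:
    def test_single_identity_gets_probability_one(self):
        probs, _ = cl.softmax_probabilities(np.array([0.3]), np.array([0.8]))
        assert probs == pytest.approx([1.0])

    @pytest.mark.parametrize("k", [2, 5, 100])
    def test_symmetric_inputs_give_uniform(self, k):
        probs, _ = cl.softmax_probabilities(np.full(k, -1.3), np.full(k, 0.55))
        np.testing.assert_allclose(probs, 1.0 / k, atol=1e-14)

    def test_two_identity_worked_example(self):
        probs, ks = cl.softmax_probabilities(
            np.array([1.0, 0.0]), np.array([0.7, 0.7])
        )
        assert ks[0] == pytest.approx(K2_ORACLE_K, abs=1e-12)
        assert probs[0] == pytest.approx(K2_ORACLE_P1, abs=1e-12)

    def test_overflow_safe_for_extreme_z(self):
        probs, _ = cl.softmax_probabilities(
            np.array([400.0, -400.0]), np.array([0.9, 0.1])
        )
        assert np.all(np.isfinite(probs))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        z=st.lists(st.floats(-30, 30), min_size=1, max_size=40),
        seed=st.integers(0, 2**16),
    )
    def test_probabilities_sum_to_one(self, z, seed):
        l = np.random.default_rng(seed).uniform(-0.2, 1.0, size=len(z))
        probs, _ = cl.softmax_probabilities(np.array(z), l)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(probs >= 0) and np.all(probs <= 1)

    @settings(max_examples=60, derandomize=True)
    @given(
        z=st.lists(st.floats(-4, 4), min_size=1, max_size=40),
        seed=st.integers(0, 2**16),
    )
    def test_probabilities_strictly_positive_at_moderate_z(self, z, seed):
        # extreme Z separations can underflow a loser to exactly 0 in float64;
        # within the Z ranges screens actually produce, every identity keeps
        # nonzero probability
        l = np.random.default_rng(seed).uniform(-0.2, 1.0, size=len(z))
        probs, _ = cl.softmax_probabilities(np.array(z), l)
        assert np.all(probs > 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cl.softmax_probabilities(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def screen():
    spec = cl.ScenarioSpec(seed=11)
    return cl.make_screen_scenario(spec), spec


class TestScoreCandidates:
    def test_true_identity_ranks_first(self, screen):
        (density_map, receptor, candidates, truth), spec = screen
        rows = cl.score_candidates(density_map, receptor, candidates,
                                   spec.resolution)
        assert rows[0].identity == truth["identity"]
        assert rows[0].rank == 1

    def test_ranks_are_a_permutation(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        rows = cl.score_candidates(density_map, receptor, candidates,
                                   spec.resolution)
        ok = [r for r in rows if r.status == "ok"]
        assert sorted(r.rank for r in ok) == list(range(1, len(ok) + 1))
        assert sum(r.probability for r in ok) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariant_under_input_permutation(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        forward = cl.score_candidates(density_map, receptor, candidates,
                                      spec.resolution)
        backward = cl.score_candidates(density_map, receptor, candidates[::-1],
                                       spec.resolution)
        assert [r.identity for r in forward] == [r.identity for r in backward]
        for a, b in zip(forward, backward):
            assert a.probability == pytest.approx(b.probability, abs=1e-12)

    def test_identical_candidates_tie_deterministically(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        true = candidates[0]
        twin_b = cl.LigandCandidate("BBB", true.pose, true.delta_g)
        twin_a = cl.LigandCandidate("AAA", true.pose, true.delta_g)
        rows = cl.score_candidates(density_map, receptor, [twin_b, twin_a],
                                   spec.resolution)
        assert [r.identity for r in rows] == ["AAA", "BBB"]  # label tie-break
        assert rows[0].probability == pytest.approx(rows[1].probability, abs=1e-12)

    def test_single_candidate_certainty(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        rows = cl.score_candidates(density_map, receptor, candidates[:1],
                                   spec.resolution)
        assert rows[0].rank == 1
        assert rows[0].probability == pytest.approx(1.0)

    def test_failed_pose_reported_not_dropped(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        out_of_map = cl.LigandCandidate(
            "OUT", candidates[0].pose.translated((500.0, 0.0, 0.0)), -20.0
        )
        rows = cl.score_candidates(density_map, receptor,
                                   candidates + [out_of_map], spec.resolution)
        by_id = {r.identity: r for r in rows}
        assert by_id["OUT"].status == "failed"
        ok = [r for r in rows if r.status == "ok"]
        assert sum(r.probability for r in ok) == pytest.approx(1.0, abs=1e-9)

    def test_quality_flags(self, screen):
        (density_map, receptor, candidates, _), spec = screen
        rows = cl.score_candidates(density_map, receptor, candidates,
                                   spec.resolution)
        top = rows[0]
        if top.probability > 0.60:
            assert "high_confidence" in top.flags
        for r in rows:
            if r.status == "ok" and (r.z_dens < -1.0 or r.z_dg < -1.0):
                assert "below_z_quality" in r.flags
            if r.status == "ok" and r.a <= 10 and r.z_dens > 0:
                assert "overfit_suspect" in r.flags

    def test_empty_candidate_list_rejected(self, screen):
        (density_map, receptor, _, _), spec = screen
        with pytest.raises(ValueError):
            cl.score_candidates(density_map, receptor, [], spec.resolution)
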