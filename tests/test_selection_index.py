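"""Index weights, accuracy, responses, restrictions, trait-holding values."""

import numpy as np
import pytest

import feedsel as fs
from feedsel.params import ParameterError
from feedsel.selection_index import BreedingGoal, IndexMatrices


def toy_matrices(p, g, c=None, traits=None):
    p = np.asarray(p, dtype=float)
    traits = traits or tuple(f"T{i}" for i in range(p.shape[0]))
    return IndexMatrices(traits=traits, P=p, G=np.asarray(g, float),
                         C=np.asarray(c if c is not None else g, float))


@pytest.fixture(scope="module")
def three_trait(trait_params, full_corr):
    """FY, AFS, RFI sub-problem of the full fixture."""
    keep = ["FY", "AFS", "RFI"]
    sub = [p for p in trait_params if p.trait.code in keep]
    rg = full_corr.rg.loc[keep, keep]
    return fs.build_gebv_index_matrices(sub, rg)


class TestBuildMatrices:
    def test_single_trait_closed_form(self, trait_params, full_corr):
        fy = [p for p in trait_params if p.trait.code == "FY"]
        m = fs.build_gebv_index_matrices(fy, np.eye(1))
        # r^2 sigma_g^2 with r = 0.80, sigma_g = 30.67
        assert m.P[0, 0] == pytest.approx(0.64 * 940.6, abs=0.5)
        assert np.array_equal(m.P, m.G)

    def test_uncorrelated_traits_give_block_diagonal(self, trait_params):
        two = [p for p in trait_params if p.trait.code in ("FY", "RFI")]
        m = fs.build_gebv_index_matrices(two, np.eye(2))
        assert m.P[0, 1] == 0.0

    def test_gebv_convention_makes_p_equal_g(self, index_matrices):
        assert np.array_equal(index_matrices.P, index_matrices.G)

    def test_singular_case_rejected(self, trait_params):
        two = [p for p in trait_params if p.trait.code in ("DMI", "RFI")]
        with pytest.raises(ParameterError):
            fs.build_gebv_index_matrices(two, np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestSolveIndexWeights:
    def test_weights_equal_values_when_p_equals_g(self, index_matrices):
        v = np.array([9.02, 7.16, 0, 0, -2.57, -6.86, -233.0, -707.0, 0, -88.45])
        goal = BreedingGoal(index_matrices.traits, v)
        sol = fs.solve_index_weights(index_matrices, goal)
        assert np.allclose(sol.b, v, atol=1e-8)
        assert 0 < sol.accuracy <= 1

    def test_homogeneity_in_economic_values(self, index_matrices):
        v = np.zeros(10)
        v[0], v[9] = 9.02, -88.45
        goal1 = BreedingGoal(index_matrices.traits, v)
        goal3 = BreedingGoal(index_matrices.traits, 3 * v)
        s1 = fs.solve_index_weights(index_matrices, goal1)
        s3 = fs.solve_index_weights(index_matrices, goal3)
        assert np.allclose(s3.b, 3 * s1.b)
        assert s3.accuracy == pytest.approx(s1.accuracy, abs=1e-12)

    def test_two_by_two_hand_case(self):
        m = toy_matrices([[2, 0], [0, 2]], np.eye(2))
        sol = fs.solve_index_weights(m, BreedingGoal(m.traits, np.ones(2)))
        assert np.allclose(sol.b, [0.5, 0.5])

    def test_accuracy_equals_gebv_accuracy_for_single_trait(self, trait_params):
        fy = [p for p in trait_params if p.trait.code == "FY"]
        m = fs.build_gebv_index_matrices(fy, np.eye(1))
        sol = fs.solve_index_weights(m, BreedingGoal(m.traits, np.ones(1)))
        assert sol.accuracy == pytest.approx(0.80, abs=1e-12)

    def test_grid_search_finds_no_better_index(self, three_trait):
        # brute-force oracle: no weight direction on a 0.01-step grid beats
        # the analytic solution's correlation with the goal
        v = np.array([9.02, -2.57, -88.45])
        goal = BreedingGoal(three_trait.traits, v)
        sol = fs.solve_index_weights(three_trait, goal)
        sigma_h = np.sqrt(v @ three_trait.C @ v)
        r_best = sol.sigma_index / sigma_h

        axis = np.arange(-1.0, 1.0 + 1e-9, 0.01)
        bb = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                      axis=-1).reshape(-1, 3)
        bb = bb[np.any(bb != 0, axis=1)]
        # scale out: correlation is invariant, so normalize cheaply
        num = bb @ (three_trait.G @ v)
        den = np.sqrt(np.einsum("ij,jk,ik->i", bb, three_trait.P, bb)) * sigma_h
        r_grid = (num / den).max()
        assert r_grid <= r_best + 1e-3


class TestRestrictedIndex:
    def test_restricted_trait_has_zero_response(self, index_matrices):
        v = np.zeros(10)
        v[0], v[1], v[9] = 9.02, 7.16, -88.45
        goal = BreedingGoal(index_matrices.traits, v)
        sol = fs.restricted_index_weights(index_matrices, goal, ["RFI"])
        j = index_matrices.traits.index("RFI")
        assert abs(sol.response_per_intensity[j]) < 1e-10

    def test_empty_restriction_matches_unrestricted(self, index_matrices):
        v = np.zeros(10)
        v[0] = 1.0
        goal = BreedingGoal(index_matrices.traits, v)
        a = fs.restricted_index_weights(index_matrices, goal, [])
        b = fs.solve_index_weights(index_matrices, goal)
        assert np.allclose(a.b, b.b)

    def test_restricting_all_traits_is_degenerate(self, index_matrices):
        goal = BreedingGoal(index_matrices.traits, np.ones(10))
        sol = fs.restricted_index_weights(index_matrices, goal,
                                          list(index_matrices.traits))
        assert sol.degenerate
        assert sol.sigma_index == 0.0
        assert np.allclose(sol.response_per_intensity, 0.0)

    def test_restriction_never_gains_index_sd(self, index_matrices):
        v = np.zeros(10)
        v[0], v[1] = 9.02, 7.16
        goal = BreedingGoal(index_matrices.traits, v)
        free = fs.solve_index_weights(index_matrices, goal)
        restr = fs.restricted_index_weights(index_matrices, goal, ["DMI"])
        assert restr.sigma_index <= free.sigma_index + 1e-12


class TestSelectionIntensity:
    def test_no_selection_gives_zero(self):
        assert fs.selection_intensity(1.0) == 0.0

    def test_half_selected(self):
        assert fs.selection_intensity(0.5) == pytest.approx(0.7979, abs=1e-4)

    def test_genomic_bull_proportion(self):
        # 2,100 of 30,000 bull calves kept
        assert fs.selection_intensity(0.07) == pytest.approx(1.918, abs=1e-3)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_proportions(self, p):
        with pytest.raises(ParameterError):
            fs.selection_intensity(p)


class TestResponseToSelection:
    def test_single_trait_classic_form(self, trait_params):
        rfi = [p for p in trait_params if p.trait.code == "RFI"]
        m = fs.build_gebv_index_matrices(rfi, np.eye(1))
        sol = fs.solve_index_weights(m, BreedingGoal(m.traits, np.ones(1)))
        i = 1.755
        resp = fs.response_to_selection(sol, m, i)["units"]
        assert resp[0] == pytest.approx(i * 0.40 * 0.89, rel=1e-9)

    def test_zero_intensity_zero_response(self, index_matrices):
        goal = BreedingGoal(index_matrices.traits, np.ones(10))
        sol = fs.solve_index_weights(index_matrices, goal)
        assert np.allclose(
            fs.response_to_selection(sol, index_matrices, 0.0)["units"], 0.0)

    def test_two_trait_hand_arithmetic(self):
        p = np.array([[2.0, 0.5], [0.5, 1.0]])
        m = toy_matrices(p, p)
        v = np.array([1.0, 2.0])
        sol = fs.solve_index_weights(m, BreedingGoal(m.traits, v))
        sigma = np.sqrt(v @ p @ v)
        assert np.allclose(sol.response_per_intensity, (p @ v) / sigma)

    def test_sdu_scaling(self, index_matrices, sigma_g):
        goal = BreedingGoal(index_matrices.traits, np.ones(10))
        sol = fs.solve_index_weights(index_matrices, goal)
        out = fs.response_to_selection(sol, index_matrices, 1.0, sigma_g=sigma_g)
        assert np.allclose(out["sdu"] * sigma_g, out["units"])

    def test_reordering_equivariance(self, trait_params, full_corr):
        perm = np.array([3, 0, 9, 1, 2, 4, 5, 6, 7, 8])
        params_p = [trait_params[i] for i in perm]
        rg_p = full_corr.rg.iloc[perm, perm]
        m0 = fs.build_gebv_index_matrices(trait_params, full_corr.rg)
        mp = fs.build_gebv_index_matrices(params_p, rg_p)
        v = np.linspace(-2, 2, 10)
        s0 = fs.solve_index_weights(m0, BreedingGoal(m0.traits, v))
        sp = fs.solve_index_weights(mp, BreedingGoal(mp.traits, v[perm]))
        assert np.allclose(sp.response_per_intensity,
                           s0.response_per_intensity[perm], atol=1e-10)


class TestHoldingEconomicValue:
    def test_orthogonal_trait_holds_at_zero(self):
        m = toy_matrices([[2.0, 0.0], [0.0, 1.0]], [[2.0, 0.0], [0.0, 1.0]])
        goal = BreedingGoal(m.traits, np.array([1.0, 0.0]))
        v = fs.solve_holding_economic_value(m, goal, "T1")
        assert v == pytest.approx(0.0, abs=1e-8)

    def test_post_check_response_is_zero(self, index_matrices):
        v = np.zeros(10)
        v[0], v[1], v[9] = 9.02, 7.16, -88.45
        goal = BreedingGoal(index_matrices.traits, v)
        held_value = fs.solve_holding_economic_value(index_matrices, goal, "STAT")
        sol = fs.solve_index_weights(
            index_matrices, goal.with_value("STAT", held_value))
        j = index_matrices.traits.index("STAT")
        assert abs(sol.response_per_intensity[j]) < 1e-8

    def test_agrees_with_restricted_index(self, three_trait):
        goal = BreedingGoal(three_trait.traits, np.array([9.02, -2.57, 0.0]))
        held_value = fs.solve_holding_economic_value(three_trait, goal, "RFI")
        by_value = fs.solve_index_weights(
            three_trait, goal.with_value("RFI", held_value))
        by_restriction = fs.restricted_index_weights(three_trait, goal, ["RFI"])
        assert np.allclose(by_value.response_per_intensity,
                           by_restriction.response_per_intensity, atol=1e-6)

    def test_joint_hold_solves_linear_system(self, index_matrices):
        v = np.zeros(10)
        v[0], v[1], v[9] = 9.02, 7.16, -88.45
        goal = BreedingGoal(index_matrices.traits, v)
        held = fs.solve_holding_economic_values(index_matrices, goal,
                                                ["STAT", "BCS"])
        sol = fs.solve_index_weights(index_matrices, held)
        for t in ("STAT", "BCS"):
            assert abs(sol.response_per_intensity[index_matrices.traits.index(t)]) < 1e-8

    def test_bracket_without_sign_change_reports_endpoints(self):
        m = toy_matrices([[2.0, 0.0], [0.0, 1.0]], [[2.0, 0.0], [0.0, 1.0]])
        goal = BreedingGoal(m.traits, np.array([1.0, 5.0]))
        with pytest.raises(ParameterError, match="bracket"):
            fs.solve_holding_economic_value(m, goal, "T1", bracket=(1.0, 2.0))


class TestProgenyTestAccuracy:
    def test_no_daughters_no_accuracy(self):
        assert fs.progeny_test_accuracy(0, 0.29) == 0.0

    def test_limit_is_one(self):
        assert fs.progeny_test_accuracy(10 ** 6, 0.29) == pytest.approx(1.0, abs=1e-3)

    def test_proven_bull_with_hundred_daughters(self):
        assert fs.progeny_test_accuracy(100, 0.29) == pytest.approx(0.942, abs=1e-3)

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.2])
    def test_h2_out_of_range(self, h2):
        with pytest.raises(ParameterError):
            fs.progeny_test_accuracy(100, h2)
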