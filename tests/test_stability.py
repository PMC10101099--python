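import numpy as np
import pytest

from microstab import (GlvModel, assess_stability, boundary_equilibria,
                       dissipativity_check, dominant_eigenvalue,
                       interior_equilibrium, invasibility_test, jacobian,
                       permanence_lp, random_stable_glv, simulate_ricker)
from microstab.stability import StabilityError, verify_certificate
from microstab.synthetic import batch_min_abundance

LOGISTIC = GlvModel([[-1.0]], [1.0])
WEAK = GlvModel([[-1.0, -0.5], [-0.5, -1.0]], [1.0, 1.0])
STRONG = GlvModel([[-1.0, -2.0], [-2.0, -1.0]], [1.0, 1.0])


class TestInteriorEquilibrium:
    def test_logistic(self):
        x, feasible = interior_equilibrium(LOGISTIC)
        assert feasible and x[0] == pytest.approx(1.0)

    def test_weak_competition(self):
        x, feasible = interior_equilibrium(WEAK)
        assert feasible
        np.testing.assert_allclose(x, [2 / 3, 2 / 3], atol=1e-12)

    def test_strong_competition_feasible_but_not_permanent(self):
        x, feasible = interior_equilibrium(STRONG)
        assert feasible
        np.testing.assert_allclose(x, [1 / 3, 1 / 3], atol=1e-12)
        assert permanence_lp(STRONG)[0] is False

    def test_infeasible_flagged_not_clamped(self):
        m = GlvModel([[-1.0, 0.0], [0.0, -1.0]], [1.0, -0.5])
        x, feasible = interior_equilibrium(m)
        assert not feasible and x[1] == pytest.approx(-0.5)

    def test_singular_matrix_raises(self):
        m = GlvModel([[1e-15, 0.0], [0.0, -1.0]], [1.0, 1.0])
        with pytest.raises(StabilityError):
            interior_equilibrium(m)


class TestJacobian:
    def test_logistic(self):
        J = jacobian(LOGISTIC, np.array([1.0]))
        assert J[0, 0] == pytest.approx(-1.0)

    def test_symmetric_pair_scales_A(self):
        x = np.array([2 / 3, 2 / 3])
        J = jacobian(WEAK, x)
        np.testing.assert_allclose(J, (2 / 3) * WEAK.A, atol=1e-12)
        eig = np.sort(np.linalg.eigvals(J).real)
        np.testing.assert_allclose(eig, [-1.0, -1 / 3], atol=1e-12)

    def test_origin_gives_growth_rates(self):
        J = jacobian(WEAK, np.zeros(2))
        np.testing.assert_allclose(J, np.diag(WEAK.r), atol=1e-12)


class TestDominantEigenvalue:
    def test_scalar(self):
        assert dominant_eigenvalue(np.array([[-1.0]])) == -1.0

    def test_imaginary_pair_is_zero(self):
        assert dominant_eigenvalue(np.array([[0.0, 1.0], [-1.0, 0.0]])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_weak_pair(self):
        J = jacobian(WEAK, np.array([2 / 3, 2 / 3]))
        assert dominant_eigenvalue(J) == pytest.approx(-1 / 3, abs=1e-12)

    def test_diagonal_exact(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=6)
        assert dominant_eigenvalue(np.diag(d)) == pytest.approx(d.max(),
                                                                abs=1e-12)


class TestBoundaryEquilibria:
    def test_one_species_only_origin(self):
        eqs = boundary_equilibria(LOGISTIC)
        assert len(eqs) == 1
        np.testing.assert_array_equal(eqs[0][1], [0.0])

    def test_symmetric_competition_three_points(self):
        eqs = {tuple(np.round(x, 10)) for _, x in boundary_equilibria(WEAK)}
        assert eqs == {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)}

    def test_negative_restricted_solution_excluded(self):
        # prey-dependent predator cannot persist alone: its 1-species
        # "equilibrium" is negative and must not appear
        m = GlvModel([[-1.0, -0.5], [0.5, -1.0]], [1.0, -0.5])
        subsets = {S for S, _ in boundary_equilibria(m)}
        assert (1,) not in subsets  # predator alone: x = -0.5 < 0
        assert (0,) in subsets

    def test_n_max_guard(self):
        m = GlvModel(-np.eye(25), np.ones(25))
        with pytest.raises(StabilityError, match="n_max"):
            boundary_equilibria(m)


class TestPermanence:
    def test_logistic_permanent(self):
        permanent, p = permanence_lp(LOGISTIC)
        assert permanent and p[0] >= 1.0

    def test_weak_competition_certificate(self):
        permanent, p = permanence_lp(WEAK)
        assert permanent
        # p = (1, 1) is itself a valid certificate: at (1,0) the weighted
        # invasion sum is 1 - 0.5 = 0.5 > 0, at the origin it is 2 > 0
        assert verify_certificate(WEAK, np.array([1.0, 1.0]),
                                  boundary_equilibria(WEAK))
        assert verify_certificate(WEAK, p, boundary_equilibria(WEAK))

    def test_strong_competition_not_permanent(self):
        permanent, p = permanence_lp(STRONG)
        assert not permanent and p is None
        # bistability confirmed by simulation: an interior start near a
        # boundary attractor loses one species
        lo = batch_min_abundance(STRONG, np.array([[0.9, 0.02]]), 2000)
        assert lo < 1e-8

    def test_infeasible_interior_not_permanent(self):
        m = GlvModel([[-1.0, 0.0], [0.0, -1.0]], [1.0, -0.5])
        assert permanence_lp(m) == (False, None)

    def test_certificate_reverification_margin(self):
        for seed in range(5):
            model, _ = random_stable_glv(4, seed=seed)
            permanent, p = permanence_lp(model)
            if permanent:
                assert verify_certificate(model, p,
                                          boundary_equilibria(model))


class TestDissipativity:
    def test_negative_diagonal_true(self):
        assert dissipativity_check(WEAK)

    def test_nonnegative_diagonal_false(self):
        m = GlvModel([[0.0, -0.5], [-0.5, -1.0]], [1.0, 1.0])
        assert not dissipativity_check(m)

    def test_mixed_signs_bounded_in_simulation(self):
        model, xs = random_stable_glv(4, seed=77)
        assert dissipativity_check(model)
        rng = np.random.default_rng(0)
        starts = xs * np.exp(rng.normal(0, 1.0, (100, 4)))
        batch_min_abundance(model, starts, 500)  # raises on divergence


class TestInvasibility:
    def test_neutral_invader_not_invasible(self):
        invasible, lam = invasibility_test(WEAK, r_inv=0.0)
        assert not invasible and lam == pytest.approx(0.0, abs=1e-12)

    def test_positive_growth_invades(self):
        invasible, lam = invasibility_test(WEAK, r_inv=0.1)
        assert invasible and lam == pytest.approx(0.1)

    def test_unstable_resident_warns(self):
        m = GlvModel([[-1.0, -2.0], [-2.0, -1.0]], [1.0, 1.0])
        with pytest.warns(UserWarning, match="resident"):
            invasibility_test(m, r_inv=0.0)

    @pytest.mark.parametrize("r_inv", [-0.2, 0.05, 0.3])
    def test_verdict_matches_simulation(self, r_inv):
        # grow the invader from rarity under the augmented model
        model, xs = random_stable_glv(3, seed=19)
        invasible, _ = invasibility_test(model, r_inv=r_inv)
        n = model.n
        A_aug = np.zeros((n + 1, n + 1))
        A_aug[:n, :n] = model.A
        A_aug[n, n] = -1.0  # invader self-limits; irrelevant when rare
        aug = GlvModel(A_aug, np.append(model.r, r_inv))
        x0 = np.append(xs, 1e-4)
        traj = simulate_ricker(aug, x0, 100, extinction_floor=0.0)
        grew = traj[-1, n] > 2 * x0[n]
        assert grew == invasible


class TestAssessStability:
    def test_full_report_consistency(self):
        model, _ = random_stable_glv(4, seed=3)
        rep = assess_stability(model, "P01")
        assert rep.locally_stable == (rep.dominant_eigenvalue < -1e-9)
        if rep.permanent:
            assert rep.lyapunov_certificate is not None
            assert rep.dissipative
            assert verify_certificate(model, rep.lyapunov_certificate,
                                      boundary_equilibria(model))
        doc = rep.to_dict()
        assert doc["participant_id"] == "P01"
        assert isinstance(doc["locally_stable"], bool)

    def test_reports_both_eigenvalue_conventions(self):
        rep = assess_stability(WEAK, "x")
        assert rep.dominant_eigenvalue == pytest.approx(-1 / 3, abs=1e-12)
        assert rep.dominant_eigenvalue_A == pytest.approx(-0.5, abs=1e-12)
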