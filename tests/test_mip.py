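import numpy as np
import pytest

from markerpanel import (
    PanelProblem,
    SolverOptions,
    build_mip,
    solve_mip,
    exhaustive_oracle,
    sweep_parameters,
    specificity_scores,
    difference_tensor,
)
from markerpanel.mip import tight_slack
from conftest import random_instance


def make_problem(seed=0, m=None, n=None, k=2, lambda_=1.0, mu=1.0):
    rng = np.random.default_rng(seed)
    em = random_instance(rng, m=m, n=n)
    zt = difference_tensor(em)
    ss = specificity_scores(em).ss_l
    return em, PanelProblem(zt, ss, k, lambda_, mu)


class TestBuildMip:
    def test_variable_and_constraint_counts(self):
        _, prob = make_problem(m=3, n=4, k=2)
        model = build_mip(prob)
        assert model.n == 4 and model.n_pairs == 3
        assert model.c.shape == (7,)
        assert int(model.integrality.sum()) == 4
        card, pairs = model.constraints
        assert card.A.shape == (1, 7)
        assert pairs.A.shape == (3, 7)

    def test_mu_zero_drops_specificity_from_objective(self):
        _, prob0 = make_problem(m=3, n=5, k=2, mu=0.0)
        model0 = build_mip(prob0)
        zp = prob0.zt.pair_matrix()
        np.testing.assert_allclose(model0.c[:5], -zp.sum(axis=0))

    def test_k_exceeding_n_rejected(self):
        rng = np.random.default_rng(0)
        em = random_instance(rng, m=3, n=4)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        with pytest.raises(ValueError):
            PanelProblem(zt, ss, k=5)


class TestSolveMip:
    def test_matches_oracle_on_toy_instance(self):
        _, prob = make_problem(seed=3, m=3, n=5, k=2, lambda_=1.0, mu=1.0)
        a, b = solve_mip(prob), exhaustive_oracle(prob)
        assert a.status == "optimal"
        assert a.objective == pytest.approx(b.objective, abs=1e-6)
        assert set(a.selected) == set(b.selected)

    def test_full_panel_reduces_to_specificity_term(self):
        em, _ = make_problem(seed=1, m=4, n=6)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        for mu in (0.0, 10.0):
            sol = solve_mip(PanelProblem(zt, ss, k=em.n, lambda_=1.0, mu=mu))
            assert np.all(sol.w == 1.0)
            np.testing.assert_allclose(sol.xi, 0.0, atol=1e-12)
            assert sol.objective == pytest.approx(-mu * ss.sum(), abs=1e-8)

    def test_k1_no_penalties_selects_largest_pair_sum(self):
        em, _ = make_problem(seed=5, m=4, n=8)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        sol = solve_mip(PanelProblem(zt, ss, k=1, lambda_=0.0, mu=0.0))
        expected = int(np.argmax(zt.pair_matrix().sum(axis=0)))
        assert list(sol.selected) == [expected]

    def test_objective_decomposition(self):
        _, prob = make_problem(seed=7, k=3, lambda_=10.0, mu=5.0)
        sol = solve_mip(prob)
        zp = prob.zt.pair_matrix()
        D = zp.sum()
        d = zp @ sol.w
        recomputed = (D - d.sum() + prob.lambda_ * sol.xi.sum()
                      - prob.mu * sol.w @ prob.ss_l)
        assert sol.objective == pytest.approx(recomputed, abs=1e-8)

    def test_slack_is_tight_at_optimum(self):
        _, prob = make_problem(seed=11, k=2, lambda_=100.0, mu=0.0)
        sol = solve_mip(prob)
        np.testing.assert_allclose(sol.xi, tight_slack(prob, sol.w), atol=1e-8)

    def test_relaxation_never_beats_binary_downward(self):
        for seed in range(5):
            _, prob = make_problem(seed=seed, k=2, lambda_=10.0, mu=1.0)
            rel = solve_mip(prob, relax=True)
            full = solve_mip(prob)
            assert rel.objective <= full.objective + 1e-8

    def test_zero_penalty_full_panel_objective_is_zero(self):
        em, _ = make_problem(seed=2)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        sol = solve_mip(PanelProblem(zt, ss, k=em.n, lambda_=0.0, mu=0.0))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)


class TestExhaustiveOracle:
    def test_forced_single_gene(self):
        rng = np.random.default_rng(0)
        em = random_instance(rng, m=3, n=6)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        # oracle over k=1 equals explicit enumeration of singletons
        prob = PanelProblem(zt, ss, k=1, lambda_=2.0, mu=3.0)
        sol = exhaustive_oracle(prob)
        objs = []
        zp = zt.pair_matrix()
        target = zp.sum(axis=1) / zt.n
        for l in range(zt.n):
            d = zp[:, l]
            xi = np.maximum(0.0, target - d)
            objs.append(zp.sum() - d.sum() + 2.0 * xi.sum() - 3.0 * ss[l])
        assert sol.objective == pytest.approx(min(objs), abs=1e-10)

    def test_instance_size_guard(self):
        _, prob = make_problem(m=3, n=10, k=5)
        with pytest.raises(ValueError):
            exhaustive_oracle(prob, max_subsets=10)

    def test_tie_break_is_lexicographic(self):
        # duplicate genes -> equally optimal panels; smallest indices win
        from markerpanel import ExpressionMatrix

        S = np.array([[50.0, 50.0, 50.0, 5.0], [5.0, 5.0, 5.0, 50.0]])
        em = ExpressionMatrix(("a", "b"), ("g0", "g1", "g2", "g3"), S)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        prob = PanelProblem(zt, ss, k=1, lambda_=1.0, mu=1.0)
        a, b = solve_mip(prob), exhaustive_oracle(prob)
        assert list(a.selected) == list(b.selected) == [0]


class TestSweep:
    def test_grid_size_and_columns(self):
        em, _ = make_problem(seed=9, m=3, n=6)
        zt = difference_tensor(em)
        ss = specificity_scores(em).ss_l
        table = sweep_parameters(zt, ss, [2], [1.0], [0.0, 1.0],
                                 gene_ids=em.gene_ids)
        assert len(table) == 2
        assert {"k", "lambda", "mu", "panel", "objective", "C1", "C2", "C3"} <= set(table.columns)
        assert (table["status"] == "optimal").all()
        assert table["panel"].str.split(",").str.len().eq(2).all()
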