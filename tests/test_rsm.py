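import numpy as np
import pytest

from emulgelopt import datasets
from emulgelopt.design import EMULGEL_FACTOR_SPACE
from emulgelopt.rsm import (
    ModelSpec,
    diagnostics,
    family_terms,
    fit,
    prune_terms,
    recode,
    select_model,
)
from emulgelopt._poly import evaluate

SPACE = EMULGEL_FACTOR_SPACE
RNG = np.random.default_rng(20240613)


def _orthogonal_solve(design, y):
    """Independent closed-form OLS for the balanced 9-run design: the
    coded columns 1, A, B are mutually orthogonal, so each coefficient is
    a simple contrast ratio."""
    M = design.coded_matrix
    yv = np.array([y[r.run_id] for r in design.runs], dtype=float)
    b0 = yv.mean()
    bA = float(M[:, 0] @ yv / (M[:, 0] @ M[:, 0]))
    bB = float(M[:, 1] @ yv / (M[:, 1] @ M[:, 1]))
    return b0, bA, bB


class TestFit:
    def test_mean_level_d50_fit_matches_contrast_oracle(self, ref_design, d50_means):
        m = fit(ref_design, d50_means, ModelSpec.from_family("d50", "linear"))
        b0, bA, bB = _orthogonal_solve(ref_design, d50_means)
        assert m.coef_coded[(0, 0)] == pytest.approx(b0, abs=1e-12)
        assert m.coef_coded[(1, 0)] == pytest.approx(bA, abs=1e-12)
        assert m.coef_coded[(0, 1)] == pytest.approx(bB, abs=1e-12)
        # frozen values from the contrast oracle
        assert m.coef_coded[(0, 0)] == pytest.approx(0.38389, abs=1e-4)
        assert m.coef_coded[(1, 0)] == pytest.approx(-0.0370, abs=1e-10)
        assert m.coef_coded[(0, 1)] == pytest.approx(-0.08933, abs=1e-4)

    def test_noiseless_quadratic_interpolation(self, ref_design):
        truth = {(0, 0): 2.0, (1, 0): -1.5, (0, 1): 0.7, (1, 1): 0.3, (2, 0): -0.4, (0, 2): 1.1}
        y = {r.run_id: float(evaluate(truth, list(r.coded))) for r in ref_design}
        m = fit(ref_design, y, ModelSpec.from_family("r", "quadratic"))
        for t, c in truth.items():
            assert m.coef_coded[t] == pytest.approx(c, abs=1e-9)

    def test_constant_response(self, ref_design):
        y = {r.run_id: 3.25 for r in ref_design}
        m = fit(ref_design, y, ModelSpec.from_family("r", "linear"))
        assert m.coef_coded[(0, 0)] == pytest.approx(3.25)
        assert m.coef_coded[(1, 0)] == pytest.approx(0.0, abs=1e-12)

    def test_replicates_enter_as_rows(self, ref_design):
        y = {r.run_id: [1.0, 2.0, 3.0] for r in ref_design}
        m = fit(ref_design, y, ModelSpec.from_family("r", "linear"))
        assert m.n_obs == 27
        assert m.coef_coded[(0, 0)] == pytest.approx(2.0)

    def test_rank_deficiency_names_terms(self, ref_design):
        # duplicated main-effect column
        spec = ModelSpec("r", ((0, 0), (1, 0), (1, 0)))
        with pytest.raises(ValueError, match="collinear"):
            fit(ref_design, {r.run_id: 1.0 for r in ref_design}, spec)

    def test_orthogonality_linear_coefs_stable_under_interaction(self, ref_design):
        y = {r.run_id: float(RNG.standard_normal()) for r in ref_design}
        m_lin = fit(ref_design, y, ModelSpec.from_family("r", "linear"))
        m_2fi = fit(ref_design, y, ModelSpec.from_family("r", "2FI"))
        for t in ((1, 0), (0, 1)):
            assert m_lin.coef_coded[t] == pytest.approx(m_2fi.coef_coded[t], abs=1e-12)


class TestRecode:
    def test_coded_to_actual_hand_example(self):
        coded = {(0, 0): 0.38, (1, 0): -0.03, (0, 1): -0.09}
        actual = recode(coded, SPACE, "coded_to_actual")
        assert actual[(0, 0)] == pytest.approx(0.515)
        assert actual[(1, 0)] == pytest.approx(-0.0015)
        assert actual[(0, 1)] == pytest.approx(-0.018)

    def test_reference_ph_equation_center_value(self):
        val = evaluate(datasets.ACTUAL_MODELS["ph"], [30.0, 5.0])
        assert round(val, 2) == 9.04

    def test_recode_round_trip_identity(self):
        for _ in range(20):
            coefs = {t: float(RNG.standard_normal()) for t in family_terms("quadratic")}
            back = recode(recode(coefs, SPACE, "coded_to_actual"), SPACE, "actual_to_coded")
            for t, c in coefs.items():
                assert back[t] == pytest.approx(c, abs=1e-9)

    def test_coded_and_actual_forms_agree_at_random_points(self, ref_design, d50_means):
        m = fit(ref_design, d50_means, ModelSpec.from_family("d50", "linear"))
        pts = np.column_stack([RNG.uniform(10, 50, 1000), RNG.uniform(0, 10, 1000)])
        coded_pts = np.column_stack([SPACE.to_coded(pts[:, 0], "mineral_oil"),
                                     SPACE.to_coded(pts[:, 1], "polysorbate_80")])
        ya = m.predict_actual(pts)
        yc = m.predict_coded(coded_pts)
        assert np.allclose(ya, yc, atol=1e-9)


class TestDiagnostics:
    def test_d50_mean_level_diagnostics(self, ref_design, d50_means):
        m = fit(ref_design, d50_means, ModelSpec.from_family("d50", "linear"))
        d = diagnostics(m)
        assert d.adj_r2 == pytest.approx(0.971, abs=0.001)
        assert d.adeq_precision == pytest.approx(30.5, abs=0.5)
        assert d.r2 >= d.adj_r2 >= d.pred_r2
        assert d.press > m.sse

    def test_noiseless_linear_data_perfect_r2(self, ref_design):
        y = {r.run_id: 1.0 + 2.0 * r.coded[0] - 0.5 * r.coded[1] for r in ref_design}
        d = diagnostics(fit(ref_design, y, ModelSpec.from_family("r", "linear")))
        assert d.r2 == pytest.approx(1.0, abs=1e-12)
        assert d.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert d.pred_r2 == pytest.approx(1.0, abs=1e-9)

    def test_press_equals_explicit_leave_one_out(self, ref_design):
        y = {r.run_id: float(RNG.standard_normal()) for r in ref_design}
        spec = ModelSpec.from_family("r", "linear")
        m = fit(ref_design, y, spec)
        d = diagnostics(m)
        press_loo = 0.0
        from emulgelopt._poly import design_matrix

        X = design_matrix(spec.terms, ref_design.coded_matrix)
        yv = np.array([y[r.run_id] for r in ref_design.runs])
        for i in range(len(yv)):
            keep = np.arange(len(yv)) != i
            beta = np.linalg.lstsq(X[keep], yv[keep], rcond=None)[0]
            press_loo += (yv[i] - X[i] @ beta) ** 2
        assert d.press == pytest.approx(press_loo, abs=1e-10)

    def test_pvalues_within_unit_interval(self, ref_design, d50_means):
        d = diagnostics(fit(ref_design, d50_means, ModelSpec.from_family("d50", "quadratic")))
        assert 0 <= d.model_p_value <= 1
        assert all(0 <= p <= 1 for p in d.term_p_values.values())

    def test_interpolated_points_make_press_undefined(self):
        # three distinct points, one replicated: the two singleton points
        # are fitted exactly (leverage 1), so leave-one-out is undefined
        from emulgelopt.design import DesignRun, DesignTable, FactorSpace

        space = FactorSpace(("a", "b"), (-1.0, -1.0), (1.0, 1.0))
        runs = tuple(
            DesignRun(rid, coded, coded)
            for rid, coded in [("r1", (-1.0, 0.0)), ("r2", (1.0, 0.0)), ("r3", (0.0, 1.0))]
        )
        table = DesignTable(space, runs)
        y = {"r1": [0.1, 0.2], "r2": 0.5, "r3": -0.3}
        m = fit(table, y, ModelSpec.from_family("r", "linear"))
        with pytest.raises(ValueError, match="PRESS undefined"):
            diagnostics(m)

    def test_too_few_observations_rejected(self, ref_design):
        terms = ((0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (2, 2))
        y = {r.run_id: float(RNG.standard_normal()) for r in ref_design}
        with pytest.raises(ValueError, match="p\\+1"):
            fit(ref_design, y, ModelSpec("r", terms))


class TestPruneAndSelect:
    def test_interaction_pruned_parents_kept(self, ref_design):
        truth = {(0, 0): 5.0, (1, 0): 0.0, (0, 1): 0.0, (1, 1): 0.0, (2, 0): 2.0, (0, 2): 2.0}
        rng = np.random.default_rng(5)
        y = {r.run_id: [float(evaluate(truth, list(r.coded)) + 0.01 * rng.standard_normal())
                        for _ in range(3)] for r in ref_design}
        m = fit(ref_design, y, ModelSpec.from_family("r", "quadratic"))
        pruned = prune_terms(m)
        assert (1, 1) not in pruned.terms          # AB insignificant, removable
        assert (2, 0) in pruned.terms and (0, 2) in pruned.terms
        assert (1, 0) in pruned.terms and (0, 1) in pruned.terms  # hierarchy

    def test_all_significant_spec_unchanged(self, ref_design):
        truth = {(0, 0): 1.0, (1, 0): 2.0, (0, 1): -3.0}
        rng = np.random.default_rng(6)
        y = {r.run_id: [float(evaluate(truth, list(r.coded)) + 0.01 * rng.standard_normal())
                        for _ in range(3)] for r in ref_design}
        m = fit(ref_design, y, ModelSpec.from_family("r", "linear"))
        assert prune_terms(m).terms == m.spec.terms

    def test_backward_elimination_on_single_factor_truth(self, ref_design):
        # truth Y = 2 + 3A: the true effect must always survive, and any
        # spurious term that survives must itself pass the 0.10 threshold
        # in the final refit.  Null-term p-values are uniform regardless
        # of the noise scale, so a spurious term survives a 4-term purge
        # with non-negligible probability; the bulk of simulations must
        # still collapse to the pure single-factor form.
        exact = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(100 + s)
            y = {r.run_id: [2.0 + 3.0 * r.coded[0] + 0.01 * float(rng.standard_normal())
                            for _ in range(3)] for r in ref_design}
            m = fit(ref_design, y, ModelSpec.from_family("r", "quadratic"))
            pruned = prune_terms(m)
            assert (0, 0) in pruned.terms and (1, 0) in pruned.terms
            final = fit(ref_design, y, pruned)
            pvals = diagnostics(final).term_p_values
            removable = _strict_removable(pruned.terms, pvals)
            assert not removable  # nothing left above the threshold
            exact += set(pruned.terms) == {(0, 0), (1, 0)}
        assert exact / n_sim > 0.5


def _strict_removable(terms, pvals, threshold=0.10):
    from emulgelopt.rsm import _removable

    return _removable(terms, pvals, threshold)

    def test_selection_reference_families(self, ref_design):
        from emulgelopt.simulate import GeneratorConfig, simulate_responses
        from emulgelopt.io_utils import response_series

        resp = simulate_responses(ref_design, GeneratorConfig(seed=3))
        for name, family in (("d50", "linear"), ("t_sol_gel", "quadratic")):
            sel = select_model(ref_design, response_series(resp, name), response_name=name)
            assert sel.spec.family == family

    def test_pure_noise_flagged(self, ref_design):
        rng = np.random.default_rng(9)
        y = {r.run_id: [float(rng.standard_normal()) for _ in range(3)] for r in ref_design}
        sel = select_model(ref_design, y)
        assert not sel.validated
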