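import numpy as np
import pytest
from hypothesis import given, strategies as st

from emulgelopt import datasets
from emulgelopt.design import EMULGEL_FACTOR_SPACE
from emulgelopt.desirability import (
    Criterion,
    composite,
    desirability,
    observed_bounds,
    optimize,
)

SPACE = EMULGEL_FACTOR_SPACE


class TestDesirability:
    @pytest.mark.parametrize("w", [0.5, 1.0, 3.0])
    def test_ramp_endpoints(self, w):
        c = Criterion("y", "maximize", 1.0, 3.0, weight=w)
        assert desirability(3.0, c) == 1.0
        assert desirability(1.0, c) == 0.0
        assert desirability(5.0, c) == 1.0  # clipped beyond U

    def test_linear_ramp_midpoint(self):
        c = Criterion("y", "maximize", 1.0, 3.0)
        assert desirability(2.0, c) == pytest.approx(0.5)
        cmin = Criterion("y", "minimize", 1.0, 3.0)
        assert desirability(2.0, cmin) == pytest.approx(0.5)

    def test_target_goal_peaks_at_target(self):
        c = Criterion("y", "target", 0.0, 10.0, target=4.0)
        assert desirability(4.0, c) == 1.0
        assert desirability(2.0, c) == pytest.approx(0.5)
        assert desirability(7.0, c) == pytest.approx(0.5)
        assert desirability(0.0, c) == 0.0

    def test_in_range_indicator(self):
        c = Criterion("y", "in_range", 1.0, 2.0)
        assert desirability(1.5, c) == 1.0
        assert desirability(2.5, c) == 0.0

    @given(st.tuples(st.floats(-5, 5), st.floats(-5, 5)).map(sorted))
    def test_monotonicity(self, pair):
        lo_y, hi_y = pair
        c = Criterion("y", "maximize", 0.0, 1.0)
        assert desirability(lo_y, c) <= desirability(hi_y, c)
        cmin = Criterion("y", "minimize", 0.0, 1.0)
        assert desirability(lo_y, cmin) >= desirability(hi_y, cmin)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = float(rng.uniform(-2, 2))
            a, b = float(rng.uniform(0.1, 5)), float(rng.uniform(-10, 10))
            c = Criterion("y", "maximize", -1.0, 1.5, weight=2.0)
            c_scaled = Criterion("y", "maximize", a * -1.0 + b, a * 1.5 + b, weight=2.0)
            assert desirability(y, c) == pytest.approx(
                desirability(a * y + b, c_scaled), abs=1e-12
            )

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="strictly below"):
            Criterion("y", "maximize", 2.0, 2.0)


class TestComposite:
    def test_geometric_mean_examples(self):
        assert composite([0.25, 1.0]) == pytest.approx(0.5)
        assert composite([0.4, 0.5, 0.9]) == pytest.approx((0.4 * 0.5 * 0.9) ** (1 / 3))
        assert composite([0.3, 0.0, 0.9]) == 0.0

    def test_importance_weighting(self):
        # importance 2 vs 1: D = (d1^2 d2)^(1/3)
        assert composite([0.5, 1.0], [2.0, 1.0]) == pytest.approx(0.25 ** (1 / 3))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite([1.2, 0.5])


class TestOptimize:
    def _reference_setup(self):
        models = {k: datasets.ACTUAL_MODELS[k] for k in ("flux", "t_sol_gel", "d50")}
        pts = np.array([[r, p] for r, p in
                        [(30, 0), (10, 0), (10, 5), (30, 10), (50, 10),
                         (10, 10), (50, 5), (50, 0), (30, 5)]], dtype=float)
        criteria = []
        for resp, goal in (("flux", "maximize"), ("t_sol_gel", "minimize"), ("d50", "minimize")):
            lo, hi = observed_bounds(models[resp], pts)
            criteria.append(Criterion(resp, goal, lo, hi))
        return models, criteria

    def test_monotone_single_criterion_hits_boundary(self):
        model = {(0, 0): 1.0, (1, 0): 0.1}  # increasing in oil only
        c = Criterion("y", "maximize", 2.0, 6.0)
        res = optimize({"y": model}, [c], SPACE, seed=1, grid_resolution=0.5)
        assert res.factor_values[0] == pytest.approx(50.0, abs=1e-6)

    def test_concave_quadratic_matches_stationary_point(self):
        model = {(0, 0): 0.0, (1, 0): 2 * 37.0, (0, 1): 2 * 4.0,
                 (2, 0): -1.0, (0, 2): -1.0}  # peak at (37, 4)
        c = Criterion("y", "maximize", 0.0, 37.0**2 + 4.0**2)
        res = optimize({"y": model}, [c], SPACE, seed=2, grid_resolution=0.5)
        assert res.factor_values[0] == pytest.approx(37.0, rel=1e-4)
        assert res.factor_values[1] == pytest.approx(4.0, rel=1e-4)

    def test_incompatible_criteria_flagged_degenerate(self):
        # non-overlapping ramps on the same response: wanting it above 4
        # and below 4 at once leaves no point with positive desirability
        model = {(0, 0): 1.0, (1, 0): 0.1}
        crits = [Criterion("a", "maximize", 4.0, 6.0), Criterion("b", "minimize", 2.0, 4.0)]
        res = optimize({"a": model, "b": model}, crits, SPACE, seed=3, grid_resolution=0.5)
        assert res.composite_desirability == pytest.approx(0.0, abs=1e-12)
        assert res.degenerate
        # tie broken toward the design center
        assert res.factor_values == pytest.approx(SPACE.center)

    def test_missing_model_reported(self):
        with pytest.raises(ValueError, match="flux"):
            optimize({}, [Criterion("flux", "maximize", 0.0, 1.0)], SPACE, seed=0)

    def test_composite_consistency_and_refinement_agreement(self):
        models, criteria = self._reference_setup()
        res = optimize(models, criteria, SPACE, seed=7)
        d = np.array(list(res.individual_desirabilities.values()))
        assert res.composite_desirability == pytest.approx(composite(d), abs=1e-9)
        grid_D = res.trace[0]["D"]
        assert res.composite_desirability - grid_D <= 1e-4
        assert res.composite_desirability >= grid_D - 1e-12

    def test_reference_models_optimum_region(self):
        models, criteria = self._reference_setup()
        res = optimize(models, criteria, SPACE, seed=11, grid_resolution=0.05)
        oil, pol = res.factor_values
        assert abs(oil - datasets.OPTIMUM["mineral_oil"]) < 3.0
        assert abs(pol - datasets.OPTIMUM["polysorbate_80"]) < 3.0
        assert res.composite_desirability == pytest.approx(
            datasets.OPTIMUM["desirability"], abs=0.10
        )
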