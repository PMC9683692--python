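"""Sensitivity, importance, collinearity, and the reduction loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cvcalib.identifiability import (GAMMA_CAP, ReductionConfig,
                                     collinearity, collinearity_matrix,
                                     parameter_importance,
                                     reduce_parameters, sensitivity_matrix)
from cvcalib.measurements import Measurement, MeasurementSet
from cvcalib.parameters import Parameter, ParameterSet


class TestImportance:
    def test_zero_column_zero_importance(self):
        S = np.zeros((4, 2))
        S[:, 1] = 1.0
        d = parameter_importance(S)
        assert d[0] == 0.0

    def test_constant_column_importance_is_magnitude(self):
        S = np.full((5, 1), -2.5)
        assert parameter_importance(S)[0] == pytest.approx(2.5)

    def test_matches_bruteforce_column_rms(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(4, 3))
        expect = [math.sqrt(np.mean(S[:, j] ** 2)) for j in range(3)]
        np.testing.assert_allclose(parameter_importance(S), expect)

    def test_invariant_under_row_reordering(self):
        rng = np.random.default_rng(4)
        S = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        np.testing.assert_allclose(parameter_importance(S),
                                   parameter_importance(S[perm]))


class TestCollinearity:
    def test_orthogonal_columns_gamma_one(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        d = parameter_importance(S)
        assert collinearity(S, d, 0, 1) == pytest.approx(1.0)

    def test_proportional_columns_capped(self):
        S = np.array([[1.0, 2.0], [2.0, 4.0], [-1.0, -2.0]])
        d = parameter_importance(S)
        assert collinearity(S, d, 0, 1) == GAMMA_CAP

    def test_cosine_099_hits_default_threshold(self):
        """|cos| = 0.99 gives gamma = 10 exactly, the default t_c (from
        eigen-decomposition of [[1, .99], [.99, 1]] whose smallest
        eigenvalue is 0.01)."""
        c = 0.99
        u = np.array([1.0, 0.0])
        v = np.array([c, math.sqrt(1 - c * c)])
        S = np.stack([u, v], axis=1)
        d = parameter_importance(S)
        mu_min = np.linalg.eigvalsh(np.array([[1.0, c], [c, 1.0]]))[0]
        assert collinearity(S, d, 0, 1) == pytest.approx(1 / math.sqrt(mu_min))
        assert collinearity(S, d, 0, 1) == pytest.approx(10.0)
        assert ReductionConfig().t_c == 10.0

    @given(arrays(np.float64, (5, 3),
                  elements=st.floats(-10, 10, allow_nan=False)))
    @settings(max_examples=80, deadline=None)
    def test_eigen_path_equals_closed_form(self, S):
        """gamma via the 2x2 eigenvalue path equals 1/sqrt(1-|cos|) of the
        column angle, to 1e-10 relative."""
        d = parameter_importance(S)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            if d[i] <= 1e-12 or d[j] <= 1e-12:
                continue
            g = collinearity(S, d, i, j)
            cosang = abs(S[:, i] @ S[:, j]) / (
                np.linalg.norm(S[:, i]) * np.linalg.norm(S[:, j]))
            if cosang >= 1.0 - 1e-12:
                assert g > 1e5
            else:
                closed = 1.0 / math.sqrt(1.0 - cosang)
                assert g == pytest.approx(closed, rel=1e-10)
            assert g >= 1.0 - 1e-12

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(5)
        S = rng.normal(size=(6, 4))
        d = parameter_importance(S)
        g = collinearity_matrix(S, d)
        np.testing.assert_allclose(g, g.T)
        np.testing.assert_allclose(np.diag(g), 1.0)
        assert np.all(g[np.isfinite(g)] >= 1.0 - 1e-12)

    def test_zero_importance_pair_not_applicable(self):
        S = np.zeros((3, 2))
        S[:, 1] = 1.0
        d = parameter_importance(S)
        assert math.isnan(collinearity(S, d, 0, 1))


# ---------------------------------------------------------------------------
# finite-difference sensitivities on analytic toy models
# ---------------------------------------------------------------------------

def _toy_params(values, bounds=(1e-6, 100.0)):
    return ParameterSet([
        Parameter(f"t{i}", "1", v, bounds[0], bounds[1], "free")
        for i, v in enumerate(values)
    ])


def _toy_data(entries):
    return MeasurementSet([Measurement(n, v, sigma=s) for n, v, s in entries])


class TestSensitivityMatrix:
    def test_linear_model_exact(self):
        """First-order forward differences are exact on a linear map:
        S_kl = a_k theta_l / sigma_k."""
        a = np.array([2.0, -1.5])
        params = _toy_params([3.0])
        data = _toy_data([("y0", 6.0, 0.5), ("y1", -4.5, 2.0)])

        def forward(ps):
            th = ps.value("t0")
            return {"y0": a[0] * th, "y1": a[1] * th}

        res = sensitivity_matrix(params, data, ReductionConfig(),
                                 forward=forward)
        expect = a * 3.0 / np.array([0.5, 2.0])
        np.testing.assert_allclose(res.S[:, 0], expect, rtol=1e-9)

    def test_doubling_sigma_halves_its_row_only(self):
        params = _toy_params([2.0, 5.0])

        def forward(ps):
            t0, t1 = ps.value("t0"), ps.value("t1")
            return {"y0": t0 * t1, "y1": t0 + t1 ** 2}

        d1 = _toy_data([("y0", 10.0, 1.0), ("y1", 27.0, 1.0)])
        d2 = _toy_data([("y0", 10.0, 2.0), ("y1", 27.0, 1.0)])
        s1 = sensitivity_matrix(params, d1, ReductionConfig(), forward=forward)
        s2 = sensitivity_matrix(params, d2, ReductionConfig(), forward=forward)
        np.testing.assert_allclose(s2.S[0], s1.S[0] / 2.0, rtol=1e-12)
        np.testing.assert_allclose(s2.S[1], s1.S[1], rtol=1e-12)

    def test_quadratic_fd_error_first_order(self):
        """On f = theta^2 the forward-difference estimate approaches the
        analytic 2 theta*^2 / sigma at O(h)."""
        params = _toy_params([1.7])
        data = _toy_data([("y", 1.7 ** 2, 1.0)])

        def forward(ps):
            return {"y": ps.value("t0") ** 2}

        analytic = 2 * 1.7 * 1.7 / 1.0
        errs = []
        for h in (1e-2, 1e-3):
            res = sensitivity_matrix(params, data,
                                     ReductionConfig(fd_rel_step=h),
                                     forward=forward)
            errs.append(abs(res.S[0, 0] - analytic))
        assert errs[1] < errs[0]
        assert errs[1] / errs[0] == pytest.approx(0.1, rel=0.3)

    def test_sigma_scaling_scales_importance(self):
        rng = np.random.default_rng(0)
        params = _toy_params([1.0, 2.0, 0.5])
        a = rng.normal(size=(4, 3))

        def forward(ps):
            th = ps.free_values
            y = a @ th
            return {f"y{k}": y[k] for k in range(4)}

        d1 = _toy_data([(f"y{k}", 0.0, 1.0) for k in range(4)])
        d2 = _toy_data([(f"y{k}", 0.0, 3.0) for k in range(4)])
        s1 = sensitivity_matrix(params, d1, ReductionConfig(), forward=forward)
        s2 = sensitivity_matrix(params, d2, ReductionConfig(), forward=forward)
        np.testing.assert_allclose(s2.delta, s1.delta / 3.0, rtol=1e-9)

    def test_zero_parameter_rejected(self):
        params = _toy_params([1.0])
        data = _toy_data([("y", 1.0, 1.0)])
        bad = ParameterSet([Parameter("t0", "1", 0.0, 0.0, 1.0, "free")])
        with pytest.raises(ValueError, match="zero-valued"):
            sensitivity_matrix(bad, data, ReductionConfig(),
                               forward=lambda ps: {"y": 1.0})


class TestPredictionSensitivities:
    def test_inert_parameter_has_zero_prediction_importance(self):
        from cvcalib.identifiability import prediction_sensitivities

        params = _toy_params([2.0, 3.0])

        def forward(ps):
            return {"pred": ps.value("t0") ** 2}  # t1 has no effect

        res = prediction_sensitivities(params, ReductionConfig(),
                                       forward=forward,
                                       prediction_names=["pred"])
        assert res.delta[1] == 0.0
        assert res.delta[0] > 0.0

    def test_shapes_follow_free_parameter_count(self, params, sim_cfg):
        """delta_p has length n_theta and gamma_p is n_theta x n_theta
        regardless of how many data observables exist; on the packaged
        model the middle cerebral terminal resistance visibly shapes its
        own bed's pressure (delta_p > 0)."""
        from cvcalib.identifiability import prediction_sensitivities

        res = prediction_sensitivities(params, ReductionConfig(),
                                       sim_config=sim_cfg)
        n = len(params.free_names)
        assert res.delta.shape == (n,)
        assert res.gamma.shape == (n, n)
        i_mc = params.free_names.index("R_MC_T")
        assert res.delta[i_mc] > 0.0


# ---------------------------------------------------------------------------
# the reduction loop on toy models (exact Jacobian oracles)
# ---------------------------------------------------------------------------

def _nelder_optimizer(objective, bounds):
    """Cheap deterministic optimizer for toy reductions."""
    from scipy.optimize import minimize

    x0 = bounds.mean(axis=1)
    res = minimize(objective, x0, method="Nelder-Mead",
                   bounds=[tuple(b) for b in bounds])

    class R:
        theta_star = np.clip(res.x, bounds[:, 0], bounds[:, 1])
        best_cost = float(res.fun)

    return R


class TestReduceToyModels:
    def test_product_model_fixes_exactly_one(self):
        """f = theta1 * theta2 with one output is fully collinear: the
        loop fixes exactly one of the pair and keeps the other."""
        params = _toy_params([2.0, 3.0], bounds=(0.5, 10.0))
        data = _toy_data([("y", 6.0, 0.5)])

        def forward(ps):
            return {"y": ps.value("t0") * ps.value("t1")}

        rep = reduce_parameters(params, data, ReductionConfig(),
                                _nelder_optimizer, forward=forward,
                                prediction_names=[])
        assert len(rep.final_fixed) == 1
        assert len(rep.final_free) == 1
        assert rep.iterations[0]["reason"].startswith("collinear-with")

    def test_inert_parameter_fixed_by_importance(self):
        """A parameter absent from the outputs has delta = 0 < t_i and is
        fixed by the importance rule."""
        params = _toy_params([2.0, 3.0, 1.0], bounds=(0.5, 10.0))
        data = _toy_data([("y0", 2.0, 0.1), ("y1", 9.0, 0.1)])

        def forward(ps):
            return {"y0": ps.value("t0"), "y1": ps.value("t1") ** 2}

        rep = reduce_parameters(params, data, ReductionConfig(),
                                _nelder_optimizer, forward=forward,
                                prediction_names=[])
        assert "t2" in rep.final_fixed
        reasons = [it["reason"] for it in rep.iterations if it["fixed"] == "t2"]
        assert reasons and reasons[0].startswith("low-importance")
        assert set(rep.final_free) == {"t0", "t1"}

    def test_matches_jacobian_rank_deficiency(self):
        """On a linear-Gaussian model with a rank-deficient Jacobian the
        fixed parameters span the null directions found by SVD of the
        exact Jacobian (oracle)."""
        # outputs depend on t0 + t1 (collinear pair) and on t2
        A = np.array([[1.0, 1.0, 0.0],
                      [2.0, 2.0, 0.0],
                      [0.0, 0.0, 1.0]])
        theta_true = np.array([1.0, 1.0, 2.0])
        y = A @ theta_true
        params = _toy_params(list(theta_true), bounds=(0.2, 5.0))
        data = _toy_data([(f"y{k}", y[k], 0.1) for k in range(3)])

        def forward(ps):
            out = A @ ps.values(["t0", "t1", "t2"])
            return {f"y{k}": out[k] for k in range(3)}

        # oracle: scaled Jacobian has a null direction mixing t0 and t1
        J = A * theta_true / 0.1
        s = np.linalg.svd(J, compute_uv=False)
        assert s[-1] < 1e-10  # rank deficient

        rep = reduce_parameters(params, data, ReductionConfig(),
                                _nelder_optimizer, forward=forward,
                                prediction_names=[])
        assert len(rep.final_fixed) == 1
        assert set(rep.final_fixed) <= {"t0", "t1"}
        assert "t2" in rep.final_free

    def test_termination_bound(self):
        """At most n_theta - 1 iterations can fix a parameter each."""
        params = _toy_params([1.0, 1.0, 1.0, 1.0], bounds=(0.5, 2.0))
        data = _toy_data([("y", 1.0, 0.1)])

        def forward(ps):
            return {"y": float(np.prod(ps.free_values))}

        rep = reduce_parameters(params, data, ReductionConfig(),
                                _nelder_optimizer, forward=forward,
                                prediction_names=[])
        n_fixing = sum(it["fixed"] is not None for it in rep.iterations)
        assert n_fixing <= 3
        assert len(rep.final_free) >= 1

    def test_too_few_free_parameters_rejected(self):
        params = _toy_params([1.0])
        data = _toy_data([("y", 1.0, 1.0)])
        with pytest.raises(ValueError, match="at least 2"):
            reduce_parameters(params, data, ReductionConfig(),
                              _nelder_optimizer,
                              forward=lambda ps: {"y": 1.0},
                              prediction_names=[])

    def test_report_roundtrip(self, tmp_path):
        params = _toy_params([2.0, 3.0], bounds=(0.5, 10.0))
        data = _toy_data([("y", 6.0, 0.5)])

        def forward(ps):
            return {"y": ps.value("t0") * ps.value("t1")}

        rep = reduce_parameters(params, data, ReductionConfig(),
                                _nelder_optimizer, forward=forward,
                                prediction_names=[])
        path = tmp_path / "report.json"
        rep.to_json(path)
        from cvcalib.identifiability import ReductionReport

        back = ReductionReport.from_json(path)
        assert back.final_free == rep.final_free
        assert back.final_fixed == rep.final_fixed
        assert back.converged == rep.converged
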