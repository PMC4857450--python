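"""Mixed-model engine tests against dense linear-algebra oracles."""

import numpy as np
import pandas as pd
import pytest

from uniformvar.lmm import (
    EstimabilityError, GeneticTerm, IndependentTerm, MixedModelSpec,
    StackedData, compute_leverages, estimate_reml, solve_blup,
)
from uniformvar.lmm import _Workspace, _theta_from_components
from uniformvar.pedigree import RelationshipMatrix


def _halfsib_A(q: int) -> RelationshipMatrix:
    A = np.eye(q)
    for i in range(0, q - 1, 2):
        A[i, i + 1] = A[i + 1, i] = 0.25
    return RelationshipMatrix(ids=[f"s{i}" for i in range(q)], A=A)


def _random_fixture(seed: int, n: int = 50, q: int = 8, n_hen: int = 6):
    rng = np.random.default_rng(seed)
    resp = rng.integers(0, 2, n)
    spec = MixedModelSpec(
        responses=["r0", "r1"],
        fixed_terms={"r0": ["fac"], "r1": ["fac"]},
        genetic=GeneticTerm(responses=("r0", "r1")),
        groups=[IndependentTerm("pe", ("r0", "r1"), "hen")],
    )
    data = StackedData(
        y=rng.normal(0, 2, n) + 1.5 * resp,
        response=resp,
        weight=rng.uniform(0.5, 2.0, n),
        factors={"fac": rng.integers(0, 3, n),
                 "sire": rng.integers(0, q, n),
                 "hen": rng.integers(0, n_hen, n)},
    )
    comp = {
        "genetic": np.array([[1.0, 0.3], [0.3, 0.8]]),
        "pe": np.array([[0.5, 0.1], [0.1, 0.4]]),
        "residual": np.array([1.2, 0.9]),
    }
    return spec, data, _halfsib_A(q), comp


def _dense_pieces(spec, data, A, comp):
    """Explicit dense T, V, prior G for the oracle computations."""
    ws = _Workspace(spec, data, A)
    T1 = ws.T1.toarray()
    T2 = ws.T2.toarray() if ws.T2 is not None else np.zeros((ws.n, 0))
    T = np.hstack([T1, T2])
    q = len(A)
    nrand = T.shape[1] - ws.p
    Gf = np.zeros((nrand, nrand))
    Gf[:2 * q, :2 * q] = np.kron(comp["genetic"], A.A)
    for l in range(ws.g2[0]["L"]):
        s = 2 * q + 2 * l
        Gf[s:s + 2, s:s + 2] = comp["pe"]
    Rv = comp["residual"][data.response] / data.weight
    X, Z = T[:, :ws.p], T[:, ws.p:]
    V = Z @ Gf @ Z.T + np.diag(Rv)
    return ws, T, X, Z, Gf, Rv, V


class TestSolveBlup:
    def test_intercept_only_is_weighted_mean(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 2, 30)
        w = rng.uniform(0.5, 2, 30)
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": []})
        data = StackedData(y=y, response=np.zeros(30, np.int64), weight=w,
                           factors={})
        res = solve_blup(spec, data, None, {"residual": np.array([1.0])})
        assert res.solutions["fixed"][0] == pytest.approx(
            np.average(y, weights=w))

    def test_single_record_shrinkage_matches_scalar_formula(self):
        # one record, one random-effect level: u = (Z'R^-1 y)/(Z'R^-1 Z+1/s2)
        s2u, s2e, y0 = 2.0, 1.5, 3.0
        spec = MixedModelSpec(
            responses=["y"], fixed_terms={"y": []},
            genetic=GeneticTerm(responses=("y",)))
        A = RelationshipMatrix(ids=["s0"], A=np.eye(1))
        data = StackedData(y=np.array([y0]), response=np.zeros(1, np.int64),
                           weight=np.ones(1), factors={"sire": np.zeros(1, np.int64)})
        res = solve_blup(spec, data, A,
                         {"genetic": np.array([[s2u]]),
                          "residual": np.array([s2e])})
        # intercept is aliased with the single record; drop it by checking
        # the combined fit reproduces y with the scalar shrinkage structure
        u = res.solutions["genetic"][0, 0]
        b = res.solutions["fixed"][0]
        expect_u = (1 / s2e) * (y0 - b) / (1 / s2e + 1 / s2u)
        assert u == pytest.approx(expect_u, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_gls_oracle(self, seed):
        spec, data, A, comp = _random_fixture(seed)
        res = solve_blup(spec, data, A, comp)
        ws, T, X, Z, Gf, Rv, V = _dense_pieces(spec, data, A, comp)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data.y)
        u = Gf @ Z.T @ Vi @ (data.y - X @ b)
        np.testing.assert_allclose(res.solutions["fixed"], b, atol=1e-8)
        got_u = np.concatenate([res.solutions["genetic"].ravel(),
                                res.solutions["pe"].ravel()])
        np.testing.assert_allclose(got_u, u, atol=1e-8)
        np.testing.assert_allclose(res.residuals, data.y - T @ np.concatenate(
            [b, u]), atol=1e-8)


class TestLeverages:
    def test_intercept_only_uniform(self):
        n = 20
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": []})
        data = StackedData(y=np.arange(n, dtype=float),
                           response=np.zeros(n, np.int64),
                           weight=np.ones(n), factors={})
        h = compute_leverages(spec, data, None, {"residual": np.array([2.0])})
        np.testing.assert_allclose(h, np.full(n, 1 / n), atol=1e-12)

    def test_singleton_fixed_level_saturates(self):
        n = 6
        fac = np.array([0, 0, 0, 0, 0, 1])  # level 1 holds a single record
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": ["fac"]})
        data = StackedData(y=np.arange(n, dtype=float),
                           response=np.zeros(n, np.int64),
                           weight=np.ones(n), factors={"fac": fac})
        with pytest.warns(UserWarning, match="saturated"):
            h = compute_leverages(spec, data, None,
                                  {"residual": np.array([1.0])})
        assert h[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_dense_hat_matrix_oracle(self, seed):
        spec, data, A, comp = _random_fixture(seed)
        res = solve_blup(spec, data, A, comp)
        ws, T, X, Z, Gf, Rv, V = _dense_pieces(spec, data, A, comp)
        C = T.T @ np.diag(1 / Rv) @ T
        C[ws.p:, ws.p:] += np.linalg.inv(Gf)
        H = T @ np.linalg.inv(C) @ T.T @ np.diag(1 / Rv)
        np.testing.assert_allclose(res.leverages, np.diag(H), atol=1e-8)
        # leverage sum equals the hat-matrix trace
        assert np.sum(res.leverages) == pytest.approx(np.trace(H))


class TestREML:
    def test_balanced_sire_design_matches_anova(self):
        rng = np.random.default_rng(10)
        q, nd = 100, 20
        A = RelationshipMatrix(ids=[f"s{i}" for i in range(q)], A=np.eye(q))
        u = rng.normal(0, 1.0, q)
        sire = np.repeat(np.arange(q), nd)
        y = 10 + u[sire] + rng.normal(0, 2.0, q * nd)
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": []},
                              genetic=GeneticTerm(responses=("y",)))
        data = StackedData(y=y, response=np.zeros(len(y), np.int64),
                           weight=np.ones(len(y)), factors={"sire": sire})
        res = estimate_reml(spec, data, A)
        assert res.converged
        df = pd.DataFrame({"y": y, "s": sire})
        msb = nd * df.groupby("s")["y"].mean().var(ddof=1)
        msw = df.groupby("s")["y"].var(ddof=1).mean()
        s2s_anova = (msb - msw) / nd
        # balanced one-way REML coincides with the ANOVA estimator
        assert res.components["genetic"][0, 0] == pytest.approx(
            s2s_anova, rel=1e-6)
        assert res.components["residual"][0] == pytest.approx(msw, rel=1e-6)

    def test_constant_response_is_estimability_error(self):
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": []})
        data = StackedData(y=np.ones(10), response=np.zeros(10, np.int64),
                           weight=np.ones(10), factors={})
        with pytest.raises(EstimabilityError, match="constant"):
            estimate_reml(spec, data, None)

    def test_loglik_beats_dense_grid_oracle(self):
        # 30-record toy: optimizer log-likelihood >= grid max of the
        # explicit REML log-likelihood over (s2_s, s2_e)
        rng = np.random.default_rng(2)
        q, nd = 6, 5
        A = RelationshipMatrix(ids=[f"s{i}" for i in range(q)], A=np.eye(q))
        sire = np.repeat(np.arange(q), nd)
        y = 5 + rng.normal(0, 1, q)[sire] + rng.normal(0, 1.5, q * nd)
        spec = MixedModelSpec(responses=["y"], fixed_terms={"y": []},
                              genetic=GeneticTerm(responses=("y",)))
        data = StackedData(y=y, response=np.zeros(len(y), np.int64),
                           weight=np.ones(len(y)), factors={"sire": sire})
        res = estimate_reml(spec, data, A)

        X = np.ones((len(y), 1))
        Z = np.zeros((len(y), q))
        Z[np.arange(len(y)), sire] = 1.0

        def ll(s2s, s2e):
            V = s2s * Z @ Z.T + s2e * np.eye(len(y))
            Vi = np.linalg.inv(V)
            _, ldV = np.linalg.slogdet(V)
            XVX = X.T @ Vi @ X
            _, ldX = np.linalg.slogdet(XVX)
            P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
            return -0.5 * (ldV + ldX + y @ P @ y)

        grid = [ll(a, b) for a in np.linspace(0.01, 3, 25)
                for b in np.linspace(0.5, 5, 25)]
        assert res.loglik >= max(grid) - 1e-6

    def test_em_fixed_point_agrees_with_ai_solution(self):
        spec, data, A, comp = _random_fixture(1, n=120, q=10, n_hen=12)
        res = estimate_reml(spec, data, A, init=comp)
        ws = _Workspace(spec, data, A)
        F = ws.factorize(res.theta)
        em = ws.em_update(F)
        # at an interior stationary point one EM step must not move
        interior = np.abs(res.theta) > 1e-4
        move = np.abs(em - res.theta)[interior]
        scale = np.abs(res.theta)[interior]
        assert np.all(move <= 0.05 * scale + 1e-6)

    def test_consistency_bias_shrinks_with_family_count(self):
        # REML on model-simulated data: bias of s2_s falls as sires increase
        def mean_est(q, reps=4):
            out = []
            for r in range(reps):
                rng = np.random.default_rng(100 + r)
                A = RelationshipMatrix(ids=[f"s{i}" for i in range(q)],
                                       A=np.eye(q))
                sire = np.repeat(np.arange(q), 10)
                y = rng.normal(0, 1, q)[sire] + rng.normal(0, 2, 10 * q)
                spec = MixedModelSpec(
                    responses=["y"], fixed_terms={"y": []},
                    genetic=GeneticTerm(responses=("y",)))
                data = StackedData(y=y, response=np.zeros(len(y), np.int64),
                                   weight=np.ones(len(y)),
                                   factors={"sire": sire})
                out.append(estimate_reml(spec, data, A)
                           .components["genetic"][0, 0])
            return np.mean(out)

        assert abs(mean_est(200) - 1.0) <= abs(mean_est(50) - 1.0) + 0.15

    def test_aliased_fixed_level_dropped_with_warning(self):
        # two identical factors -> aliased columns
        n = 30
        rng = np.random.default_rng(0)
        fac = rng.integers(0, 3, n)
        spec = MixedModelSpec(responses=["y"],
                              fixed_terms={"y": ["f1", "f2"]})
        data = StackedData(y=rng.normal(size=n) + fac,
                           response=np.zeros(n, np.int64),
                           weight=np.ones(n),
                           factors={"f1": fac, "f2": fac})
        with pytest.warns(UserWarning, match="aliased"):
            res = solve_blup(spec, data, None, {"residual": np.array([1.0])})
        assert np.isfinite(res.residuals).all()
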