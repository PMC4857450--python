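"""Simulation experiments: null calibration, the cage-definition contrast,
the simple log-variance analysis, and pathway-degeneracy checks."""

import numpy as np
import pandas as pd
import pytest

from uniformvar.dhglm import DHGLM, fit_period_models, run_dhglm, DHGLMConfig
from uniformvar.genpar import log_variance_analysis
from uniformvar.io import PhenotypeTable
from uniformvar.pedigree import build_relationship_matrix
from uniformvar.simgen import (
    SimulationParams, run_cage_definition_experiment, simulate_dataset,
)


def _fit(table, ped, **kw):
    A = build_relationship_matrix(ped, sorted(table.data["sire_id"].unique()))
    kw.setdefault("damping", True)
    kw.setdefault("max_outer_iterations", 15)
    return DHGLM(**kw).fit(table, A=A), A


class TestNullSimulation:
    def test_zero_genetic_lognormal_variance_estimated_near_zero(self):
        params = SimulationParams(
            seed=21, n_sires=40, n_grandsires=8, daughters_per_sire_p=10,
            records_per_hen=6, cages_per_sire_c=0,
            G=np.diag([2200.0, 2408.8, 1e-6, 1e-6]),
            pe=np.diag([2803.0, 1e-6]), populations=("purebred",))
        table, ped, _ = simulate_dataset(params)
        est, _ = _fit(table, ped)
        avp = est.components_.additive_variance("purebred", "var")
        se = est.components_.additive_variance_se("purebred", "var")
        assert avp <= 2 * se + 1e-4


class TestLogVarianceAnalysis:
    @pytest.fixture(scope="class")
    def purebred_sim(self):
        params = SimulationParams(
            seed=31, n_sires=60, n_grandsires=12, daughters_per_sire_p=12,
            records_per_hen=12, cages_per_sire_c=0,
            populations=("purebred",))
        table, ped, truth = simulate_dataset(params)
        A = build_relationship_matrix(
            ped, sorted(table.data["sire_id"].unique()))
        return table, A, params

    def test_recovers_lognormal_genetic_variance(self, purebred_sim):
        table, A, params = purebred_sim
        out = log_variance_analysis(table, A)
        true = params.G[2, 2]
        assert abs(out["genetic_variance"] - true) <= \
            2 * out["genetic_variance_se"] + 0.01
        assert 0 <= out["heritability"] <= 1

    def test_constant_record_hens_excluded(self, purebred_sim):
        table, A, _ = purebred_sim
        df = table.data.copy()
        hen = df["hen_id"].iloc[0]
        df.loc[df["hen_id"] == hen, "y"] = 123.0
        df.loc[df["hen_id"] == hen, "laying_date"] = 0
        df.loc[df["hen_id"] == hen, "hatch_week"] = df["hatch_week"].iloc[0]
        out = log_variance_analysis(PhenotypeTable(df),
                                    A, fixed_terms=("hatch_week",))
        assert out["n_hens_excluded"] >= 1


class TestPeriodModels:
    @pytest.fixture(scope="class")
    def fitted(self):
        params = SimulationParams(
            seed=51, n_sires=40, n_grandsires=8, daughters_per_sire_p=10,
            records_per_hen=8, cages_per_sire_c=0,
            populations=("purebred",))
        table, ped, _ = simulate_dataset(params)
        A = build_relationship_matrix(
            ped, sorted(table.data["sire_id"].unique()))
        fit = run_dhglm(table, A, DHGLMConfig(max_outer_iterations=12,
                                              damping=True))
        return table, A, fit

    def test_same_trait_across_periods_gives_correlation_near_one(self, fitted):
        # the repeatability simulation treats log V_E as one trait, so the
        # between-period genetic correlation should approach 1
        table, A, fit = fitted
        out = fit_period_models(table, A, fit, [(2, 3)])
        res = out[(2, 3)]
        assert res["converged"] or res["result"] is not None
        rho, se = res["genetic_correlation_var"]
        if np.isfinite(rho) and np.isfinite(se):
            assert rho >= 1.0 - 2 * max(se, 0.05) - 0.35
        rho_m, se_m = res["genetic_correlation_mean"]
        assert rho_m == pytest.approx(1.0, abs=3 * max(se_m, 0.05))

    def test_empty_period_subset_raises(self, fitted):
        table, A, fit = fitted
        with pytest.raises(ValueError, match="empty subset"):
            fit_period_models(table, A, fit, [(1, 9)])


class TestCageDefinitionExperiment:
    def test_default_replicate_count_matches_protocol(self):
        import inspect
        sig = inspect.signature(run_cage_definition_experiment)
        assert sig.parameters["n_replicates"].default == 20
        assert sig.parameters["cage_size"].default == 4

    @pytest.fixture(scope="class")
    def experiment(self):
        params = SimulationParams(
            seed=61, n_sires=50, n_grandsires=10, daughters_per_sire_p=16,
            records_per_hen=8, cages_per_sire_c=0,
            sigma2_a_between=0.6, populations=("purebred",))
        return run_cage_definition_experiment(
            params, n_replicates=4, cage_size=4,
            dhglm_kwargs=dict(max_outer_iterations=15))

    def test_replicates_complete_with_both_definitions(self, experiment):
        ok = experiment[experiment["ok"]]
        assert len(ok) == 4
        assert {"var_ic", "var_mc", "r_ic_mc", "r_mean"} <= set(ok.columns)
        assert np.isfinite(ok[["var_ic", "var_mc"]]).all().all()
        # mean-trait correlation between the two halves of the same families
        # is high (one trait split in two)
        assert ok["r_mean"].median() > 0.7

    def test_between_genetics_inflates_multiple_cage_variance(self, experiment):
        # an independent genetic component in the between-individual
        # variance pushes the multiple-hen-cage genetic variance above the
        # individual-cage one (at this reduced scale: in most replicates)
        ok = experiment[experiment["ok"]]
        assert (ok["var_mc"] > ok["var_ic"]).sum() >= 2


class TestPathwayDegeneracy:
    def test_single_hen_cages_match_purebred_pathway(self):
        # crossbred pathway with 1-hen cages estimates the same log-variance
        # genetic variance as the purebred pathway on like-for-like designs
        base = dict(n_sires=40, n_grandsires=8, records_per_hen=6,
                    records_per_hen_c=6, sd_line=0.0, sd_tier=0.0,
                    sd_hatch_week=0.0, sd_laying_date=0.0)
        pp = SimulationParams(seed=71, daughters_per_sire_p=10,
                              cages_per_sire_c=0,
                              populations=("purebred",), **base)
        pc = SimulationParams(seed=71, daughters_per_sire_p=0,
                              cages_per_sire_c=10, cage_size_range=(1, 1),
                              populations=("crossbred",), **base)
        tp, pedp, _ = simulate_dataset(pp)
        tc, pedc, _ = simulate_dataset(pc)
        ep, _ = _fit(tp, pedp)
        ec, _ = _fit(tc, pedc)
        avp = ep.components_.additive_variance("purebred", "var")
        sep = ep.components_.additive_variance_se("purebred", "var")
        avc = ec.components_.additive_variance("crossbred", "var")
        sec = ec.components_.additive_variance_se("crossbred", "var")
        assert abs(avp - avc) <= 2 * np.hypot(sep, sec) + 0.02
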