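"""Generator self-consistency: determinism, moments, null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uniformvar.pedigree import build_relationship_matrix
from uniformvar.simgen import (
    SimulationParams, default_G, mask_half_into_cages, simulate_dataset,
)


def _small(seed=1, **kw):
    defaults = dict(seed=seed, n_sires=20, n_grandsires=5,
                    daughters_per_sire_p=6, records_per_hen=5,
                    cages_per_sire_c=2, cage_size_range=(4, 6),
                    records_per_hen_c=4)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestDeterminismAndStructure:
    def test_identical_seed_bitwise_identical(self):
        t1, p1, _ = simulate_dataset(_small(7))
        t2, p2, _ = simulate_dataset(_small(7))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert p1 == p2

    def test_different_seed_differs(self):
        t1, _, _ = simulate_dataset(_small(7))
        t2, _, _ = simulate_dataset(_small(8))
        assert (len(t1) != len(t2)
                or not np.allclose(t1.data["y"], t2.data["y"]))

    def test_crossbred_rows_mask_hen_identity(self):
        table, _, truth = simulate_dataset(_small())
        cb = table.data[table.data["population"] == "crossbred"]
        assert cb["hen_id"].isna().all()
        assert cb["cage_id"].notna().all()
        # truth retains the hen behind each cage
        assert (truth.hens["population"] == "crossbred").any()

    def test_cage_sizes_within_range(self):
        table, _, truth = simulate_dataset(_small(cage_size_range=(4, 6)))
        sizes = truth.cages["n_hens"]
        assert sizes.between(4, 6).all()

    def test_non_psd_covariance_rejected(self):
        G = default_G()
        G[0, 1] = G[1, 0] = 1e9
        with pytest.raises(ValueError, match="PSD"):
            SimulationParams(seed=1, G=G)

    def test_pedigree_links_sires_to_grandsires(self):
        _, ped, _ = simulate_dataset(_small())
        sires = [e for e in ped if e.id.startswith("S")]
        assert all(e.sire_id is not None and e.sire_id.startswith("G")
                   for e in sires)


class TestGenerativeMoments:
    def test_pure_noise_variance_matches_exponential_scale(self):
        # all variance parameters ~0 except the residual: empirical variance
        # approx sigma2_e within Monte-Carlo error at n = 50,000
        n = 50_000
        params = SimulationParams(
            seed=3, n_sires=10, n_grandsires=2, daughters_per_sire_p=100,
            records_per_hen=n // 1000, cages_per_sire_c=0,
            G=np.diag([1e-8, 1e-8, 1e-10, 1e-10]),
            pe=np.diag([1e-8, 1e-10]), sd_hatch_week=0.0, sd_laying_date=0.0,
            populations=("purebred",))
        table, _, _ = simulate_dataset(params)
        y = table.data["y"].to_numpy()
        v = np.var(y)
        # var of a sample variance of normals: 2 sigma^4 / n
        mc_se = np.sqrt(2.0 / len(y)) * params.sigma2_e_p
        assert abs(v - params.sigma2_e_p) < 3 * mc_se

    def test_null_heterogeneity_calibrated(self):
        # no genetic or pe variance in log V_E: a Levene test across hens
        # should reject at alpha=0.01 about 1% of the time
        rejections = 0
        n_rep = 100
        for r in range(n_rep):
            params = SimulationParams(
                seed=1000 + r, n_sires=4, n_grandsires=1,
                daughters_per_sire_p=5, records_per_hen=10,
                cages_per_sire_c=0,
                G=np.diag([1e-8, 1e-8, 1e-10, 1e-10]),
                pe=np.diag([1e-8, 1e-10]), sd_hatch_week=0.0,
                sd_laying_date=0.0, populations=("purebred",))
            table, _, _ = simulate_dataset(params)
            groups = [g["y"].to_numpy()
                      for _, g in table.data.groupby("hen_id")]
            if stats.levene(*groups)[1] < 0.01:
                rejections += 1
        assert rejections <= 5  # non-significant in >= 95% of replicates

    def test_sire_family_mean_variance(self):
        # variance of purebred family-mean deviations ~ 1/4 V_A + residual
        # noise terms; check the genetic quarter dominates with many records
        params = SimulationParams(
            seed=5, n_sires=300, n_grandsires=300, daughters_per_sire_p=40,
            records_per_hen=10, cages_per_sire_c=0,
            pe=np.diag([1e-8, 0.32]), sd_hatch_week=0.0, sd_laying_date=0.0,
            populations=("purebred",))
        table, _, truth = simulate_dataset(params)
        fam = table.data.groupby("sire_id")["y"].mean()
        va = params.G[0, 0]
        # var(family mean) = va/4 + (3/4 va + pe + E[V_E]/records)/daughters
        expect = va / 4 + (0.75 * va + params.sigma2_e_p / 10) / 40
        assert fam.var(ddof=1) == pytest.approx(expect, rel=0.25)

    def test_log_within_hen_variance_regresses_on_truth_with_unit_slope(self):
        params = SimulationParams(
            seed=9, n_sires=40, n_grandsires=8, daughters_per_sire_p=10,
            records_per_hen=40, cages_per_sire_c=0, sd_hatch_week=0.0,
            sd_laying_date=0.0, populations=("purebred",))
        table, _, truth = simulate_dataset(params)
        v = table.data.groupby("hen_id")["y"].var(ddof=1)
        hens = truth.hens.set_index("hen_id")
        x = (hens["a_logvar"] + hens["env_logvar"]).loc[v.index].to_numpy()
        slope = np.polyfit(x, np.log(v.to_numpy()), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestMasking:
    def test_mask_half_into_cages_structure(self):
        params = _small(cages_per_sire_c=0, populations=("purebred",),
                        daughters_per_sire_p=8)
        table, _, _ = simulate_dataset(params)
        rng = np.random.default_rng(0)
        masked = mask_half_into_cages(table, cage_size=4, rng=rng)
        df = masked.data
        cb = df[df["population"] == "crossbred"]
        pb = df[df["population"] == "purebred"]
        # half of each sire's 8 daughters masked
        assert len(cb) == len(pb)
        assert cb["hen_id"].isna().all()
        # masked cages group hens of a single sire
        per_cage = cb.groupby("cage_id")["sire_id"].nunique()
        assert (per_cage == 1).all()

    def test_masking_preserves_trait_values(self):
        params = _small(cages_per_sire_c=0, populations=("purebred",))
        table, _, _ = simulate_dataset(params)
        masked = mask_half_into_cages(table, 4, np.random.default_rng(0))
        np.testing.assert_allclose(
            np.sort(masked.data["y"]), np.sort(table.data["y"]))
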