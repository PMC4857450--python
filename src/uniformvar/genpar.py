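"""Derived genetic parameters and their approximate standard errors.

From the estimated variance components this module derives, per population:

* additive genetic variance (4 x sire variance) and heritability of the mean
  trait;
* the genetic coefficient of variation for environmental variance,
  ``GCV_Ve = sigma_av`` (the log-scale genetic standard deviation equals the
  relative genetic spread of V_E under the exponential model);
* the record-level heritability of environmental variance ``h_v^2``, the
  regression of the breeding value for V_E on the squared phenotypic
  deviation, on the additive scale implied by the exponential model;
* delta-method (first-order Taylor) sampling variances for both.

Also provided: variance-proportion summaries, a two-sided approximate normal
test for differences between estimates, and a simple sire-model analysis of
the log of the within-hen variance (an alternative to the DHGLM that shares
its exponential-model scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable, PUREBRED
from .pedigree import RelationshipMatrix
from .lmm import (
    MixedModelSpec, GeneticTerm, StackedData, REMLResult, estimate_reml,
    solve_blup,
)

__all__ = [
    "VarianceComponentSet", "DerivedParams", "genetic_variance_from_sire",
    "heritability_mean", "variance_proportions", "gcv_ve",
    "hv2_additive_scale", "approx_standard_errors", "difference_test",
    "log_variance_analysis", "derive_parameters",
]


# --------------------------------------------------------------------------
# elementary formulas
# --------------------------------------------------------------------------

def genetic_variance_from_sire(sigma2_s: float) -> float:
    """Additive genetic variance under a sire model: 4 * sire variance."""
    if sigma2_s < 0:
        raise ValueError("sire variance must be non-negative")
    return 4.0 * sigma2_s


def heritability_mean(sigma2_s: float, sigma2_pe_or_cg: float,
                      sigma2_e: float) -> float:
    """h2 = 4*s2_s / (s2_s + s2_pe|cg + s2_e)."""
    if min(sigma2_s, sigma2_pe_or_cg, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    denom = sigma2_s + sigma2_pe_or_cg + sigma2_e
    if denom <= 0:
        raise ValueError("zero phenotypic variance")
    return 4.0 * sigma2_s / denom


def variance_proportions(sigma2_s: float, sigma2_pe: float | None,
                         sigma2_cg: float | None, sigma2_e: float) -> dict:
    """Shares of phenotypic variance explained by pe (net of 3/4 V_A) or cage.

    The purebred permanent-environment effect absorbs dam and Mendelian-
    sampling genetic variance (3/4 of V_A under a sire model); its reported
    share subtracts that part.
    """
    out: dict[str, float] = {}
    if sigma2_pe is not None:
        s2p = sigma2_s + sigma2_pe + sigma2_e
        adj = sigma2_pe - 0.75 * genetic_variance_from_sire(sigma2_s)
        if adj < 0:
            import warnings
            warnings.warn("pe variance smaller than 3/4 V_A: model "
                          "inconsistency; share reported as-is", stacklevel=2)
        out["pe_share"] = adj / s2p
    if sigma2_cg is not None:
        s2p = sigma2_s + sigma2_cg + sigma2_e
        out["cage_share"] = sigma2_cg / s2p
    return out


def gcv_ve(sigma2_av: float) -> float:
    """Genetic coefficient of variation of V_E: sqrt of the log-scale
    additive genetic variance."""
    if sigma2_av < 0:
        raise ValueError("genetic variance must be non-negative")
    return float(np.sqrt(sigma2_av))


def hv2_additive_scale(sigma2_av: float, sigma2_cv: float,
                       sigma2_E_exp: float, sigma2_P: float
                       ) -> tuple[float, float, float]:
    """Additive-scale variances of V_E and the record-level heritability.

    Under the exponential model V_E = s2_E_exp * exp(a_v + c_v), the
    additive-scale genetic variance of V_E is

        s2_av_add = s2_E_exp^2 * exp(s2_cv) * (exp(2 s2_av) - exp(s2_av)),

    symmetrically for the non-genetic (pe or cage) component, and

        h_v^2 = s2_av_add / (2 s2_P^4 + 3 (s2_av_add + s2_cv_add)).
    """
    if min(sigma2_av, sigma2_cv, sigma2_E_exp, sigma2_P) < 0:
        raise ValueError("inputs must be non-negative")
    s4 = sigma2_E_exp ** 2
    a_add = s4 * np.exp(sigma2_cv) * (np.exp(2 * sigma2_av) - np.exp(sigma2_av))
    c_add = s4 * np.exp(sigma2_av) * (np.exp(2 * sigma2_cv) - np.exp(sigma2_cv))
    denom = 2.0 * sigma2_P ** 2 + 3.0 * (a_add + c_add)
    # note sigma2_P is the phenotypic *variance*; the denominator term is
    # 2 * sigma_P^4 = 2 * (sigma2_P)^2
    hv2 = a_add / denom if denom > 0 else 0.0
    return float(a_add), float(c_add), float(hv2)


def approx_standard_errors(
    sigma2_av: float, var_sigma2_av: float,
    sigma2_cv: float, var_sigma2_cv: float,
    sigma2_P: float, var_sigma2_P: float,
    sigma2_E_exp: float,
) -> dict:
    """Taylor-series sampling variances for h_v^2 and GCV_Ve.

    The additive-scale numerator variance treats s2_E_exp as a constant (its
    relative standard error is negligible next to that of s2_av); sampling
    covariances between distinct components are taken as zero except for the
    numerator's own contribution to the denominator, cov(num, denom) =
    3 var(num).
    """
    if sigma2_av < 0 or var_sigma2_av < 0:
        raise ValueError("invalid genetic variance or sampling variance")
    s8 = sigma2_E_exp ** 4
    var_a_add = (s8 * np.exp(2 * sigma2_cv) * var_sigma2_av
                 * (4 * np.exp(4 * sigma2_av) - 4 * np.exp(3 * sigma2_av)
                    + np.exp(2 * sigma2_av)))
    var_c_add = (s8 * np.exp(2 * sigma2_av) * var_sigma2_cv
                 * (4 * np.exp(4 * sigma2_cv) - 4 * np.exp(3 * sigma2_cv)
                    + np.exp(2 * sigma2_cv)))
    var_2p4 = 8.0 * (2.0 * sigma2_P ** 2 * var_sigma2_P + var_sigma2_P ** 2)
    var_denom = var_2p4 + 9.0 * (var_a_add + var_c_add)

    a_add, c_add, hv2 = hv2_additive_scale(
        sigma2_av, sigma2_cv, sigma2_E_exp, sigma2_P)
    denom = 2.0 * sigma2_P ** 2 + 3.0 * (a_add + c_add)
    if a_add > 0:
        var_hv2 = hv2 ** 2 * (var_a_add / a_add ** 2
                              - 6.0 * var_a_add / (a_add * denom)
                              + var_denom / denom ** 2)
    else:
        var_hv2 = 0.0
    if sigma2_av == 0.0:
        if var_sigma2_av > 0:
            raise ValueError("se(GCV) undefined at zero genetic variance")
        se_gcv = 0.0
    else:
        se_gcv = np.sqrt(var_sigma2_av) / (2.0 * np.sqrt(sigma2_av))
    return dict(
        var_a_add=float(var_a_add), var_c_add=float(var_c_add),
        var_denom=float(var_denom), hv2=float(hv2),
        se_hv2=float(np.sqrt(max(var_hv2, 0.0))), se_gcv=float(se_gcv),
    )


def difference_test(theta1: float, se1: float, theta2: float,
                    se2: float) -> tuple[float, float]:
    """Two-sided approximate normal test for a difference of estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (theta1 - theta2) / np.sqrt(se1 ** 2 + se2 ** 2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --------------------------------------------------------------------------
# variance-component container
# --------------------------------------------------------------------------

@dataclass
class VarianceComponentSet:
    """Final DHGLM variance components with sampling variances.

    Genetic covariances are stored on the sire scale in ``G_sire`` (response
    order in ``responses``); the additive scale is 4x that.  ``scaling``
    holds the residual scaling variances of the weighted joint fit (expected
    near 1), ``sigma2_e_hom`` the homogeneous-model residual variances used
    as the mean-trait residual.
    """

    responses: list[str]
    G_sire: np.ndarray
    pe: np.ndarray | None
    cage: np.ndarray | None
    scaling: dict[str, float]
    sigma2_e_hom: dict[str, float]
    sigma2_e_hom_var: dict[str, float]
    sigma2_ea: float
    sigma2_ac: float
    reml: REMLResult
    e_exp_calibration: str = "match_residual"
    psd_projections: int = 0

    @property
    def G_additive(self) -> np.ndarray:
        return 4.0 * self.G_sire

    @property
    def populations(self) -> tuple[str, ...]:
        pops = []
        if "mean_p" in self.responses:
            pops.append("purebred")
        if "mean_c" in self.responses:
            pops.append("crossbred")
        return tuple(pops)

    # -- helpers -----------------------------------------------------------
    def _resp(self, pop: str, model: str) -> str:
        tag = "p" if pop == "purebred" else "c"
        return f"{'mean' if model == 'mean' else 'var'}_{tag}"

    def _gidx(self, resp: str) -> int:
        return self.responses.index(resp)

    def sire_variance(self, pop: str, model: str = "mean") -> float:
        i = self._gidx(self._resp(pop, model))
        return float(self.G_sire[i, i])

    def sire_variance_se(self, pop: str, model: str = "mean") -> float:
        r = self._resp(pop, model)
        return self.reml.se(f"genetic({r},{r})")

    def additive_variance(self, pop: str, model: str = "mean") -> float:
        return 4.0 * self.sire_variance(pop, model)

    def additive_variance_se(self, pop: str, model: str = "mean") -> float:
        return 4.0 * self.sire_variance_se(pop, model)

    def nongenetic_variance(self, pop: str, model: str = "mean") -> float:
        """pe (purebred) or cage (crossbred) variance, mean or log scale."""
        M = self.pe if pop == "purebred" else self.cage
        i = 0 if model == "mean" else 1
        return float(np.atleast_2d(M)[i, i])

    def nongenetic_variance_se(self, pop: str, model: str = "mean") -> float:
        term = "pe" if pop == "purebred" else "cage"
        r = self._resp(pop, model)
        return self.reml.se(f"{term}({r},{r})")

    def residual_variance(self, pop: str) -> float:
        return self.sigma2_e_hom[pop]

    def phenotypic_variance(self, pop: str) -> float:
        return (self.sire_variance(pop) + self.nongenetic_variance(pop)
                + self.residual_variance(pop))

    def phenotypic_variance_var(self, pop: str) -> float:
        # no sampling covariance assumed between the three components
        return (self.sire_variance_se(pop) ** 2
                + self.nongenetic_variance_se(pop) ** 2
                + self.sigma2_e_hom_var[pop])

    def heritability(self, pop: str) -> float:
        return heritability_mean(self.sire_variance(pop),
                                 self.nongenetic_variance(pop),
                                 self.residual_variance(pop))

    def variance_proportions(self, pop: str) -> dict:
        return variance_proportions(
            self.sire_variance(pop),
            self.nongenetic_variance(pop) if pop == "purebred" else None,
            self.nongenetic_variance(pop) if pop == "crossbred" else None,
            self.residual_variance(pop))

    def sigma2_av(self, pop: str) -> float:
        return self.additive_variance(pop, "var")

    def sigma2_av_se(self, pop: str) -> float:
        return self.additive_variance_se(pop, "var")

    def sigma2_cv(self, pop: str) -> float:
        return self.nongenetic_variance(pop, "var")

    def sigma2_E_exp(self, pop: str) -> float:
        """Scale of the exponential variance model, calibrated so that the
        expected environmental variance matches the homogeneous residual."""
        s2e = self.residual_variance(pop)
        if self.e_exp_calibration == "match_residual":
            return s2e / np.exp((self.sigma2_av(pop) + self.sigma2_cv(pop)) / 2)
        return s2e

    def genetic_correlation(self, r1: str, r2: str) -> tuple[float, float]:
        return self.reml.correlation("genetic", r1, r2)

    def derive(self, pop: str) -> "DerivedParams":
        """All derived parameters for one population, with SEs."""
        s2av = self.sigma2_av(pop)
        var_s2av = self.sigma2_av_se(pop) ** 2
        s2cv = self.sigma2_cv(pop)
        var_s2cv = self.nongenetic_variance_se(pop, "var") ** 2
        s2P = self.phenotypic_variance(pop)
        var_s2P = self.phenotypic_variance_var(pop)
        s2E = self.sigma2_E_exp(pop)
        a_add, c_add, hv2 = hv2_additive_scale(s2av, s2cv, s2E, s2P)
        ses = approx_standard_errors(s2av, var_s2av, s2cv, var_s2cv,
                                     s2P, var_s2P, s2E)
        return DerivedParams(
            population=pop, h2=self.heritability(pop),
            gcv=gcv_ve(s2av), se_gcv=ses["se_gcv"],
            hv2=hv2, se_hv2=ses["se_hv2"],
            sigma2_av=s2av, se_sigma2_av=float(np.sqrt(var_s2av)),
            sigma2_a_add=a_add, sigma2_c_add=c_add,
            sigma2_E_exp=s2E, sigma2_P=s2P,
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dhglm(cls, fit: REMLResult, state, spec: MixedModelSpec
                   ) -> "VarianceComponentSet":
        responses = list(spec.genetic.responses)
        hom = state.reml_homogeneous
        s2hom: dict[str, float] = {}
        s2hom_var: dict[str, float] = {}
        if "mean_p" in responses:
            i = hom.spec.responses.index("mean_p")
            s2hom["purebred"] = float(hom.components["residual"][i])
            s2hom_var["purebred"] = hom.se(f"residual(mean_p)") ** 2
        if "mean_c" in responses:
            i = hom.spec.responses.index("mean_c")
            s2hom["crossbred"] = float(hom.components["residual"][i])
            s2hom_var["crossbred"] = hom.se(f"residual(mean_c)") ** 2
        scaling = {r: float(fit.components["residual"][k])
                   for k, r in enumerate(spec.responses)}
        return cls(
            responses=responses,
            G_sire=np.array(fit.components["genetic"]),
            pe=np.array(fit.components["pe"]) if "pe" in fit.components else None,
            cage=(np.array(fit.components["cage"])
                  if "cage" in fit.components else None),
            scaling=scaling, sigma2_e_hom=s2hom, sigma2_e_hom_var=s2hom_var,
            sigma2_ea=state.sigma2_ea, sigma2_ac=state.sigma2_ac, reml=fit,
            psd_projections=fit.n_psd_projections,
        )


@dataclass(frozen=True)
class DerivedParams:
    """Per-population derived parameters with approximate SEs.

    ``hv2`` is the record-level heritability of V_E; ``sigma2_a_add`` and
    ``sigma2_c_add`` are the additive-scale variances of V_E for the genetic
    and pe/cage components under the exponential model.
    """

    population: str
    h2: float
    gcv: float
    se_gcv: float
    hv2: float
    se_hv2: float
    sigma2_av: float
    se_sigma2_av: float
    sigma2_a_add: float
    sigma2_c_add: float
    sigma2_E_exp: float
    sigma2_P: float


def derive_parameters(comps: VarianceComponentSet) -> pd.DataFrame:
    """Tidy table of derived parameters (parameter, population, estimate, se)."""
    rows = []
    for pop in comps.populations:
        d = comps.derive(pop)
        rows += [
            ("genetic_variance_mean", pop, comps.additive_variance(pop),
             comps.additive_variance_se(pop)),
            ("h2", pop, d.h2, np.nan),
            ("genetic_variance_logVE", pop, d.sigma2_av, d.se_sigma2_av),
            ("GCV_Ve", pop, d.gcv, d.se_gcv),
            ("hv2", pop, d.hv2, d.se_hv2),
        ]
    if len(comps.populations) == 2:
        for r1, r2, lab in (("mean_p", "mean_c", "r_pc_mean"),
                            ("var_p", "var_c", "r_pc_logVE")):
            rho, se = comps.genetic_correlation(r1, r2)
            rows.append((lab, "both", rho, se))
    return pd.DataFrame(rows, columns=["parameter", "population",
                                       "estimate", "se"])


# --------------------------------------------------------------------------
# simple log-variance sire analysis
# --------------------------------------------------------------------------

def log_variance_analysis(
    table: PhenotypeTable,
    A: RelationshipMatrix,
    fixed_terms: tuple[str, ...] = ("hatch_week", "laying_date"),
    min_records: int = 2,
) -> dict:
    """Sire-model analysis of the log within-hen variance (purebreds).

    Records are adjusted for fixed effects (residuals from the fixed part of
    the mean model); per hen the sample variance of the adjusted records is
    log-transformed and analyzed with a single-response sire model.  The
    returned genetic variance (4 x sire) is on the same exponential-model
    scale as the DHGLM log-variance genetic variance.
    """
    from .dhglm import _factor_codes  # shared encoding

    df = table.data
    pb = table.is_purebred
    if not pb.all():
        table = table.subset(pb)
        df = table.data
    codes = _factor_codes(df, A)
    n = len(df)

    spec_f = MixedModelSpec(
        responses=["mean_p"], fixed_terms={"mean_p": list(fixed_terms)},
        genetic=None, groups=[])
    data_f = StackedData(y=df["y"].to_numpy(), response=np.zeros(n, np.int64),
                         weight=np.ones(n), factors=codes)
    blue = solve_blup(spec_f, data_f, None,
                      {"residual": np.array([float(np.var(df["y"]))])})
    resid = blue.residuals

    hen_codes = codes["hen"]
    hens = pd.DataFrame({"hen": hen_codes, "resid": resid,
                         "sire": codes["sire"]})
    grp = hens.groupby("hen")
    v = grp["resid"].var(ddof=1)
    cnt = grp.size()
    sire_of = grp["sire"].first()
    ok = (cnt >= min_records) & (v > 0)
    n_excluded = int((~ok).sum())
    logv = np.log(v[ok].to_numpy())
    sires = sire_of[ok].to_numpy()

    spec_s = MixedModelSpec(
        responses=["logvar"], fixed_terms={"logvar": []},
        genetic=GeneticTerm(responses=("logvar",)), groups=[])
    data_s = StackedData(
        y=logv, response=np.zeros(len(logv), np.int64),
        weight=np.ones(len(logv)), factors={"sire": sires})
    fit = estimate_reml(spec_s, data_s, A)
    s2s = float(fit.components["genetic"][0, 0])
    s2e = float(fit.components["residual"][0])
    return dict(
        genetic_variance=4.0 * s2s,
        genetic_variance_se=4.0 * fit.se("genetic(logvar,logvar)"),
        heritability=heritability_mean(s2s, 0.0, s2e),
        n_hens=len(logv), n_hens_excluded=n_excluded, reml=fit,
    )
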