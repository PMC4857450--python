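"""Purebred-crossbred sire-model DHGLM for heterogeneous environmental variance.

The double hierarchical generalized linear model couples a mixed model for the
trait mean with a mixed model for the log of its environmental variance
through linearized working variables and iteratively reweighted residuals:

* the deviance contribution of record *i* is ``phi_i = e_i^2 / (1 - h_i)``
  (squared residual corrected by the hat-matrix diagonal ``h_i``);
* the purebred variance-model response is the first-order Taylor
  linearization of ``log(phi_i)`` around the predicted residual variance,
  ``y_v = log(s2) + (phi - s2) / s2``;
* crossbred eggs are recorded per cage, so only sires carry genetic effects
  and the residual of the crossbred mean model contains three quarters of the
  additive genetic variance.  The sire-model adjustment rescales the deviance
  by ``s2_es / s2_ea`` (homogeneous sire-model residual variance over the
  animal-model residual variance) so that the variance model targets the
  environmental variance itself rather than V_E + 3/4 V_A.

The outer algorithm alternates a weighted 4-variate REML fit on
``(y_p, y_c, y_vp, y_vc)`` with updates of the working variables and the four
weight matrices, until the sum of relative squared differences of the
variance components falls below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import PhenotypeTable, PUREBRED, CROSSBRED
from .pedigree import RelationshipMatrix
from .lmm import (
    MixedModelSpec, GeneticTerm, IndependentTerm, StackedData, REMLResult,
    estimate_reml, solve_blup,
)

__all__ = [
    "DHGLM", "DHGLMConfig", "DHGLMState", "DHGLMFit", "SaturationError",
    "compute_phi", "working_response_purebred", "working_response_crossbred",
    "compute_weight_matrices", "convergence_metric", "run_dhglm",
    "fit_period_models", "assign_period",
]


class SaturationError(ValueError):
    """A record with leverage ~ 1 cannot contribute a deviance."""


# -- laying-period boundaries (weeks of age) --------------------------------
PERIODS = {
    PUREBRED: [(25, 35, 1), (36, 55, 2), (56, 75, 3), (76, 95, 4)],
    CROSSBRED: [(30, 45, 1), (50, 65, 2), (70, 85, 3)],
}


def assign_period(age_weeks: int, population: str) -> int:
    """Laying period of a record from hen age; 0 if outside all periods."""
    for lo, hi, p in PERIODS[population]:
        if lo <= age_weeks <= hi:
            return p
    return 0


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def compute_phi(e, h):
    """Deviance contribution ``e^2 / (1 - h)``; rejects saturated records."""
    e = np.asarray(e, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h >= 1):
        raise SaturationError("leverage outside [0, 1)")
    return e ** 2 / (1.0 - h)


def working_response_purebred(phi, sigma2_hat):
    """Linearized log-variance response: log(s2) + (phi - s2)/s2."""
    phi = np.asarray(phi, dtype=float)
    s2 = np.asarray(sigma2_hat, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("predicted residual variance must be positive")
    return np.log(s2) + (phi - s2) / s2


def working_response_crossbred(phi, sigma2_hat, ratio):
    """Sire-model-adjusted response: log(s2) + (phi*ratio - s2)/s2.

    ``ratio`` is the frozen s2_es / s2_ea; with ratio = 1 (no genetic
    variance of the mean) this reduces to the purebred working response.
    """
    if ratio < 1.0:
        raise ValueError(
            "sire/animal residual variance ratio < 1: inconsistent components")
    phi = np.asarray(phi, dtype=float)
    s2 = np.asarray(sigma2_hat, dtype=float)
    if np.any(s2 <= 0):
        raise ValueError("predicted residual variance must be positive")
    return np.log(s2) + (phi * ratio - s2) / s2


def convergence_metric(prev, curr) -> float:
    """Sum of relative squared differences between component vectors."""
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError("component vectors differ in length")
    denom = np.abs(prev)
    small = denom < 1e-12
    if small.any():
        warnings.warn(f"{int(small.sum())} components with ~zero previous "
                      "value; guarded denominator used", stacklevel=2)
        denom = np.maximum(denom, 1e-12)
    return float(np.sum(((curr - prev) / denom) ** 2))


# --------------------------------------------------------------------------
# configuration / state containers
# --------------------------------------------------------------------------

@dataclass
class DHGLMConfig:
    """Outer-iteration settings.

    The iteration stops when the sum of relative squared component
    differences drops below ``convergence_threshold`` (or at
    ``max_outer_iterations``, flagged).  ``freeze_ratio`` keeps the
    sire/animal residual-variance ratio at its value from the homogeneous
    fit, which stabilizes convergence.
    """

    max_outer_iterations: int = 100
    convergence_threshold: float = 1e-2
    freeze_ratio: bool = True
    period_mode: str = "repeatability"
    damping: bool = False
    leverage_guard: float = 0.999
    freeze_linearization: bool = False
    fixed_terms_purebred: tuple[str, ...] = ("hatch_week", "laying_date")
    fixed_terms_crossbred: tuple[str, ...] = ("line", "tier")
    inner_max_rounds: int = 50

    def __post_init__(self) -> None:
        if self.max_outer_iterations < 2:
            raise ValueError("max_outer_iterations must be >= 2")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be > 0")


@dataclass
class DHGLMState:
    """Per-record working quantities of the current outer iteration."""

    y_v: np.ndarray                  # working variance response per record
    W_mean: np.ndarray               # mean-model weight per record
    W_var: np.ndarray                # variance-model weight per record
    h: np.ndarray                    # leverage of the mean row per record
    e: np.ndarray                    # mean-model residual per record
    sigma2_hat: np.ndarray           # predicted residual variance per record
    sigma2_es: float                 # homogeneous crossbred sire-model residual
    sigma2_ea: float                 # animal-model residual = es - 3/4 ac
    sigma2_ac: float                 # crossbred additive variance (mean trait)
    sigma2_ep: float                 # homogeneous purebred residual
    ratio: float                     # sigma2_es / sigma2_ea (frozen)
    reml: REMLResult | None = None
    reml_homogeneous: REMLResult | None = None
    iteration: int = 0
    n_guarded: int = 0               # records excluded by the leverage guard
    trace: list[float] = field(default_factory=list)


@dataclass
class DHGLMFit:
    """Final components, final state, and the per-iteration trace."""

    components: "VarianceComponentSet"
    state: DHGLMState
    component_trace: list[np.ndarray]
    converged: bool
    n_iterations: int


def compute_weight_matrices(state: DHGLMState, is_purebred: np.ndarray,
                            yv_fitted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All four weight vectors from the current fitted variance responses.

    W_p = 1/exp(yv_p);  W_c = 1/[s2_ea * exp(yv_c)/mean(exp(yv_c)) + 3/4 s2_ac];
    W_vp = (1 - h)/2;   W_vc = (1 - h)^2 (s2_ea/s2_es)^2 / 2.
    Returns (W_mean, W_var) over records.
    """
    pb = np.asarray(is_purebred, dtype=bool)
    cb = ~pb
    W_mean = np.empty(len(pb))
    W_var = np.empty(len(pb))
    # clamp fitted log-variance deviations: a runaway fitted value must not
    # overflow the exponential or zero a weight
    yv_fitted = np.asarray(yv_fitted, dtype=float).copy()
    for m in (pb, cb):
        if m.any():
            c = np.median(yv_fitted[m])
            yv_fitted[m] = np.clip(yv_fitted[m], c - 12.0, c + 12.0)
    W_mean[pb] = 1.0 / np.exp(yv_fitted[pb])
    if cb.any():
        ev = np.exp(yv_fitted[cb])
        W_mean[cb] = 1.0 / (state.sigma2_ea * ev / ev.mean()
                            + 0.75 * state.sigma2_ac)
    W_var[pb] = 0.5 * (1.0 - state.h[pb])
    W_var[cb] = 0.5 * (1.0 - state.h[cb]) ** 2 / state.ratio ** 2
    bad = np.flatnonzero(W_mean <= 0)
    if bad.size:
        raise ValueError(f"non-positive mean-model weight at record {bad[0]}")
    bad = np.flatnonzero(W_var < 0)
    if bad.size:
        raise ValueError(f"negative variance-model weight at record {bad[0]}")
    return W_mean, W_var


# --------------------------------------------------------------------------
# stacking the table into engine input
# --------------------------------------------------------------------------

def _factor_codes(df: pd.DataFrame, A: RelationshipMatrix) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for col in ("hatch_week", "laying_date", "line", "tier"):
        vals = df[col]
        codes, _ = pd.factorize(vals, use_na_sentinel=True)
        out[col] = codes.astype(np.int64)
    sire = np.array([A.index.get(s, -1) for s in df["sire_id"]], dtype=np.int64)
    if (sire < 0).any():
        missing = df["sire_id"][sire < 0].iloc[0]
        raise KeyError(f"sire {missing!r} not among relationship-matrix subjects")
    out["sire"] = sire
    pb = (df["population"] == PUREBRED).to_numpy()
    hen = np.full(len(df), -1, dtype=np.int64)
    if pb.any():
        hen[pb] = pd.factorize(df.loc[pb, "hen_id"])[0]
    cage = np.full(len(df), -1, dtype=np.int64)
    cb = ~pb
    if cb.any():
        cage[cb] = pd.factorize(df.loc[cb, "cage_id"])[0]
    out["hen"] = hen
    out["cage"] = cage
    return out


def _stack(table: PhenotypeTable, A: RelationshipMatrix, cfg: DHGLMConfig,
           y_v: np.ndarray | None = None,
           W_mean: np.ndarray | None = None,
           W_var: np.ndarray | None = None,
           var_mask: np.ndarray | None = None,
           ) -> tuple[MixedModelSpec, StackedData, np.ndarray]:
    """Stack mean (and optionally variance) responses into engine input.

    Returns (spec, data, var_row_index) where var_row_index[j] is the record
    index of stacked variance row j.
    """
    df = table.data
    n = len(df)
    pb = table.is_purebred
    cb = table.is_crossbred
    has_p, has_c = bool(pb.any()), bool(cb.any())

    responses: list[str] = []
    if has_p:
        responses.append("mean_p")
    if has_c:
        responses.append("mean_c")
    with_var = y_v is not None
    if with_var:
        if has_p:
            responses.append("var_p")
        if has_c:
            responses.append("var_c")

    rcode = {name: i for i, name in enumerate(responses)}
    resp_mean = np.where(pb, rcode.get("mean_p", -1), rcode.get("mean_c", -1))

    codes = _factor_codes(df, A)
    if with_var:
        if var_mask is None:
            var_mask = np.ones(n, dtype=bool)
        vidx = np.flatnonzero(var_mask)
        y = np.concatenate([df["y"].to_numpy(), y_v[vidx]])
        resp_var = np.where(pb, rcode.get("var_p", -1), rcode.get("var_c", -1))
        resp = np.concatenate([resp_mean, resp_var[vidx]])
        w = np.concatenate([W_mean, W_var[vidx]])
        factors = {k: np.concatenate([v, v[vidx]]) for k, v in codes.items()}
    else:
        vidx = np.empty(0, dtype=np.int64)
        y = df["y"].to_numpy()
        resp = resp_mean
        w = np.ones(n) if W_mean is None else W_mean
        factors = codes

    fixed: dict[str, list[str]] = {}
    for r in responses:
        fixed[r] = list(cfg.fixed_terms_purebred if r.endswith("_p")
                        else cfg.fixed_terms_crossbred)

    groups: list[IndependentTerm] = []
    if has_p:
        pe_resp = tuple(r for r in ("mean_p", "var_p") if r in responses)
        groups.append(IndependentTerm("pe", pe_resp, "hen"))
    if has_c:
        cg_resp = tuple(r for r in ("mean_c", "var_c") if r in responses)
        groups.append(IndependentTerm("cage", cg_resp, "cage"))

    spec = MixedModelSpec(
        responses=responses, fixed_terms=fixed,
        genetic=GeneticTerm(responses=tuple(responses)),
        groups=groups,
    )
    data = StackedData(y=y, response=resp, weight=w, factors=factors)
    return spec, data, vidx


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

class DHGLM(BaseEstimator):
    """Sire-model DHGLM estimator for the mean and log environmental variance.

    Parameters mirror :class:`DHGLMConfig`.  After :meth:`fit`:

    ``G_`` : additive-scale genetic covariance matrix over the fitted
    responses (4 x sire covariance); ``components_`` the full
    :class:`~uniformvar.genpar.VarianceComponentSet`; ``state_`` the final
    working-variable state; ``n_iter_``, ``converged_`` iteration
    diagnostics; ``trace_`` the per-iteration convergence metric.
    """

    def __init__(self, max_outer_iterations: int = 100,
                 convergence_threshold: float = 1e-2,
                 freeze_ratio: bool = True,
                 period_mode: str = "repeatability",
                 damping: bool = False,
                 leverage_guard: float = 0.999,
                 freeze_linearization: bool = False,
                 fixed_terms_purebred: tuple[str, ...] = ("hatch_week", "laying_date"),
                 fixed_terms_crossbred: tuple[str, ...] = ("line", "tier"),
                 inner_max_rounds: int = 50):
        self.max_outer_iterations = max_outer_iterations
        self.convergence_threshold = convergence_threshold
        self.freeze_ratio = freeze_ratio
        self.period_mode = period_mode
        self.damping = damping
        self.leverage_guard = leverage_guard
        self.freeze_linearization = freeze_linearization
        self.fixed_terms_purebred = fixed_terms_purebred
        self.fixed_terms_crossbred = fixed_terms_crossbred
        self.inner_max_rounds = inner_max_rounds

    def _config(self) -> DHGLMConfig:
        return DHGLMConfig(
            max_outer_iterations=self.max_outer_iterations,
            convergence_threshold=self.convergence_threshold,
            freeze_ratio=self.freeze_ratio,
            period_mode=self.period_mode,
            damping=self.damping,
            leverage_guard=self.leverage_guard,
            freeze_linearization=self.freeze_linearization,
            fixed_terms_purebred=tuple(self.fixed_terms_purebred),
            fixed_terms_crossbred=tuple(self.fixed_terms_crossbred),
            inner_max_rounds=self.inner_max_rounds,
        )

    # ------------------------------------------------------------------
    def fit(self, table: PhenotypeTable, A: RelationshipMatrix = None):
        from .genpar import VarianceComponentSet  # local: avoid import cycle

        cfg = self._config()
        if A is None:
            raise ValueError("a RelationshipMatrix is required")
        df = table.data
        pb = table.is_purebred
        cb = table.is_crossbred
        has_c = bool(cb.any())
        n = len(df)

        # ---- step 1: homogeneous-residual fit of the mean responses -------
        spec_h, data_h, _ = _stack(table, A, cfg)
        fit_h = estimate_reml(spec_h, data_h, A,
                              max_rounds=cfg.inner_max_rounds)
        resp_h = spec_h.responses
        sigma2_ep = float(fit_h.components["residual"][resp_h.index("mean_p")]) \
            if "mean_p" in resp_h else np.nan
        if has_c:
            ic = resp_h.index("mean_c")
            sigma2_es = float(fit_h.components["residual"][ic])
            gi = spec_h.genetic.responses.index("mean_c")
            sigma2_ac = 4.0 * float(fit_h.components["genetic"][gi, gi])
            sigma2_ea = sigma2_es - 0.75 * sigma2_ac
            if sigma2_ea <= 0:
                raise ValueError(
                    "animal-model residual variance non-positive "
                    f"(s2_es={sigma2_es:.4g}, 3/4*s2_ac={0.75 * sigma2_ac:.4g})")
            ratio = sigma2_es / sigma2_ea
        else:
            sigma2_es = sigma2_ea = sigma2_ac = np.nan
            ratio = 1.0

        e = fit_h.residuals[:n]
        h = np.clip(fit_h.leverages[:n], 0.0, 1.0 - 1e-12)

        # ---- step 2: initial working responses and weights ----------------
        sigma2_hat = np.where(pb, sigma2_ep, sigma2_es)
        state = DHGLMState(
            y_v=np.zeros(n), W_mean=np.empty(n), W_var=np.empty(n),
            h=h, e=e, sigma2_hat=sigma2_hat, sigma2_es=sigma2_es,
            sigma2_ea=sigma2_ea, sigma2_ac=sigma2_ac, sigma2_ep=sigma2_ep,
            ratio=ratio, reml_homogeneous=fit_h,
        )
        self._update_working(state, pb, cb, first=True)

        # warm-start components for the joint model
        init = self._initial_components(fit_h, spec_h, has_p=bool(pb.any()),
                                        has_c=has_c)

        # ---- steps 3-5: iterate joint fit and weight updates ---------------
        trace_components: list[np.ndarray] = []
        prev_theta = None
        converged = False
        fit = None
        for it in range(cfg.max_outer_iterations):
            guard = state.h <= cfg.leverage_guard
            state.n_guarded = int((~guard).sum())
            spec, data, vidx = _stack(
                table, A, cfg, y_v=state.y_v, W_mean=state.W_mean,
                W_var=state.W_var, var_mask=guard)
            fit = estimate_reml(
                spec, data, A, init=init,
                max_rounds=cfg.inner_max_rounds if it == 0 else 8)
            init = {k: v.copy() for k, v in fit.components.items()}
            state.reml = fit
            state.iteration = it + 1

            # fitted variance-model values per record
            yv_fitted = np.log(state.sigma2_hat)  # fallback for guarded rows
            fitted_var = fit.fitted[n:]
            yv_fitted[vidx] = fitted_var

            # residuals/leverages of the mean rows
            state.e = fit.residuals[:n]
            state.h = np.clip(fit.leverages[:n], 0.0, 1.0 - 1e-12)

            if not cfg.freeze_ratio and has_c:
                gi = spec.genetic.responses.index("mean_c")
                state.sigma2_ac = 4.0 * float(fit.components["genetic"][gi, gi])
                state.sigma2_ea = state.sigma2_es - 0.75 * state.sigma2_ac
                if state.sigma2_ea <= 0:
                    raise ValueError("animal-model residual variance became "
                                     "non-positive during iteration")
                state.ratio = state.sigma2_es / state.sigma2_ea

            state.W_mean, state.W_var = compute_weight_matrices(
                state, pb, yv_fitted)
            # Linearization points.  Purebreds: per-record predicted residual
            # variance exp(yv_p-fitted) by default — the per-record point
            # keeps the working variable on the log scale, which matters when
            # hen-level variance heterogeneity is strong; with
            # freeze_linearization the homogeneous s2_ep is used instead,
            # which is more robust when families are small (the per-record
            # point feeds the model's own hen solutions back into the
            # response and can collapse the signal).  Crossbreds: always the
            # frozen homogeneous sire-model residual s2_es — only then does
            # the ratio-scaled deviance have unit slope in true log V_E,
            # which is the point of the sire-model adjustment (a tracking
            # point shrinks the slope toward ratio/(2*ratio - 1)).
            if cfg.freeze_linearization:
                state.sigma2_hat = np.where(pb, state.sigma2_ep,
                                            state.sigma2_es)
            else:
                state.sigma2_hat = np.where(pb, 1.0 / state.W_mean,
                                            state.sigma2_es)
            y_v_new = self._working_responses(state, pb, cb)
            if cfg.damping and it > 0:
                y_v_new = 0.5 * (y_v_new + state.y_v)
            state.y_v = y_v_new

            trace_components.append(fit.theta.copy())
            if prev_theta is not None:
                metric = convergence_metric(prev_theta, fit.theta)
                state.trace.append(metric)
                if metric < cfg.convergence_threshold:
                    converged = True
                    prev_theta = fit.theta
                    break
            prev_theta = fit.theta

        comps = VarianceComponentSet.from_dhglm(fit, state, spec)
        self.components_ = comps
        self.G_ = comps.G_additive
        self.response_names_ = list(spec.genetic.responses)
        self.state_ = state
        self.trace_ = list(state.trace)
        self.n_iter_ = state.iteration
        self.converged_ = converged
        self.result_ = DHGLMFit(
            components=comps, state=state,
            component_trace=trace_components, converged=converged,
            n_iterations=state.iteration,
        )
        return self

    # ------------------------------------------------------------------
    def _update_working(self, state: DHGLMState, pb, cb, first: bool) -> None:
        state.y_v = self._working_responses(state, pb, cb)
        state.W_mean = np.where(pb, 1.0 / state.sigma2_ep,
                                1.0 / state.sigma2_es if cb.any() else 1.0)
        state.W_var = np.where(
            pb, 0.5 * (1.0 - state.h),
            0.5 * (1.0 - state.h) ** 2 / state.ratio ** 2)

    def _working_responses(self, state: DHGLMState, pb, cb) -> np.ndarray:
        phi = compute_phi(state.e, state.h)
        y_v = np.empty(len(phi))
        if pb.any():
            y_v[pb] = working_response_purebred(phi[pb], state.sigma2_hat[pb])
        if cb.any():
            y_v[cb] = working_response_crossbred(
                phi[cb], state.sigma2_hat[cb], state.ratio)
        return y_v

    @staticmethod
    def _initial_components(fit_h: REMLResult, spec_h: MixedModelSpec,
                            has_p: bool, has_c: bool) -> dict[str, np.ndarray]:
        mean_resp = list(spec_h.genetic.responses)
        t_mean = len(mean_resp)
        t = 2 * t_mean
        G = np.zeros((t, t))
        G[:t_mean, :t_mean] = fit_h.components["genetic"]
        G[t_mean:, t_mean:] = 0.01 * np.eye(t_mean)
        init: dict[str, np.ndarray] = {"genetic": G,
                                       "residual": np.ones(t)}
        if has_p:
            pe = np.zeros((2, 2))
            pe[0, 0] = float(np.atleast_2d(fit_h.components["pe"])[0, 0])
            pe[1, 1] = 0.1
            init["pe"] = pe
        if has_c:
            cg = np.zeros((2, 2))
            cg[0, 0] = float(np.atleast_2d(fit_h.components["cage"])[0, 0])
            cg[1, 1] = 0.05
            init["cage"] = cg
        return init


def run_dhglm(table: PhenotypeTable, A: RelationshipMatrix,
              config: DHGLMConfig | None = None) -> DHGLMFit:
    """Functional wrapper over :class:`DHGLM`."""
    cfg = config or DHGLMConfig()
    est = DHGLM(**{f: getattr(cfg, f) for f in (
        "max_outer_iterations", "convergence_threshold", "freeze_ratio",
        "period_mode", "damping", "leverage_guard", "freeze_linearization",
        "fixed_terms_purebred", "fixed_terms_crossbred",
        "inner_max_rounds")})
    est.fit(table, A=A)
    return est.result_


# --------------------------------------------------------------------------
# period analyses with frozen weights
# --------------------------------------------------------------------------

def fit_period_models(
    table: PhenotypeTable,
    A: RelationshipMatrix,
    full_fit: DHGLMFit,
    period_pairs: list[tuple],
    config: DHGLMConfig | None = None,
) -> dict[tuple, dict]:
    """Bivariate-per-trait refits for pairs of laying periods.

    Each pair member is ``(population, period)`` (a bare int means purebred).
    The working responses and weights are frozen at their values from the
    full repeatability-model fit; within-population pairs replace the other
    population's random term by a second term of the same kind (two pe terms
    for purebred pairs, two cage terms for crossbred pairs).  Genetic
    correlations between the two periods are returned with standard errors;
    a non-converged refit is flagged, not raised.
    """
    cfg = config or DHGLMConfig()
    df = table.data
    state = full_fit.state
    out: dict[tuple, dict] = {}
    for pair in period_pairs:
        members = []
        for m in pair:
            members.append((PUREBRED, m) if isinstance(m, int) else tuple(m))
        masks = []
        for popn, per in members:
            mk = ((df["population"] == popn) & (df["period"] == per)).to_numpy()
            if not mk.any():
                raise ValueError(f"empty subset for {popn} period {per}")
            masks.append(mk)

        responses, fixed, groups = [], {}, []
        y_parts, resp_parts, w_parts, row_parts = [], [], [], []
        for k, ((popn, per), mk) in enumerate(zip(members, masks)):
            tagm, tagv = f"mean{k + 1}", f"var{k + 1}"
            responses += [tagm, tagv]
            ft = (cfg.fixed_terms_purebred if popn == PUREBRED
                  else cfg.fixed_terms_crossbred)
            fixed[tagm] = list(ft)
            fixed[tagv] = list(ft)
            factor = "hen" if popn == PUREBRED else "cage"
            gname = "pe" if popn == PUREBRED else "cage"
            groups.append(IndependentTerm(f"{gname}{k + 1}", (tagm, tagv),
                                          factor))
            guard = mk & (state.h <= cfg.leverage_guard)
            rows = np.flatnonzero(mk)
            vrows = np.flatnonzero(guard)
            y_parts += [df["y"].to_numpy()[rows], state.y_v[vrows]]
            w_parts += [state.W_mean[rows], state.W_var[vrows]]
            row_parts += [rows, vrows]
            resp_parts += [np.full(len(rows), 2 * k),
                           np.full(len(vrows), 2 * k + 1)]

        codes = _factor_codes(df, A)
        rows_all = np.concatenate(row_parts)
        data = StackedData(
            y=np.concatenate(y_parts),
            response=np.concatenate(resp_parts),
            weight=np.concatenate(w_parts),
            factors={kk: vv[rows_all] for kk, vv in codes.items()},
        )
        spec = MixedModelSpec(
            responses=responses, fixed_terms=fixed,
            genetic=GeneticTerm(responses=tuple(responses)), groups=groups)
        try:
            fit = estimate_reml(spec, data, A,
                                max_rounds=cfg.inner_max_rounds)
            rho_var, se_var = fit.correlation("genetic", "var1", "var2")
            rho_mean, se_mean = fit.correlation("genetic", "mean1", "mean2")
            out[pair] = dict(
                result=fit, converged=fit.converged,
                genetic_correlation_var=(rho_var, se_var),
                genetic_correlation_mean=(rho_mean, se_mean),
                genetic_variance_var=tuple(
                    4.0 * fit.components["genetic"][i, i] for i in (1, 3)),
            )
        except Exception as exc:  # noqa: BLE001 - flagged per pair
            out[pair] = dict(result=None, converged=False, error=str(exc))
    return out
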