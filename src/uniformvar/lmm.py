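"""Weighted multi-response linear mixed model engine.

Implements REML variance-component estimation (average-information updates
with expectation-maximization fallback), BLUE/BLUP solutions of Henderson's
mixed-model equations, and exact per-record leverages (diagonal of the hat
matrix) for models of the form

    y = X b + Z_g u_g + sum_k Z_k u_k + e

over a stack of named responses, where

* ``u_g`` is a genetic (sire) term spanning a subset of responses with
  covariance ``Gamma_g (x) A`` (``A`` a numerator relationship matrix;
  ``Gamma_g`` is on the *sire* scale, i.e. one quarter of the additive-scale
  covariance),
* each ``u_k`` is an independent-levels term (permanent environment, cage)
  spanning a subset of responses with covariance ``Gamma_k (x) I``,
* the residual is diagonal: record *i* of response *r* has variance
  ``sigma2_r / w_i`` with known weight ``w_i`` and free scaling variance
  ``sigma2_r``.

The mixed-model equations are solved by absorbing the independent-levels
blocks (block-diagonal, one small block per level) into the fixed + genetic
part, leaving a dense Schur complement of modest dimension.  All REML traces
(score, EM updates, leverages) are evaluated exactly from the partitioned
inverse of the coefficient matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

__all__ = [
    "MixedModelSpec", "GeneticTerm", "IndependentTerm", "StackedData",
    "REMLResult", "EstimabilityError", "estimate_reml", "solve_blup",
    "compute_leverages",
]


class EstimabilityError(ValueError):
    """Model is not identifiable on the data supplied."""


# --------------------------------------------------------------------------
# model specification containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticTerm:
    """Sire genetic term with covariance Gamma (x) A over ``responses``."""

    responses: tuple[str, ...]
    factor: str = "sire"


@dataclass(frozen=True)
class IndependentTerm:
    """Independent-levels term (pe, cage) with covariance Gamma (x) I."""

    name: str
    responses: tuple[str, ...]
    factor: str


@dataclass
class MixedModelSpec:
    """Responses, fixed terms per response, and random-term structure."""

    responses: list[str]
    fixed_terms: dict[str, list[str]]
    genetic: GeneticTerm | None = None
    groups: list[IndependentTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.responses:
            self.fixed_terms.setdefault(r, [])
        if self.genetic is not None:
            for r in self.genetic.responses:
                if r not in self.responses:
                    raise ValueError(f"genetic term spans unknown response {r!r}")
        for g in self.groups:
            for r in g.responses:
                if r not in self.responses:
                    raise ValueError(f"term {g.name!r} spans unknown response {r!r}")


@dataclass
class StackedData:
    """Stacked observation vectors for a multi-response fit.

    ``response`` holds integer codes into ``MixedModelSpec.responses``;
    ``factors`` maps factor names to integer level codes per stacked row
    (-1 where the factor does not apply to that row).  The genetic factor's
    codes index the subjects of the relationship matrix.
    """

    y: np.ndarray
    response: np.ndarray
    weight: np.ndarray
    factors: dict[str, np.ndarray]
    factor_labels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.y)
        self.y = np.asarray(self.y, dtype=float)
        self.response = np.asarray(self.response, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.response) == len(self.weight) == n):
            raise ValueError("stacked arrays have unequal lengths")
        if np.any(self.weight <= 0):
            i = int(np.flatnonzero(self.weight <= 0)[0])
            raise ValueError(f"non-positive weight at stacked row {i}")


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------

@dataclass
class REMLResult:
    """Variance components with sampling covariances, solutions, diagnostics.

    ``components`` maps term name ('genetic', group names, 'residual') to the
    estimated covariance matrix (sire scale for 'genetic') or the per-response
    scaling-variance vector.  ``sampling_cov`` is the inverse average-
    information matrix over ``param_names`` (same scales).
    """

    spec: MixedModelSpec
    components: dict[str, np.ndarray]
    param_names: list[str]
    theta: np.ndarray
    sampling_cov: np.ndarray
    loglik: float
    converged: bool
    n_rounds: int
    message: str = ""
    n_psd_projections: int = 0
    solutions: dict[str, np.ndarray] | None = None
    fixed_labels: dict[str, list[str]] | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    leverages: np.ndarray | None = None

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def se(self, name: str) -> float:
        i = self.param_index(name)
        return float(np.sqrt(max(self.sampling_cov[i, i], 0.0)))

    def cov(self, name1: str, name2: str) -> float:
        return float(self.sampling_cov[self.param_index(name1),
                                       self.param_index(name2)])

    def correlation(self, term: str, r1: str, r2: str) -> tuple[float, float]:
        """Correlation between responses ``r1``/``r2`` of a covariance term,
        with a delta-method standard error from the sampling covariances."""
        c = self.components[term]
        resp = (self.spec.genetic.responses if term == "genetic"
                else next(g for g in self.spec.groups if g.name == term).responses)
        i, j = resp.index(r1), resp.index(r2)
        v1, v2, cv = c[i, i], c[j, j], c[i, j]
        if v1 <= 0 or v2 <= 0:
            return np.nan, np.nan
        rho = cv / np.sqrt(v1 * v2)
        names = [_param_name(term, resp, i, j), _param_name(term, resp, i, i),
                 _param_name(term, resp, j, j)]
        grad = np.array([1.0 / np.sqrt(v1 * v2),
                         -0.5 * cv / (v1 ** 1.5 * np.sqrt(v2)),
                         -0.5 * cv / (np.sqrt(v1) * v2 ** 1.5)])
        idx = [self.param_index(n) for n in names]
        V = self.sampling_cov[np.ix_(idx, idx)]
        se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
        return float(rho), se


def _param_name(term: str, responses: tuple[str, ...] | list[str],
                i: int, j: int) -> str:
    a, b = sorted((responses[i], responses[j]))
    return f"{term}({a},{b})"


# --------------------------------------------------------------------------
# covariance-block helpers
# --------------------------------------------------------------------------

def bend_to_psd(M: np.ndarray, floor_frac: float = 1e-4) -> tuple[np.ndarray, bool]:
    """Project a symmetric covariance matrix toward PSD, preserving scales.

    Bending happens on the correlation scale: eigenvalues of the correlation
    matrix are floored at ``floor_frac`` and the variances put back.  Blocks
    here mix traits whose variances differ by five orders of magnitude
    (trait means vs log variances); flooring eigenvalues of the raw
    covariance would let the dominant directions leak variance into the
    small-scale traits.  Returns (matrix, bent?).
    """
    M = 0.5 * (M + M.T)
    d = np.sqrt(np.maximum(np.diag(M), 1e-300))
    R = M / np.outer(d, d)
    w, V = np.linalg.eigh(R)
    if w[0] >= floor_frac:
        return M, False
    w = np.maximum(w, floor_frac)
    R = (V * w) @ V.T
    # renormalize the diagonal to exactly 1 before restoring scales
    s = np.sqrt(np.diag(R))
    R = R / np.outer(s, s)
    return R * np.outer(d, d), True


def balanced_inv_logdet(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a covariance block via its correlation
    decomposition.  Blocks mixing trait-mean and log-variance scales are far
    better conditioned on the correlation scale."""
    M = np.atleast_2d(M)
    d = np.sqrt(np.maximum(np.diag(M), 1e-300))
    R = M / np.outer(d, d)
    w, V = np.linalg.eigh(R)
    w = np.maximum(w, 1e-12)
    Rinv = (V / w) @ V.T
    logdet = float(np.sum(np.log(w)) + 2.0 * np.sum(np.log(d)))
    return Rinv / np.outer(d, d), logdet


def _pack(blocks: list[np.ndarray], resid: np.ndarray) -> np.ndarray:
    out = []
    for B in blocks:
        t = B.shape[0]
        out.extend(B[i, j] for i in range(t) for j in range(i, t))
    out.extend(resid)
    return np.array(out, dtype=float)


# --------------------------------------------------------------------------
# the engine
# --------------------------------------------------------------------------

class _Workspace:
    """Precomputed design structure for repeated factorizations."""

    def __init__(self, spec: MixedModelSpec, data: StackedData,
                 A: RelationshipMatrix | None):
        self.spec = spec
        self.data = data
        self.n = len(data.y)
        self.t = len(spec.responses)
        self.resp = data.response
        if self.resp.min() < 0 or self.resp.max() >= self.t:
            raise ValueError("response codes out of range")
        self.n_r = np.bincount(self.resp, minlength=self.t)
        for r, name in enumerate(spec.responses):
            yr = data.y[self.resp == r]
            if len(yr) == 0:
                raise EstimabilityError(f"response {name!r} has no records")
            if len(yr) > 1 and np.ptp(yr) == 0.0:
                raise EstimabilityError(f"response {name!r} is constant")

        # ---- part-1 column layout: fixed effects then genetic -------------
        cols_rows: list[np.ndarray] = []
        cols_idx: list[np.ndarray] = []
        self.fixed_labels: dict[str, list[str]] = {}
        J1_cols: list[np.ndarray] = []  # per "slot", -1 padded
        col = 0
        rows_all = np.arange(self.n)
        # intercept per response
        icept = np.full(self.n, -1, dtype=np.int64)
        for r, name in enumerate(spec.responses):
            m = self.resp == r
            icept[m] = col
            self.fixed_labels[name] = [f"{name}:intercept"]
            col += 1
        # remember response -> intercept col for labeling
        self._icept_cols = {name: i for i, name in enumerate(spec.responses)}
        cols_rows.append(rows_all)
        cols_idx.append(icept)
        J1_cols.append(icept)

        max_fac = max((len(v) for v in spec.fixed_terms.values()), default=0)
        for slot in range(max_fac):
            slot_col = np.full(self.n, -1, dtype=np.int64)
            for r, name in enumerate(spec.responses):
                terms = spec.fixed_terms[name]
                if slot >= len(terms):
                    continue
                fac = terms[slot]
                codes = np.asarray(data.factors[fac], dtype=np.int64)
                m = (self.resp == r) & (codes >= 0)
                if not m.any():
                    continue
                levels = np.unique(codes[m])
                ref = levels[0]  # first observed level = reference
                lut = {lv: -1 for lv in levels}
                lab_list = data.factor_labels.get(fac)
                for k, lv in enumerate(levels[1:]):
                    lut[lv] = col + k
                    lab = lab_list[lv] if lab_list is not None else lv
                    self.fixed_labels[name].append(f"{name}:{fac}={lab}")
                mapped = np.array([lut[c] for c in codes[m]], dtype=np.int64)
                slot_col[np.flatnonzero(m)] = mapped
                col += len(levels) - 1
            J1_cols.append(slot_col)
            mrows = slot_col >= 0
            cols_rows.append(np.flatnonzero(mrows))
            cols_idx.append(slot_col[mrows])
        self.p = col

        # genetic columns, response-major
        self.A = A
        self.gen = spec.genetic
        if self.gen is not None:
            if A is None:
                raise ValueError("genetic term requires a relationship matrix")
            self.q_g = len(A)
            self.t_g = len(self.gen.responses)
            self.g_resp_idx = {spec.responses.index(r): k
                               for k, r in enumerate(self.gen.responses)}
            sire = np.asarray(data.factors[self.gen.factor], dtype=np.int64)
            gcol = np.full(self.n, -1, dtype=np.int64)
            for r, k in self.g_resp_idx.items():
                m = (self.resp == r) & (sire >= 0)
                gcol[m] = self.p + k * self.q_g + sire[m]
            J1_cols.append(gcol)
            mrows = gcol >= 0
            cols_rows.append(np.flatnonzero(mrows))
            cols_idx.append(gcol[mrows])
            self.Ainv = np.linalg.inv(A.A)
            sign, self.logdet_A = np.linalg.slogdet(A.A)
            if sign <= 0:
                raise ValueError("relationship matrix is singular")
            self.m1 = self.p + self.t_g * self.q_g
        else:
            self.q_g = self.t_g = 0
            self.Ainv = None
            self.logdet_A = 0.0
            self.m1 = self.p

        self.J1 = np.stack(J1_cols, axis=1)  # (n, k1), -1 padded

        rows = np.concatenate(cols_rows)
        cidx = np.concatenate(cols_idx)
        self.T1 = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cidx)), shape=(self.n, self.m1))

        # ---- part-2 (absorbed independent-levels groups) -------------------
        self.groups = spec.groups
        self.g2: list[dict] = []
        off = 0
        j2 = np.full(self.n, -1, dtype=np.int64)
        grp_of_row = np.full(self.n, -1, dtype=np.int64)
        for gi, g in enumerate(self.groups):
            codes = np.asarray(data.factors[g.factor], dtype=np.int64)
            t_k = len(g.responses)
            ridx = {spec.responses.index(r): k for k, r in enumerate(g.responses)}
            tcol = np.full(self.n, -1, dtype=np.int64)
            for r, k in ridx.items():
                m = (self.resp == r) & (codes >= 0)
                tcol[m] = k
            m = tcol >= 0
            L = int(codes[m].max()) + 1 if m.any() else 0
            if L == 0:
                raise EstimabilityError(f"term {g.name!r} has no observations")
            j2[m] = off + codes[m] * t_k + tcol[m]
            grp_of_row[m] = gi
            self.g2.append(dict(name=g.name, t=t_k, L=L, off=off,
                                tcol=tcol, codes=codes))
            off += L * t_k
        self.m2 = off
        self.j2 = j2
        self.grp_of_row = grp_of_row
        if self.m2:
            m = j2 >= 0
            self.T2 = sp.csr_matrix(
                (np.ones(int(m.sum())), (np.flatnonzero(m), j2[m])),
                shape=(self.n, self.m2))
        else:
            self.T2 = None

        # ---- per-response precomputed data products ------------------------
        self.C11_r, self.C12_r, self.d22_r = [], [], []
        self.r1_r, self.r2_r, self.yy_r = [], [], []
        w = data.weight
        for r in range(self.t):
            m = (self.resp == r).astype(float) * w
            Wm = sp.diags(m)
            T1W = Wm @ self.T1
            self.C11_r.append((self.T1.T @ T1W).toarray())
            self.r1_r.append(self.T1.T @ (m * data.y))
            self.yy_r.append(float(np.sum(m * data.y ** 2)))
            if self.m2:
                self.C12_r.append((self.T1.T @ (Wm @ self.T2)).tocsr())
                self.d22_r.append(np.bincount(
                    j2[j2 >= 0], weights=m[j2 >= 0], minlength=self.m2))
                self.r2_r.append(np.bincount(
                    j2[j2 >= 0], weights=(m * data.y)[j2 >= 0],
                    minlength=self.m2))

        # ---- fixed-effect rank check (pivoted QR on the fixed block) -------
        F = sum(self.C11_r)[:self.p, :self.p]
        if self.p:
            _, Rq, piv = sla.qr(F, pivoting=True)
            d = np.abs(np.diag(Rq))
            tol = d.max() * max(F.shape) * np.finfo(float).eps * 100
            rank = int(np.sum(d > tol))
            if rank < self.p:
                dropped = sorted(piv[rank:])
                labels = [lab for name in spec.responses
                          for lab in self.fixed_labels[name]]
                names = [labels[i] for i in dropped if i < len(labels)]
                warnings.warn(f"aliased fixed-effect levels dropped: {names}",
                              stacklevel=2)
                self._aliased = np.array(dropped, dtype=np.int64)
            else:
                self._aliased = np.empty(0, dtype=np.int64)
        else:
            self._aliased = np.empty(0, dtype=np.int64)

    # ------------------------------------------------------------------
    def param_layout(self, ):
        names: list[str] = []
        if self.gen is not None:
            rs = self.gen.responses
            for i in range(self.t_g):
                for j in range(i, self.t_g):
                    names.append(_param_name("genetic", rs, i, j))
        for g in self.groups:
            rs = g.responses
            for i in range(len(rs)):
                for j in range(i, len(rs)):
                    names.append(_param_name(g.name, rs, i, j))
        names.extend(f"residual({r})" for r in self.spec.responses)
        return names

    def unpack(self, theta: np.ndarray):
        """theta -> (Gamma_g, [Gamma_k...], sigma2) matrices."""
        pos = 0
        Gg = None
        if self.gen is not None:
            t = self.t_g
            Gg = np.zeros((t, t))
            for i in range(t):
                for j in range(i, t):
                    Gg[i, j] = Gg[j, i] = theta[pos]
                    pos += 1
        Gks = []
        for g in self.g2:
            t = g["t"]
            Gk = np.zeros((t, t))
            for i in range(t):
                for j in range(i, t):
                    Gk[i, j] = Gk[j, i] = theta[pos]
                    pos += 1
            Gks.append(Gk)
        sigma2 = theta[pos:pos + self.t].copy()
        return Gg, Gks, sigma2

    def project(self, theta: np.ndarray, floors: np.ndarray) -> tuple[np.ndarray, bool]:
        """Bend covariance blocks to PSD and floor variances; note if bent."""
        Gg, Gks, sigma2 = self.unpack(theta)
        bent = False
        blocks = []
        k = 0
        if Gg is not None:
            fl = floors[:self.t_g]
            Gg = Gg.copy()
            d = np.diag(Gg).copy()
            if np.any(d < fl):
                Gg[np.diag_indices_from(Gg)] = np.maximum(d, fl)
                bent = True
            Gg, b = bend_to_psd(Gg)
            bent |= b
            blocks.append(Gg)
            k += self.t_g
        for g, Gk in zip(self.g2, Gks):
            fl = floors[k:k + g["t"]]
            Gk = Gk.copy()
            d = np.diag(Gk).copy()
            if np.any(d < fl):
                Gk[np.diag_indices_from(Gk)] = np.maximum(d, fl)
                bent = True
            Gk, b = bend_to_psd(Gk)
            bent |= b
            blocks.append(Gk)
            k += g["t"]
        fl = floors[k:]
        if np.any(sigma2 < fl):
            sigma2 = np.maximum(sigma2, fl)
            bent = True
        return _pack(blocks, sigma2), bent

    # ------------------------------------------------------------------
    def factorize(self, theta: np.ndarray, full: bool = True):
        """Factorize at ``theta``; ``full=False`` computes only solutions and
        the log-likelihood (line-search candidates), deferring the
        partitioned-inverse pieces to :meth:`complete`."""
        Gg, Gks, sigma2 = self.unpack(theta)
        c = 1.0 / sigma2
        rinv = self.data.weight / sigma2[self.resp]

        C11 = np.zeros((self.m1, self.m1))
        for r in range(self.t):
            C11 += c[r] * self.C11_r[r]
        r1 = sum(c[r] * self.r1_r[r] for r in range(self.t))
        logdet_G = 0.0
        if self.gen is not None:
            Gg_inv, ld = balanced_inv_logdet(Gg)
            C11[self.p:, self.p:] += np.kron(Gg_inv, self.Ainv)
            logdet_G += self.q_g * ld + self.t_g * self.logdet_A
        else:
            Gg_inv = None

        # aliased fixed columns: pin with a huge diagonal (effect forced to 0)
        if len(self._aliased):
            C11[self._aliased, self._aliased] += 1e12

        grp_data = []
        if self.m2:
            C12 = sum(c[r] * self.C12_r[r] for r in range(self.t)).toarray()
            d22 = sum(c[r] * self.d22_r[r] for r in range(self.t))
            r2 = sum(c[r] * self.r2_r[r] for r in range(self.t))
            C_red = C11.copy()
            r1_red = r1.copy()
            for g, Gk in zip(self.g2, Gks):
                L, t_k, off = g["L"], g["t"], g["off"]
                sl = slice(off, off + L * t_k)
                Gk_inv, ldG = balanced_inv_logdet(Gk)
                D = np.zeros((L, t_k, t_k))
                idx = np.arange(t_k)
                D[:, idx, idx] = d22[sl].reshape(L, t_k)
                D += Gk_inv[None, :, :]
                Dinv = np.linalg.inv(D)
                sign, ldD = np.linalg.slogdet(D)
                logdet_C22 = float(ldD.sum())
                logdet_G += L * ldG
                B = C12[:, sl].reshape(self.m1, L, t_k)
                S = np.matmul(B.transpose(1, 0, 2), Dinv).transpose(1, 0, 2)
                C_red -= S.reshape(self.m1, -1) @ B.reshape(self.m1, -1).T
                r2g = r2[sl].reshape(L, t_k)
                r1_red -= S.reshape(self.m1, -1) @ r2g.ravel()
                grp_data.append(dict(g=g, Gk=Gk, Gk_inv=Gk_inv, D=D, Dinv=Dinv,
                                     B=B, S=S, r2=r2g, logdet_C22=logdet_C22))
        else:
            C_red = C11
            r1_red = r1

        try:
            cf = sla.cho_factor(C_red, lower=True)
        except np.linalg.LinAlgError as exc:
            raise EstimabilityError(
                "mixed-model equations are singular (non-identifiable model)"
            ) from exc
        logdet_Cred = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        alpha1 = sla.cho_solve(cf, r1_red)

        logdet_C = logdet_Cred
        alpha2_full = np.zeros(self.m2)
        for gd in grp_data:
            g = gd["g"]
            L, t_k, off = g["L"], g["t"], g["off"]
            rhs = (gd["r2"].ravel()
                   - gd["B"].reshape(self.m1, -1).T @ alpha1).reshape(L, t_k)
            gd["alpha2"] = np.matmul(gd["Dinv"], rhs[:, :, None])[:, :, 0]
            alpha2_full[off:off + L * t_k] = gd["alpha2"].ravel()
            logdet_C += gd["logdet_C22"]

        # residuals and Py
        fit = self.T1 @ alpha1
        if self.m2:
            fit = fit + self.T2 @ alpha2_full
        ehat = self.data.y - fit
        Py = rinv * ehat
        yPy = float(self.data.y @ Py)

        logdet_R = float(np.sum(np.log(sigma2[self.resp] / self.data.weight)))
        loglik = -0.5 * (logdet_R + logdet_G + logdet_C + yPy)

        F = dict(theta=theta, Gg=Gg, Gg_inv=Gg_inv, Gks=Gks, sigma2=sigma2,
                 rinv=rinv, cf=cf, alpha1=alpha1, alpha2=alpha2_full,
                 grp=grp_data, ehat=ehat, Py=Py, fitted=fit,
                 loglik=loglik, complete=False)
        if full:
            self.complete(F)
        return F

    def complete(self, F) -> None:
        """Partitioned-inverse pieces, traces and leverages for an accepted
        factorization (score, AI, EM and hat-diagonal all need these)."""
        if F["complete"]:
            return
        cf, grp_data, rinv = F["cf"], F["grp"], F["rinv"]
        Cinv11 = sla.cho_solve(cf, np.eye(self.m1))
        for gd in grp_data:
            L, t_k = gd["g"]["L"], gd["g"]["t"]
            Mg = sla.cho_solve(cf, gd["B"].reshape(self.m1, -1)
                               ).reshape(self.m1, L, t_k)
            # per-level blocks of B' C_red^{-1} B (batched over levels)
            Gl = np.matmul(gd["B"].transpose(1, 2, 0), Mg.transpose(1, 0, 2))
            C22f = gd["Dinv"] + np.matmul(
                np.matmul(gd["Dinv"], Gl), gd["Dinv"])
            gd["C22full"] = C22f
            gd["C12til"] = -np.matmul(Mg.transpose(1, 0, 2), gd["Dinv"]
                                      ).transpose(1, 0, 2)
            gd["Q"] = C22f.sum(axis=0)

        Qg = ug = None
        if self.gen is not None:
            Qg = np.zeros((self.t_g, self.t_g))
            Cg = Cinv11[self.p:, self.p:]
            for i in range(self.t_g):
                for j in range(self.t_g):
                    blk = Cg[i * self.q_g:(i + 1) * self.q_g,
                             j * self.q_g:(j + 1) * self.q_g]
                    Qg[i, j] = float(np.sum(self.Ainv * blk))
            ug = F["alpha1"][self.p:].reshape(self.t_g, self.q_g)

        h = self._leverages(Cinv11, grp_data, rinv)
        F.update(Cinv11=Cinv11, Qg=Qg, ug=ug, h=h,
                 sum_h_r=np.bincount(self.resp, weights=h, minlength=self.t),
                 complete=True)

    # ------------------------------------------------------------------
    def _leverages(self, Cinv11, grp_data, rinv) -> np.ndarray:
        """h_i = rinv_i * t_i' C^{-1} t_i via padded gathers."""
        m1 = self.m1
        Cp = np.zeros((m1 + 1, m1 + 1))
        Cp[:m1, :m1] = Cinv11
        J = np.where(self.J1 < 0, m1, self.J1)
        k = J.shape[1]
        quad = np.zeros(self.n)
        for a in range(k):
            quad += Cp[J[:, a], J[:, a]]
            for b in range(a + 1, k):
                quad += 2.0 * Cp[J[:, a], J[:, b]]
        for gd in grp_data:
            g = gd["g"]
            L, t_k = g["L"], g["t"]
            rows = np.flatnonzero(self.grp_of_row == self._gi(gd))
            lev = g["codes"][rows]
            tc = g["tcol"][rows]
            # cross part: 2 * sum_a C12til[J[:,a], level, tcol]
            C12t = gd["C12til"]  # (m1, L, t)
            C12tp = np.zeros((m1 + 1, L, t_k))
            C12tp[:m1] = C12t
            cross = np.zeros(len(rows))
            for a in range(k):
                cross += C12tp[J[rows, a], lev, tc]
            quad[rows] += 2.0 * cross
            quad[rows] += gd["C22full"][lev, tc, tc]
        return rinv * quad

    def _gi(self, gd) -> int:
        return self.g2.index(gd["g"])

    # ------------------------------------------------------------------
    def score(self, F) -> np.ndarray:
        s: list[float] = []
        if self.gen is not None:
            Gi = F["Gg_inv"]
            Q = F["Qg"]
            M2 = Gi @ Q @ Gi
            V = Gi @ F["ug"] @ self.Ainv  # v = Psi u, (t_g, q)
            AV = V @ self.A.A             # A v  (t_g, q)
            for i in range(self.t_g):
                for j in range(i, self.t_g):
                    if i == j:
                        trP = self.q_g * Gi[i, i] - M2[i, i]
                        quad = float(V[i] @ AV[i])
                    else:
                        trP = 2.0 * (self.q_g * Gi[i, j] - M2[i, j])
                        quad = 2.0 * float(V[i] @ AV[j])
                    s.append(-0.5 * (trP - quad))
        for gd in F["grp"]:
            g = gd["g"]
            Gi = gd["Gk_inv"]
            Q = gd["Q"]
            M2 = Gi @ Q @ Gi
            V = gd["alpha2"] @ Gi  # (L, t)
            L, t_k = g["L"], g["t"]
            for i in range(t_k):
                for j in range(i, t_k):
                    if i == j:
                        trP = L * Gi[i, i] - M2[i, i]
                        quad = float(V[:, i] @ V[:, i])
                    else:
                        trP = 2.0 * (L * Gi[i, j] - M2[i, j])
                        quad = 2.0 * float(V[:, i] @ V[:, j])
                    s.append(-0.5 * (trP - quad))
        Py = F["Py"]
        for r in range(self.t):
            m = self.resp == r
            trP = (self.n_r[r] - F["sum_h_r"][r]) / F["sigma2"][r]
            quad = float(np.sum(Py[m] ** 2 / self.data.weight[m]))
            s.append(-0.5 * (trP - quad))
        return np.array(s)

    # ------------------------------------------------------------------
    def _ai_vectors(self, F) -> np.ndarray:
        """Columns f_j = dV_j @ Py for every parameter."""
        cols: list[np.ndarray] = []
        resp = self.resp
        if self.gen is not None:
            V = F["Gg_inv"] @ F["ug"] @ self.Ainv
            AV = V @ self.A.A
            sire = np.asarray(self.data.factors[self.gen.factor], np.int64)
            rmap = np.full(self.t, -1, np.int64)
            for r, kk in self.g_resp_idx.items():
                rmap[r] = kk
            trow = rmap[resp]
            ok = (trow >= 0) & (sire >= 0)
            for i in range(self.t_g):
                for j in range(i, self.t_g):
                    W = np.zeros((self.t_g, self.q_g))
                    W[i] += AV[j]
                    if i != j:
                        W[j] += AV[i]
                    f = np.zeros(self.n)
                    f[ok] = W[trow[ok], sire[ok]]
                    cols.append(f)
        for gd in F["grp"]:
            g = gd["g"]
            Gi = gd["Gk_inv"]
            V = gd["alpha2"] @ Gi
            codes, tcol = g["codes"], g["tcol"]
            ok = tcol >= 0
            t_k = g["t"]
            for i in range(t_k):
                for j in range(i, t_k):
                    W = np.zeros_like(V)
                    W[:, i] += V[:, j]
                    if i != j:
                        W[:, j] += V[:, i]
                    f = np.zeros(self.n)
                    f[ok] = W[codes[ok], tcol[ok]]
                    cols.append(f)
        Py = F["Py"]
        for r in range(self.t):
            f = np.zeros(self.n)
            m = resp == r
            f[m] = Py[m] / self.data.weight[m]
            cols.append(f)
        return np.stack(cols, axis=1)

    def apply_P(self, F, Fmat: np.ndarray) -> np.ndarray:
        """P @ f for each column f (multiple right-hand sides)."""
        rinv = F["rinv"]
        RF = rinv[:, None] * Fmat
        rhs1 = np.asarray(self.T1.T @ RF)
        out = Fmat.copy()
        if self.m2:
            rhs2 = np.asarray(self.T2.T @ RF)
            rhs1_red = rhs1.copy()
            for gd in F["grp"]:
                g = gd["g"]
                L, t_k, off = g["L"], g["t"], g["off"]
                r2g = rhs2[off:off + L * t_k].reshape(L, t_k, -1)
                rhs1_red -= np.einsum("als,lsj->aj", gd["S"], r2g)
            a1 = sla.cho_solve(F["cf"], rhs1_red)
            fit = np.asarray(self.T1 @ a1)
            for gd in F["grp"]:
                g = gd["g"]
                L, t_k, off = g["L"], g["t"], g["off"]
                r2g = rhs2[off:off + L * t_k].reshape(L, t_k, -1)
                rhs = r2g - np.einsum("alt,aj->ltj", gd["B"], a1)
                a2 = np.einsum("lts,lsj->ltj", gd["Dinv"], rhs)
                fit += np.asarray(self.T2[:, off:off + L * t_k]
                                  @ a2.reshape(L * t_k, -1))
        else:
            a1 = sla.cho_solve(F["cf"], rhs1)
            fit = np.asarray(self.T1 @ a1)
        return rinv[:, None] * (Fmat - fit)

    def ai_matrix(self, F) -> np.ndarray:
        Fmat = self._ai_vectors(F)
        PF = self.apply_P(F, Fmat)
        AI = 0.5 * (Fmat.T @ PF)
        return 0.5 * (AI + AI.T)

    # ------------------------------------------------------------------
    def em_update(self, F) -> np.ndarray:
        blocks: list[np.ndarray] = []
        if self.gen is not None:
            U = F["ug"]  # (t_g, q)
            Gnew = (U @ self.Ainv @ U.T + F["Qg"]) / self.q_g
            blocks.append(0.5 * (Gnew + Gnew.T))
        for gd in F["grp"]:
            U = gd["alpha2"]  # (L, t)
            L = gd["g"]["L"]
            Gnew = (U.T @ U + gd["Q"]) / L
            blocks.append(0.5 * (Gnew + Gnew.T))
        sigma2 = np.empty(self.t)
        for r in range(self.t):
            m = self.resp == r
            ewe = float(np.sum(self.data.weight[m] * F["ehat"][m] ** 2))
            sigma2[r] = (ewe + F["sigma2"][r] * F["sum_h_r"][r]) / self.n_r[r]
        return _pack(blocks, sigma2)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def default_init(spec: MixedModelSpec, data: StackedData) -> dict[str, np.ndarray]:
    """Crude starting components: split each response's weighted variance."""
    t = len(spec.responses)
    v = np.empty(t)
    for r in range(t):
        m = data.response == r
        v[r] = max(float(np.var(data.y[m] * np.sqrt(data.weight[m]))), 1e-8)
    comp: dict[str, np.ndarray] = {"residual": 0.6 * v}
    if spec.genetic is not None:
        idx = [spec.responses.index(r) for r in spec.genetic.responses]
        comp["genetic"] = np.diag(0.05 * v[idx])
    for g in spec.groups:
        idx = [spec.responses.index(r) for r in g.responses]
        comp[g.name] = np.diag(0.2 * v[idx])
    return comp


def _theta_from_components(ws: _Workspace,
                           comp: dict[str, np.ndarray]) -> np.ndarray:
    blocks = []
    if ws.gen is not None:
        blocks.append(np.atleast_2d(np.asarray(comp["genetic"], dtype=float)))
    for g in ws.groups:
        blocks.append(np.atleast_2d(np.asarray(comp[g.name], dtype=float)))
    return _pack(blocks, np.asarray(comp["residual"], dtype=float))


def _components_from_theta(ws: _Workspace, theta: np.ndarray):
    Gg, Gks, sigma2 = ws.unpack(theta)
    comp: dict[str, np.ndarray] = {"residual": sigma2}
    if Gg is not None:
        comp["genetic"] = Gg
    for g, Gk in zip(ws.groups, Gks):
        comp[g.name] = Gk
    return comp


def estimate_reml(
    spec: MixedModelSpec,
    data: StackedData,
    A: RelationshipMatrix | None = None,
    init: dict[str, np.ndarray] | None = None,
    max_rounds: int = 200,
    tol_loglik: float = 1e-8,
    tol_grad: float = 1e-4,
    em_warmup: int = 2,
    keep_solutions: bool = True,
) -> REMLResult:
    """AI-REML with EM fallback; sampling variances from the inverse AI matrix.

    ``init`` maps term names to starting covariance matrices ('genetic' on the
    sire scale) and 'residual' to per-response scaling variances.  Convergence:
    relative log-likelihood change below ``tol_loglik`` and scale-adjusted
    gradient below ``tol_grad``; non-convergence is flagged, never silent.
    """
    ws = _Workspace(spec, data, A)
    comp0 = dict(default_init(spec, data))
    if init:
        comp0.update(init)
    theta = _theta_from_components(ws, comp0)
    names = ws.param_layout()

    # per-parameter variance floors: tiny fractions of starting scale
    scales = np.maximum(np.abs(theta), 1e-8)
    Gg0, Gks0, s20 = ws.unpack(theta)
    floors = []
    if ws.gen is not None:
        floors.append(np.maximum(np.abs(np.diag(Gg0)), 1e-6) * 1e-6)
    for Gk in Gks0:
        floors.append(np.maximum(np.abs(np.diag(Gk)), 1e-6) * 1e-6)
    floors.append(np.maximum(np.abs(s20), 1e-8) * 1e-8)
    floors = np.concatenate(floors)

    theta, _ = ws.project(theta, floors)
    F = ws.factorize(theta)
    converged = False
    message = ""
    n_rounds = 0
    n_small = 0  # consecutive negligible log-likelihood changes (boundary)
    n_bent = 0   # accepted steps that required a PSD projection
    AI = None
    for it in range(max_rounds):
        n_rounds = it + 1
        score = ws.score(F)
        AI = ws.ai_matrix(F)
        gscale = np.maximum(np.abs(theta), scales * 1e-3)
        gnorm = float(np.max(np.abs(score * gscale)))
        if it < em_warmup:
            # conservative EM start: aggressive first AI steps can slam
            # variance components onto the zero boundary, which is an
            # absorbing state for EM and a frequent inferior local mode
            cand = ws.em_update(F)
            cand, _ = ws.project(cand, floors)
            Fc = ws.factorize(cand)
            dll = abs(Fc["loglik"] - F["loglik"]) / (1.0 + abs(Fc["loglik"]))
            theta, F = cand, Fc
            continue
        # AI step with EM fallback
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(AI)), score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(AI, score, rcond=None)[0]
        # trust region: no parameter may move more than a few times its
        # current magnitude in one round (AI steps near singular information
        # matrices can otherwise diverge)
        limit = 4.0 * (np.abs(theta) + 0.25 * scales)
        delta = np.clip(delta, -limit, limit)
        # back-track along the AI direction; fall back to EM if no step helps
        tol_dec = 1e-10 * (1 + abs(F["loglik"]))
        cand = Fc = None
        for lam in (1.0, 0.5, 0.25, 0.1, 0.05):
            c, bent = ws.project(theta + lam * delta, floors)
            Ft = ws.factorize(c, full=False)
            if Ft["loglik"] >= F["loglik"] - tol_dec:
                cand, Fc = c, Ft
                break
        if cand is None:
            cand = ws.em_update(F)
            cand, bent = ws.project(cand, floors)
            Fc = ws.factorize(cand, full=False)
        n_bent += int(bent)
        ws.complete(Fc)
        dll = abs(Fc["loglik"] - F["loglik"]) / (1.0 + abs(Fc["loglik"]))
        rel_step = float(np.max(np.abs(cand - theta) / np.maximum(scales, 1e-12)))
        theta, F = cand, Fc
        n_small = n_small + 1 if dll < tol_loglik else 0
        if dll < tol_loglik and (gnorm < tol_grad or rel_step < 1e-7):
            converged = True
            break
        if n_small >= 3:
            # likelihood is stationary but a component sits on the boundary
            # of the parameter space, where the gradient cannot vanish
            converged = True
            message = "converged at a parameter-space boundary"
            break
    if not converged:
        message = f"REML did not converge in {max_rounds} rounds"

    AI = ws.ai_matrix(F)
    try:
        samp = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        samp = np.linalg.pinv(AI)

    comp = _components_from_theta(ws, theta)
    res = REMLResult(
        spec=spec, components=comp, param_names=names, theta=theta,
        sampling_cov=samp, loglik=F["loglik"], converged=converged,
        n_rounds=n_rounds, message=message, n_psd_projections=n_bent,
    )
    if keep_solutions:
        _attach_solutions(res, ws, F)
    return res


def _attach_solutions(res: REMLResult, ws: _Workspace, F) -> None:
    sol: dict[str, np.ndarray] = {"fixed": F["alpha1"][:ws.p]}
    if ws.gen is not None:
        sol["genetic"] = F["alpha1"][ws.p:].reshape(ws.t_g, ws.q_g)
    for gd in F["grp"]:
        sol[gd["g"]["name"]] = gd["alpha2"]
    res.solutions = sol
    res.fixed_labels = ws.fixed_labels
    res.fitted = F["fitted"]
    res.residuals = F["ehat"]
    res.leverages = F["h"]


def solve_blup(
    spec: MixedModelSpec,
    data: StackedData,
    A: RelationshipMatrix | None,
    components: dict[str, np.ndarray],
) -> REMLResult:
    """BLUE/BLUP at fixed variance components (one factorization)."""
    ws = _Workspace(spec, data, A)
    theta = _theta_from_components(ws, components)
    F = ws.factorize(theta)
    res = REMLResult(
        spec=spec, components=_components_from_theta(ws, theta),
        param_names=ws.param_layout(), theta=theta,
        sampling_cov=np.zeros((len(theta), len(theta))),
        loglik=F["loglik"], converged=True, n_rounds=0,
    )
    _attach_solutions(res, ws, F)
    return res


def compute_leverages(
    spec: MixedModelSpec,
    data: StackedData,
    A: RelationshipMatrix | None,
    components: dict[str, np.ndarray],
    saturation_tol: float = 1e-8,
) -> np.ndarray:
    """Exact hat-matrix diagonal at fixed components.

    Records with h >= 1 - tol are saturated (a fixed-effect level fitted from
    a single record); downstream deviance computations must refuse them.
    """
    res = solve_blup(spec, data, A, components)
    h = res.leverages
    sat = h >= 1.0 - saturation_tol
    if sat.any():
        warnings.warn(f"{int(sat.sum())} saturated records (h ~ 1)",
                      stacklevel=2)
    return h
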