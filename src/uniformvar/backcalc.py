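"""Within/between-individual decomposition of the purebred-crossbred
genetic correlation for environmental variance.

Purebred hens are housed individually, so their V_E is the within-individual
variance only; crossbred eggs are pooled per cage, so crossbred V_E also
contains between-hen variance.  From a paired analysis of the same
(purebred) data under both housing definitions — individual cages (ic) and
multiple-hen cages (mc) — these identities back-calculate how much of the
departure of the observed purebred-crossbred correlation ``r_pc`` from 1 is
explained by the difference in definition:

* genetic variance of the between-individual component:
  ``s2_b = s2_mc + s2_ic - 2 r s_ic s_mc``;
* genetic correlation between within- and between-individual components:
  ``r_wb = (r s_mc - s_w) / s_b``;
* correlation under an equal (within-individual) definition, assuming
  ``r_wb = 0``:  ``r_w_pc = r_pc * s_c / s_wc``, with exact inverse
  ``r_pc = r_w_pc * s_wc / s_c``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["between_variance", "corr_within_between", "corr_within_pc",
           "expected_rpc", "decompose"]


def between_variance(sigma2_mc: float, sigma2_ic: float,
                     r_ic_mc: float, tol: float = 1e-8) -> float:
    """Genetic variance of the between-individual component of V_E.

    ``sigma2_mc``/``sigma2_ic`` are the genetic variances of log V_E under
    multiple-hen-cage and individual-cage definitions; ``r_ic_mc`` their
    genetic correlation.
    """
    if sigma2_mc < 0 or sigma2_ic < 0:
        raise ValueError("variances must be non-negative")
    if abs(r_ic_mc) > 1:
        raise ValueError("correlation outside [-1, 1]")
    v = sigma2_mc + sigma2_ic - 2.0 * r_ic_mc * np.sqrt(sigma2_ic * sigma2_mc)
    if v < 0:
        scale = max(sigma2_mc, sigma2_ic, 1e-300)
        if v > -tol * scale:
            warnings.warn("slightly negative between-individual variance "
                          "clipped to 0", stacklevel=2)
            return 0.0
        raise ValueError(f"inconsistent inputs: negative variance {v:.3g}")
    return float(v)


def corr_within_between(r_ic_mc: float, sigma_mc: float, sigma_w: float,
                        sigma_b: float) -> float:
    """Genetic correlation between within- and between-individual V_E."""
    if sigma_b <= 0:
        raise ValueError("between-individual SD must be positive")
    r = (r_ic_mc * sigma_mc - sigma_w) / sigma_b
    if abs(r) > 1 + 1e-8:
        raise ValueError(f"implied correlation {r:.3f} outside [-1, 1]: "
                         "inconsistent inputs")
    return float(np.clip(r, -1.0, 1.0))


def corr_within_pc(r_pc: float, sigma_A_vc: float, sigma_A_vwc: float,
                   tol: float = 1e-8) -> float:
    """Purebred-crossbred correlation under an equal (within) definition.

    Assumes the within/between components are genetically uncorrelated
    (the caller asserts r_wb ~ 0).  With the equal-proportion assumption
    (within-share identical in both populations) pass
    ``sigma_A_vc = sqrt(s2_mc)`` and ``sigma_A_vwc = sqrt(s2_ic)``.
    """
    if sigma_A_vwc <= 0:
        raise ValueError("within-individual SD must be positive")
    r = r_pc * sigma_A_vc / sigma_A_vwc
    if abs(r) > 1 + tol:
        raise ValueError(
            f"implied correlation {r:.3f} exceeds 1: inputs violate the "
            "zero within-between-correlation assumption")
    return float(r)


def expected_rpc(r_w_pc: float, sigma_A_vwc: float, sigma_A_vc: float) -> float:
    """Observed-definition correlation from the equal-definition one
    (exact inverse of :func:`corr_within_pc`)."""
    if not (sigma_A_vc >= sigma_A_vwc > 0):
        raise ValueError("require sigma_A_vc >= sigma_A_vwc > 0")
    return float(r_w_pc * sigma_A_vwc / sigma_A_vc)


def decompose(r_pc: float, sigma2_ic: float, sigma2_mc: float,
              r_ic_mc: float) -> dict:
    """Full back-calculation report from the cage-definition experiment.

    Parameters are the observed purebred-crossbred genetic correlation for
    V_E, the genetic variances of log V_E under individual-cage and
    multiple-hen-cage definitions, and their genetic correlation.
    """
    s2_b = between_variance(sigma2_mc, sigma2_ic, r_ic_mc)
    s_w = np.sqrt(sigma2_ic)
    r_wb = (corr_within_between(r_ic_mc, np.sqrt(sigma2_mc), s_w,
                                np.sqrt(s2_b)) if s2_b > 0 else np.nan)
    # equal-proportion assumption: within-share in crossbreds = s2_ic / s2_mc
    r_w_pc = corr_within_pc(r_pc, np.sqrt(sigma2_mc), np.sqrt(sigma2_ic))
    return dict(
        sigma2_between=s2_b,
        sigma2_within=sigma2_ic,
        r_within_between=r_wb,
        r_pc=r_pc,
        r_within_pc=r_w_pc,
        within_share=sigma2_ic / sigma2_mc if sigma2_mc > 0 else np.nan,
    )
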