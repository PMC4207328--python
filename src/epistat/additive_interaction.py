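"""Departure-from-additivity interaction measures RERI, AP and S.

For two binary exposures with odds ratios OR10, OR01 (single
exposures) and OR11 (joint exposure) relative to the doubly-unexposed
reference:

* RERI = OR11 - OR10 - OR01 + 1  (relative excess risk due to interaction)
* AP   = RERI / OR11             (attributable proportion due to interaction)
* S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))  (synergy index)

All three are zero/unity exactly when the joint odds-ratio excess is
the sum of the single excesses.  Confidence intervals follow the
Hosmer-Lemeshow delta-method approach: the three ORs are the
exponentiated indicator coefficients of a logistic model, the measures
are smooth functions of those coefficients, and their variances come
from the coefficient covariance.  RERI and AP get symmetric CIs; S is
interval-estimated on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .assoc_qc import two_by_two_or
from .logistic_interaction import FitResult, fit_logistic
from .tables_io import EXPOSURE_ORDER, EffectEstimate, TwoByFourTable

__all__ = ["AdditiveResult", "additive_measures", "two_by_four_ors"]


@dataclass
class AdditiveResult:
    """Additive-interaction analysis of one 2x4 table."""

    reri: EffectEstimate
    ap: EffectEstimate
    s: Optional[EffectEstimate]
    or10: EffectEstimate
    or01: EffectEstimate
    or11: EffectEstimate
    source: str
    fit: FitResult = None


def two_by_four_ors(t: TwoByFourTable, alpha: float = 0.05):
    """Crude odds ratios of each non-reference exposure category.

    Returns ``(or10, or01, or11)`` versus the (0, 0) reference cell,
    each a cross-product OR with a Wald CI (Haldane-Anscombe corrected
    and flagged if a cell is empty).
    """
    ref_pos, ref_neg = t.counts[0]
    if ref_pos == 0 or ref_neg == 0:
        raise ValueError("empty reference cell")
    out = []
    for row, combo in zip(t.counts[1:], EXPOSURE_ORDER[1:]):
        est = two_by_two_or(
            row[0], ref_pos, row[1], ref_neg, alpha,
            scale="OR", model_tag=f"({combo[0]},{combo[1]}) vs (0,0)",
        )
        out.append(est)
    return tuple(out)


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    return math.sqrt(float(grad @ cov @ grad))


def additive_measures(t: TwoByFourTable, alpha: float = 0.05) -> AdditiveResult:
    """RERI, AP and S with delta-method CIs from a 2x4 table.

    The saturated indicator-parameterized logistic model
    ``logit ~ I(1,0) + I(0,1) + I(1,1)`` is fitted to the grouped
    counts, so with all cells positive the model ORs equal the crude
    cross-product ORs.  S is returned as ``None``-flagged missing when
    its denominator ``OR10 + OR01 - 2`` is non-positive (no joint
    excess to apportion) or the index is non-positive so that no
    log-scale interval exists.
    """
    if (t.counts == 0).any():
        raise ValueError("additive measures require all eight cells non-empty")
    X, y, w = [], [], []
    for idx in range(4):
        ind = [0.0, 0.0, 0.0]
        if idx > 0:
            ind[idx - 1] = 1.0
        for col, yy in ((0, 1.0), (1, 0.0)):
            X.append([1.0] + ind)
            y.append(yy)
            w.append(t.counts[idx, col])
    fit = fit_logistic(np.array(X), np.array(y), weights=np.array(w, dtype=float))
    b = fit.coef[1:4]
    V = fit.cov[1:4, 1:4]
    e1, e2, e3 = np.exp(b)
    z = stats.norm.ppf(1 - alpha / 2)

    reri_val = e3 - e1 - e2 + 1.0
    reri_se = _delta_se(np.array([-e1, -e2, e3]), V)
    reri = EffectEstimate(
        "RERI", reri_val, reri_val - z * reri_se, reri_val + z * reri_se,
        2 * stats.norm.sf(abs(reri_val) / reri_se) if reri_se > 0 else float("nan"),
        "hosmer-lemeshow", alpha,
    )

    ap_val = reri_val / e3
    ap_grad = np.array([-e1 / e3, -e2 / e3, e1 / e3 + e2 / e3 - 1.0 / e3])
    ap_se = _delta_se(ap_grad, V)
    ap = EffectEstimate(
        "AP", ap_val, ap_val - z * ap_se, ap_val + z * ap_se,
        2 * stats.norm.sf(abs(ap_val) / ap_se) if ap_se > 0 else float("nan"),
        "hosmer-lemeshow", alpha,
    )

    denom = e1 + e2 - 2.0
    num = e3 - 1.0
    if denom <= 0 or num / denom <= 0:
        s_est = None
    else:
        s_val = num / denom
        lns_grad = np.array([-e1 / denom, -e2 / denom, e3 / num])
        lns_se = _delta_se(lns_grad, V)
        # near-zero single-exposure excesses blow up the log-scale SE;
        # the interval then degenerates to (0, inf)
        half = z * lns_se
        s_lo = 0.0 if half > 700 else s_val * math.exp(-half)
        s_hi = math.inf if half > 700 else s_val * math.exp(half)
        s_est = EffectEstimate(
            "S", s_val, s_lo, s_hi,
            2 * stats.norm.sf(abs(math.log(s_val)) / lns_se) if lns_se > 0 else float("nan"),
            "hosmer-lemeshow", alpha,
        )

    or_ests = tuple(
        fit.wald(j, alpha, scale="OR", model_tag=f"({c[0]},{c[1]}) vs (0,0)")
        for j, c in zip((1, 2, 3), EXPOSURE_ORDER[1:])
    )
    return AdditiveResult(reri, ap, s_est, *or_ests, source="model", fit=fit)
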