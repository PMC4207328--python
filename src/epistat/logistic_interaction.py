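"""Logistic regression and the multiplicative interaction ratio (ROR).

The multiplicative interaction between two risk loci is tested as the
interaction coefficient of ``logit P(case) = b0 + b1*x1 + b2*x2 +
b3*x1*x2``; ``exp(b3)`` is the ratio of odds ratios of the interaction
(ROR_i = OR11 / (OR10 * OR01) for binary codings).  Inference is Wald
(coefficient standard errors from the inverse observed information),
matching how interaction terms are reported by mainstream statistical
packages.

The fitter is Newton scoring on (optionally frequency-weighted)
grouped data with step-halving, so saturated fits on contingency
tables are exact and cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables_io import (
    EffectEstimate,
    JointGenotypeTable,
    code_genotype,
    genotype_levels,
)

__all__ = [
    "FitResult",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "ror_i",
    "stratified_or",
    "joint_tables_to_rows",
]

#: Separation is declared when a standardized coefficient exceeds this.
SEPARATION_COEF_BOUND = 15.0

_EPS = 1e-12


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Newton scoring failed to converge within the iteration budget."""


@dataclass
class FitResult:
    """Fitted logistic model: coefficients, covariance and fit metrics."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n: float
    converged: bool
    n_iter: int = 0
    loglik_path: tuple = field(default=(), repr=False)

    @property
    def k(self) -> int:
        return len(self.coef)

    def wald(self, j: int, alpha: float = 0.05, scale: str = "OR",
             model_tag: str = "") -> EffectEstimate:
        """Wald estimate of ``exp(coef[j])`` with its CI and p-value."""
        b = float(self.coef[j])
        se = math.sqrt(float(self.cov[j, j]))
        z = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else float("nan")
        return EffectEstimate(
            scale, math.exp(b), math.exp(b - z * se), math.exp(b + z * se),
            p, model_tag, alpha,
        )


def _loglik(X, y, w, beta):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def fit_logistic(
    design,
    outcome,
    weights=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood logistic fit by Newton scoring with step-halving.

    Parameters
    ----------
    design
        Model matrix including the intercept column.
    outcome
        0/1 response per row.
    weights
        Optional nonnegative frequency weights (grouped data).
    max_iter, tol
        Iteration budget and convergence tolerance on the sup-norm of
        the score vector.

    Raises
    ------
    SeparationError
        When a standardized coefficient diverges beyond
        :data:`SEPARATION_COEF_BOUND` (complete separation) or the
        information matrix collapses.
    ConvergenceError
        When the score has not vanished after ``max_iter`` iterations.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("negative weights")
    keep = w > 0
    X, y, w = X[keep], y[keep], w[keep]
    n = float(w.sum())

    # weighted column scale for the standardized separation check
    mean = (w @ X) / n
    var = (w @ (X - mean) ** 2) / n
    sd = np.sqrt(var)

    beta = np.zeros(X.shape[1])
    ll = _loglik(X, y, w, beta)
    path = [ll]
    info = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        p = np.clip(p, _EPS, 1 - _EPS)
        score = X.T @ (w * (y - p))
        info = (X * (w * p * (1 - p))[:, None]).T @ X
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or collinear design)"
            ) from None
        # step-halving guarantees a non-decreasing log-likelihood path
        # (up to float noise near the optimum)
        slack = 1e-10 * (1.0 + abs(ll))
        new_ll = _loglik(X, y, w, beta + step)
        halvings = 0
        while new_ll < ll - slack and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll = _loglik(X, y, w, beta + step)
        beta = beta + step
        ll = new_ll
        path.append(ll)
        scaled = np.abs(beta) * np.where(sd > 0, sd, 1.0)
        if np.max(scaled) > SEPARATION_COEF_BOUND:
            raise SeparationError(
                f"coefficient diverging (standardized |coef| > {SEPARATION_COEF_BOUND:g}); "
                "data show complete or quasi-complete separation"
            )
    if not converged:
        raise ConvergenceError(f"no convergence after {max_iter} iterations")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise SeparationError("singular information matrix at the optimum") from None
    k = X.shape[1]
    return FitResult(
        coef=beta, cov=cov, loglik=ll, aic=-2.0 * ll + 2.0 * k, n=n,
        converged=True, n_iter=it, loglik_path=tuple(path),
    )


# ---------------------------------------------------------------------------
# joint-table plumbing
# ---------------------------------------------------------------------------

def joint_tables_to_rows(joint_cases: JointGenotypeTable,
                         joint_controls: JointGenotypeTable):
    """Grouped-data rows (g1, g2, y, weight) from a pair of joint tables."""
    if (joint_cases.marker1.name != joint_controls.marker1.name
            or joint_cases.marker2.name != joint_controls.marker2.name):
        raise ValueError("case and control tables refer to different marker pairs")
    lv1 = genotype_levels(joint_cases.marker1)
    lv2 = genotype_levels(joint_cases.marker2)
    rows = []
    for y, table in ((1, joint_cases), (0, joint_controls)):
        for i, g1 in enumerate(lv1):
            for j, g2 in enumerate(lv2):
                wij = int(table.counts[i, j])
                if wij:
                    rows.append((g1, g2, y, wij))
    return rows


def _interaction_design(rows, coding1, coding2, m1, m2):
    X, y, w = [], [], []
    for g1, g2, yy, ww in rows:
        x1 = code_genotype(g1, coding1, m1)
        x2 = code_genotype(g2, coding2, m2)
        X.append((1.0, x1, x2, x1 * x2))
        y.append(yy)
        w.append(ww)
    return np.array(X), np.array(y, dtype=float), np.array(w, dtype=float)


def _check_exposure_cells(X, y, w):
    """Name any empty coded-exposure/outcome cell before fitting."""
    seen = {}
    for xi, yi, wi in zip(X, y, w):
        key = (xi[1], xi[2], int(yi))
        seen[key] = seen.get(key, 0) + wi
    x1_levels = sorted({k[0] for k in seen})
    x2_levels = sorted({k[1] for k in seen})
    for x1 in x1_levels:
        for x2 in x2_levels:
            for yy in (0, 1):
                if seen.get((x1, x2, yy), 0) == 0:
                    raise SeparationError(
                        f"empty exposure cell x1={x1:g}, x2={x2:g}, outcome={yy}"
                    )


def ror_i(
    joint_cases: JointGenotypeTable,
    joint_controls: JointGenotypeTable,
    coding1: str = "dominant",
    coding2: str = "dominant",
    alpha: float = 0.05,
) -> EffectEstimate:
    """Ratio of odds ratios of the interaction between two markers.

    Fits ``logit(case) ~ x1 + x2 + x1*x2`` on the pooled joint genotype
    tables with the requested genetic codings and returns the
    exponentiated interaction coefficient with its Wald CI and p-value.
    For dominant-by-dominant coding this equals the cross-ratio
    ``OR11 / (OR10 * OR01)`` of the four exposure-cell odds ratios.
    """
    m1, m2 = joint_cases.marker1, joint_cases.marker2
    rows = joint_tables_to_rows(joint_cases, joint_controls)
    X, y, w = _interaction_design(rows, coding1, coding2, m1, m2)
    _check_exposure_cells(X, y, w)
    fit = fit_logistic(X, y, weights=w)
    return fit.wald(3, alpha, scale="ROR", model_tag=f"{coding1}x{coding2}")


def stratified_or(
    joint_cases: JointGenotypeTable,
    joint_controls: JointGenotypeTable,
    stratifier,
    target,
    alpha: float = 0.05,
):
    """Target-marker odds ratio within each stratum of the other marker.

    ``stratifier`` and ``target`` are ``(marker_name, coding)`` pairs
    naming the two markers of the joint tables.  Returns
    ``(or_in_carriers, or_in_noncarriers)``, i.e. the target OR within
    stratifier = 1 and stratifier = 0.  Under binary codings the ratio
    of the two equals the :func:`ror_i` point estimate.
    """
    from .assoc_qc import two_by_two_or  # local import avoids a cycle

    m1, m2 = joint_cases.marker1, joint_cases.marker2
    names = {m1.name, m2.name}
    (s_name, s_coding), (t_name, t_coding) = stratifier, target
    if {s_name, t_name} != names or s_name == t_name:
        raise ValueError("stratifier/target must name the two joint-table markers")
    rows = joint_tables_to_rows(joint_cases, joint_controls)
    markers = {m1.name: m1, m2.name: m2}
    # cells[(stratum, target_code, y)] -> weight
    cells = {}
    for g1, g2, yy, ww in rows:
        genos = {m1.name: g1, m2.name: g2}
        s = code_genotype(genos[s_name], s_coding, markers[s_name])
        t = code_genotype(genos[t_name], t_coding, markers[t_name])
        if s > 1 or t > 1:
            raise ValueError("stratified ORs require binary codings")
        key = (s, t, yy)
        cells[key] = cells.get(key, 0) + ww
    out = []
    for s in (1, 0):
        total = sum(cells.get((s, t, yy), 0) for t in (0, 1) for yy in (0, 1))
        if total == 0:
            raise ValueError(f"empty stratum {s_name}={s}")
        est = two_by_two_or(
            cells.get((s, 1, 1), 0), cells.get((s, 0, 1), 0),
            cells.get((s, 1, 0), 0), cells.get((s, 0, 0), 0),
            alpha, scale="OR", model_tag=f"{t_name}|{s_name}={s}",
        )
        out.append(est)
    return tuple(out)
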