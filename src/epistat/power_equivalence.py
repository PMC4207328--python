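"""Interaction power and cross-study replication classification.

``power_ror`` gives the Wald power of the multiplicative-interaction
test for a dominant-by-dominant two-locus design: expected cell counts
under the alternative fix the standard error of the log interaction
ratio, and the two-sided rejection probability follows from the normal
approximation.  At the null (ROR = 1) the formula returns exactly the
test size alpha.

``replication_verdict`` classifies whether a replication attempt can
exclude, or must declare equivalent, a previously reported effect, by
mutual confidence-interval containment of the two point estimates —
the standard heuristic when no analytic power formula exists for the
estimand (e.g. the attributable proportion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables_io import EffectEstimate

__all__ = ["PowerSpec", "ReplicationVerdict", "power_ror",
           "replication_verdict", "expected_cells"]


@dataclass(frozen=True)
class PowerSpec:
    """Design for an interaction power computation.

    ``f1``/``f2`` are carrier (exposure) probabilities of the two loci
    among controls, assumed independent; ``or1``/``or2`` the
    single-exposure odds ratios; ``ror_alt`` the interaction ratio
    under the alternative.
    """

    n_cases: int
    n_controls: int
    f1: float
    f2: float
    or1: float = 1.0
    or2: float = 1.0
    ror_alt: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        for f in (self.f1, self.f2):
            if not 0.0 < f < 1.0:
                raise ValueError("exposure frequencies must lie in (0, 1)")
        for o in (self.or1, self.or2, self.ror_alt):
            if o <= 0:
                raise ValueError("odds ratios must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ReplicationVerdict:
    """Mutual CI-containment classification of two estimates."""

    verdict: str  # excluded | equivalent | uncertain
    a_in_b: bool
    b_in_a: bool


def expected_cells(spec: PowerSpec):
    """Expected 2x2x2 cell counts (controls, cases) under the alternative.

    Control exposure-cell probabilities come from independent carrier
    frequencies; case probabilities are the control probabilities
    re-weighted by the cell odds of the logistic interaction model
    (retrospective sampling), i.e. by 1, or1, or2 and or1*or2*ror.
    """
    p = np.array([
        (1 - spec.f1) * (1 - spec.f2),
        spec.f1 * (1 - spec.f2),
        (1 - spec.f1) * spec.f2,
        spec.f1 * spec.f2,
    ])
    odds = np.array([1.0, spec.or1, spec.or2,
                     spec.or1 * spec.or2 * spec.ror_alt])
    case_p = p * odds / (p * odds).sum()
    return spec.n_controls * p, spec.n_cases * case_p


def power_ror(spec: PowerSpec):
    """Two-sided Wald power (and type II error) for the interaction ratio.

    Returns ``(power, beta)``.  The standard error of the log ratio is
    ``sqrt(sum of reciprocals of the eight expected cell counts)``; the
    power is ``Phi(lambda/SE - z) + Phi(-lambda/SE - z)`` with
    ``lambda = ln(ror_alt)`` and ``z`` the two-sided critical value, so
    ``ror_alt = 1`` returns exactly ``alpha``.
    """
    controls, cases = expected_cells(spec)
    cells = np.concatenate([controls, cases])
    if (cells < 1.0).any():
        warnings.warn(
            "expected cell count below 1: normal approximation unreliable",
            stacklevel=2,
        )
    se = math.sqrt(float((1.0 / cells).sum()))
    lam = math.log(spec.ror_alt)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    power = float(stats.norm.cdf(lam / se - z) + stats.norm.cdf(-lam / se - z))
    return power, 1.0 - power


def replication_verdict(est_a: EffectEstimate, est_b: EffectEstimate) -> ReplicationVerdict:
    """Classify two estimates by mutual point-in-CI containment.

    ``excluded`` — neither point estimate lies inside the other's CI
    (the studies exclude each other's effect); ``equivalent`` — both
    do; ``uncertain`` — one-sided containment only.
    """
    for est in (est_a, est_b):
        if any(math.isnan(v) for v in (est.est, est.lo, est.hi)):
            raise ValueError("both estimates must carry point values and CIs")
    if est_a.alpha != est_b.alpha:
        raise ValueError("confidence levels differ between the two estimates")
    a_in_b = est_b.ci_contains(est_a.est)
    b_in_a = est_a.ci_contains(est_b.est)
    if a_in_b and b_in_a:
        verdict = "equivalent"
    elif not a_in_b and not b_in_a:
        verdict = "excluded"
    else:
        verdict = "uncertain"
    return ReplicationVerdict(verdict, a_in_b, b_in_a)
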