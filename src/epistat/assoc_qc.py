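"""Marker quality control and single-marker association.

QC follows common candidate-gene practice: a marker passes when its
call rate exceeds 90% and its control genotype frequencies are
compatible with Hardy-Weinberg equilibrium (HWE) at P > 0.05 (1-df
chi-square on observed vs expected counts).  Association is the allelic
2x2 chi-square with the cross-product odds ratio and a Wald confidence
interval on the log scale.  No Yates continuity correction is applied
to chi-square statistics; zero cells in odds-ratio tables get the
Haldane-Anscombe 0.5 correction, flagged in the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .tables_io import (
    EffectEstimate,
    GenotypeCountTable,
    MarkerDef,
    aggregate_counts,
    call_rate,
)

__all__ = [
    "QCReport",
    "maf",
    "carrier_freq",
    "hwe_test",
    "allelic_or",
    "carrier_or",
    "two_by_two_or",
    "compare_freqs",
    "qc_report",
]


@dataclass
class QCReport:
    """Outcome of per-marker quality control."""

    marker: str
    call_rate: float
    hwe_chi2: float
    hwe_p: float
    maf_by_group: dict
    passed: bool


def maf(t: GenotypeCountTable) -> float:
    """Minor allele frequency of a SNP count table."""
    if t.marker.kind != "snp":
        raise ValueError(f"MAF undefined for {t.marker.kind} marker {t.marker.name!r}")
    if t.total == 0:
        raise ValueError("empty genotype table")
    return (t.n_het + 2 * t.n_minor_hom) / (2 * t.total)


def carrier_freq(t: GenotypeCountTable) -> float:
    """Fraction of people carrying at least one minor/risk state."""
    if t.total == 0:
        raise ValueError("empty genotype table")
    return (t.n_het + t.n_minor_hom) / t.total


def hwe_test(t: GenotypeCountTable) -> tuple:
    """1-df chi-square goodness-of-fit test to Hardy-Weinberg proportions.

    The allele frequency is estimated from the table itself.  A
    monomorphic table admits no test; it returns ``(0.0, 1.0)`` with a
    warning.
    """
    if t.marker.kind != "snp":
        raise ValueError("HWE test requires a SNP marker")
    n = t.total
    if n == 0:
        raise ValueError("empty genotype table")
    q = maf(t)
    if q in (0.0, 1.0):
        warnings.warn(
            f"marker {t.marker.name!r} monomorphic in {t.group_label}: HWE untestable",
            stacklevel=2,
        )
        return 0.0, 1.0
    observed = np.array([t.n_common_hom, t.n_het, t.n_minor_hom], dtype=float)
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def two_by_two_or(
    a: float, b: float, c: float, d: float, alpha: float = 0.05,
    scale: str = "OR", model_tag: str = "",
) -> EffectEstimate:
    """Cross-product odds ratio ``(a*d)/(b*c)`` with Wald CI and chi-square p.

    Layout: rows are groups, columns are exposed/unexposed —
    ``a``/``b`` exposed/unexposed in group 1, ``c``/``d`` in group 2.
    Any zero cell triggers the Haldane-Anscombe 0.5 correction for the
    estimate and CI (flagged); the p-value is always computed from the
    uncorrected Pearson chi-square.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    chi2, p = compare_freqs(a, a + b, c, c + d)
    flags = ()
    if (cells == 0).any():
        cells = cells + 0.5
        flags = ("haldane_anscombe",)
    a_, b_, c_, d_ = cells
    est = (a_ * d_) / (b_ * c_)
    se = math.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(1 - alpha / 2)
    lo = est * math.exp(-z * se)
    hi = est * math.exp(z * se)
    return EffectEstimate(scale, est, lo, hi, p, model_tag, alpha, flags)


def compare_freqs(k1: float, n1: float, k2: float, n2: float) -> tuple:
    """Pearson 2x2 chi-square comparing two proportions (no Yates).

    Returns ``(chi2, p)``; degenerate margins give ``(0, 1)``.
    """
    if n1 <= 0 or n2 <= 0 or k1 > n1 or k2 > n2:
        raise ValueError("invalid successes/totals")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    chi2 = float(n * det ** 2 / (rows.prod() * cols.prod()))
    return chi2, float(stats.chi2.sf(chi2, 1))


def allelic_or(
    cases: GenotypeCountTable, controls: GenotypeCountTable, alpha: float = 0.05
) -> EffectEstimate:
    """Allelic odds ratio (minor vs major allele, cases vs controls)."""
    if cases.marker.name != controls.marker.name:
        raise ValueError("tables refer to different markers")
    if cases.marker.kind != "snp":
        raise ValueError("allelic OR requires a SNP; use carrier_or for binary markers")
    if cases.total == 0 or controls.total == 0:
        raise ValueError("empty genotype table")
    a = cases.n_het + 2 * cases.n_minor_hom        # minor alleles, cases
    b = 2 * cases.n_common_hom + cases.n_het       # major alleles, cases
    c = controls.n_het + 2 * controls.n_minor_hom
    d = 2 * controls.n_common_hom + controls.n_het
    return two_by_two_or(a, b, c, d, alpha, scale="OR", model_tag="allelic")


def carrier_or(
    t1: GenotypeCountTable, t2: GenotypeCountTable, alpha: float = 0.05,
    invert: bool = False,
) -> EffectEstimate:
    """Odds ratio of carrying the minor/exposure state, group 1 vs group 2.

    ``invert=True`` reports the reference-state orientation instead
    (useful when a published table is oriented on the common state,
    e.g. native-allele carriage of a deletion polymorphism).
    """
    if t1.marker.name != t2.marker.name:
        raise ValueError("tables refer to different markers")
    a, b = t1.n_het + t1.n_minor_hom, t1.n_common_hom
    c, d = t2.n_het + t2.n_minor_hom, t2.n_common_hom
    if invert:
        a, b, c, d = b, a, d, c
    return two_by_two_or(a, b, c, d, alpha, scale="OR", model_tag="carrier")


def qc_report(
    records,
    marker: MarkerDef,
    call_rate_threshold: float = 0.90,
    hwe_alpha: float = 0.05,
    groups: tuple = ("cases", "controls"),
) -> QCReport:
    """Run per-marker QC on a cohort.

    HWE is tested in controls only (cases can deviate through true
    association); the pass rule is call rate strictly above the
    threshold and control HWE P strictly above ``hwe_alpha``.  MAF is
    reported per group for SNPs, carrier frequency otherwise.
    """
    cr = call_rate(records, marker)
    controls = aggregate_counts(records, marker, "controls")
    if marker.kind == "snp" and controls.total > 0:
        chi2, p = hwe_test(controls)
    else:
        chi2, p = float("nan"), float("nan")
    freq_fn = maf if marker.kind == "snp" else carrier_freq
    freqs = {}
    for g in groups:
        t = aggregate_counts(records, marker, g)
        freqs[g] = freq_fn(t) if t.total else float("nan")
    passed = cr > call_rate_threshold and (not math.isnan(p)) and p > hwe_alpha
    if marker.kind != "snp":
        passed = cr > call_rate_threshold  # HWE unobservable without het counts
    return QCReport(marker.name, cr, chi2, p, freqs, passed)
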