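"""Case-only epistasis statistics.

Under linkage equilibrium between two loci in the source population, a
multiplicative gene-gene interaction on disease risk induces an
association between the loci *within cases*.  Two statistics exploit
this:

* ``t_pearson`` — the Pearson chi-square test of independence on the
  case genotype cross-table;
* ``t_awu_co`` — an adjusted Wu-type statistic on inter-locus allelic
  association (gametic phase disequilibrium).  Each case with
  minor-allele dosages (g1, g2) contributes fractionally to a 2x2
  allele-combination table: g1*g2/2 to the minor-minor cell,
  g1*(2-g2)/2 and (2-g1)*g2/2 to the mixed cells, and
  (2-g1)*(2-g2)/2 to the major-major cell, two units per person.  The
  statistic is the squared log cross-ratio of that table divided by
  its variance.  Because the two "gametes" of one person are not
  independent, the naive four-cell variance is wrong; the adjusted
  variance here comes from the multinomial delta method over the nine
  genotype cells, which is valid without phase information or a
  Hardy-Weinberg assumption.  A seeded permutation null (shuffling one
  locus among cases) is available as the assumption-free calibration
  and is engaged automatically when the allele table has a cell below
  one.

Both statistics assume population-level independence of the loci; with
linked or stratification-correlated loci they test that assumption,
not interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables_io import JointGenotypeTable

__all__ = ["CaseOnlyResult", "t_pearson", "t_awu_co"]

_DOSAGE = np.array([0.0, 1.0, 2.0])


@dataclass
class CaseOnlyResult:
    statistic_name: str
    value: float
    df: int
    p: float
    n_used: int
    method: str = "analytic"


def _pearson_chi2(counts: np.ndarray):
    """Brute-force Pearson chi-square with zero-margin reduction."""
    c = np.asarray(counts, dtype=float)
    c = c[c.sum(axis=1) > 0][:, c.sum(axis=0) > 0]
    r, k = c.shape
    if r < 2 or k < 2:
        raise ValueError(
            "fewer than two non-empty levels on an axis: independence untestable"
        )
    expected = np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()
    chi2 = float(((c - expected) ** 2 / expected).sum())
    df = (r - 1) * (k - 1)
    return chi2, df


def t_pearson(j: JointGenotypeTable) -> CaseOnlyResult:
    """Pearson independence chi-square on a case-only joint genotype table."""
    chi2, df = _pearson_chi2(j.counts)
    return CaseOnlyResult(
        "T_Pearson", chi2, df, float(stats.chi2.sf(chi2, df)), j.total
    )


def _allele_table(counts: np.ndarray):
    """Fractional 2x2 allele-combination cells (a, b, c, d) from 3x3 counts.

    a = minor-minor, b = minor1-major2, c = major1-minor2, d = major-major.
    """
    c = np.asarray(counts, dtype=float)
    g1 = _DOSAGE[:, None]
    g2 = _DOSAGE[None, :]
    a = float((c * g1 * g2 / 2.0).sum())
    b = float((c * g1 * (2.0 - g2) / 2.0).sum())
    cc = float((c * (2.0 - g1) * g2 / 2.0).sum())
    d = float((c * (2.0 - g1) * (2.0 - g2) / 2.0).sum())
    return a, b, cc, d


def _awu_statistic(counts: np.ndarray) -> float:
    """Adjusted Wu statistic of one (or a batch of) 3x3 case tables.

    Accepts shape (3, 3) or (m, 3, 3); returns a float or an (m,) array.
    Degenerate tables (zero allele cell or zero variance) yield ``nan``.
    """
    c = np.asarray(counts, dtype=float)
    single = c.ndim == 2
    if single:
        c = c[None]
    n = c.sum(axis=(1, 2))
    g1 = _DOSAGE[None, :, None]
    g2 = _DOSAGE[None, None, :]
    wa = g1 * g2 / 2.0
    wb = g1 * (2.0 - g2) / 2.0
    wc = (2.0 - g1) * g2 / 2.0
    wd = (2.0 - g1) * (2.0 - g2) / 2.0
    a = (c * wa).sum(axis=(1, 2))
    b = (c * wb).sum(axis=(1, 2))
    cx = (c * wc).sum(axis=(1, 2))
    d = (c * wd).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log(a * d / (b * cx))
        # delta-method variance over the 9-cell multinomial
        abar = (a / n)[:, None, None]
        bbar = (b / n)[:, None, None]
        cbar = (cx / n)[:, None, None]
        dbar = (d / n)[:, None, None]
        grad = wa / abar - wb / bbar - wc / cbar + wd / dbar
        q = c / n[:, None, None]
        var = ((q * grad ** 2).sum(axis=(1, 2))
               - (q * grad).sum(axis=(1, 2)) ** 2) / n
        out = theta ** 2 / var
    out = np.where(np.isfinite(out), out, np.nan)
    return float(out[0]) if single else out


def _expand_dosages(counts: np.ndarray):
    """Per-individual dosage vectors implied by a 3x3 count table."""
    g1, g2 = [], []
    for i in range(3):
        for j in range(3):
            k = int(counts[i, j])
            g1.extend([i] * k)
            g2.extend([j] * k)
    return np.array(g1), np.array(g2)


def _counts_from_dosages(g1, g2):
    return np.bincount(3 * g1 + g2, minlength=9).reshape(3, 3)


def t_awu_co(
    j: JointGenotypeTable,
    null_calibration: str = "analytic",
    n_perm: int = 2000,
    seed=None,
) -> CaseOnlyResult:
    """Adjusted Wu case-only statistic for a SNP-by-SNP 3x3 case table.

    ``null_calibration="analytic"`` refers the statistic to chi-square
    with 1 df; ``"permutation"`` estimates the p-value by permuting one
    locus's genotypes among cases ``n_perm`` times (add-one estimator).
    Sparse allele tables (any fractional cell below 1) force the
    permutation path with a warning.
    """
    if null_calibration not in ("analytic", "permutation"):
        raise ValueError(f"unknown calibration {null_calibration!r}")
    counts = np.asarray(j.counts)
    if counts.shape != (3, 3):
        raise ValueError("adjusted Wu statistic requires a 3x3 SNP-by-SNP table")
    a, b, c, d = _allele_table(counts)
    if min(a, b, c, d) < 1.0 and null_calibration == "analytic":
        warnings.warn(
            "allele-combination cell below 1: falling back to permutation "
            "calibration",
            stacklevel=2,
        )
        null_calibration = "permutation"
    value = _awu_statistic(counts)
    n = int(counts.sum())
    if null_calibration == "analytic":
        p = float(stats.chi2.sf(value, 1))
        method = "analytic"
    else:
        rng = np.random.default_rng(seed)
        g1, g2 = _expand_dosages(counts)
        exceed = 0
        valid = 0
        for _ in range(n_perm):
            perm = _counts_from_dosages(g1, rng.permutation(g2))
            stat = _awu_statistic(perm)
            if np.isnan(stat):
                continue
            valid += 1
            if stat >= value:
                exceed += 1
        p = (exceed + 1) / (valid + 1)
        method = f"permutation[{n_perm}]"
    return CaseOnlyResult("T_AWu_co", value, 1, p, n, method)
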