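"""Seeded synthetic cohorts and published-table fixtures.

The generator emulates a two-locus candidate-gene case-control study:
control genotypes are drawn from Hardy-Weinberg proportions at stated
minor-allele (or carrier) frequencies, optionally with pairwise
linkage disequilibrium through a two-locus haplotype construction;
case genotypes are drawn retrospectively, with probability
proportional to the control genotype probability times the exponential
of the logistic linear predictor (main-effect odds ratios plus an
optional interaction term).  This preserves all odds ratios exactly in
expectation while delivering the requested case/control counts, and it
makes the baseline disease odds irrelevant to the genotype
distribution.  Patients additionally receive an antibody
(anti-CCP-like) status from a 2x4 exposure-cell model, giving the
stratified patient-only layout that additive-interaction analyses
need.

``fixture_tables`` returns the package's bundled published contingency
tables (seven SNP association rows, two antibody-stratified binary
contrasts, and the 2x4 joint-exposure table) as ready-made inputs.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tables_io import (
    CohortRecord,
    GenotypeCountTable,
    JointGenotypeTable,
    MarkerDef,
    TwoByFourTable,
    code_genotype,
    genotype_levels,
)

__all__ = [
    "SimScenario",
    "AccpModel",
    "simulate_cohort",
    "simulate_two_locus_tables",
    "simulate_two_by_four",
    "fixture_tables",
    "fixture_markers",
    "hwe_probs",
    "haplotype_freqs",
]


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (0/1/2 minor-allele dosage)."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError("MAF must lie in [0, 1]")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])


def haplotype_freqs(maf1: float, maf2: float, ld_r2: float) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab; A/B = minor).

    ``ld_r2`` is the squared correlation between the minor alleles;
    positive-sign D is used.  Raises when the implied frequency grid is
    infeasible for the given allele frequencies.
    """
    if not 0.0 <= ld_r2 <= 1.0:
        raise ValueError("ld_r2 must lie in [0, 1]")
    r = np.sqrt(ld_r2)
    d = r * np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    h = np.array([
        maf1 * maf2 + d,
        maf1 * (1 - maf2) - d,
        (1 - maf1) * maf2 - d,
        (1 - maf1) * (1 - maf2) + d,
    ])
    if (h < -1e-12).any():
        raise ValueError(
            f"infeasible LD: r^2={ld_r2:g} with MAFs {maf1:g}/{maf2:g} "
            "implies a negative haplotype frequency"
        )
    return np.clip(h, 0.0, 1.0)


def _two_locus_genotype_probs(maf1: float, maf2: float, ld_r2: float) -> np.ndarray:
    """3x3 joint genotype probabilities from random union of haplotypes."""
    h = haplotype_freqs(maf1, maf2, ld_r2)
    # haplotype k carries (minor1?, minor2?) per this order
    dos = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])
    probs = np.zeros((3, 3))
    for k1 in range(4):
        for k2 in range(4):
            g1 = dos[k1, 0] + dos[k2, 0]
            g2 = dos[k1, 1] + dos[k2, 1]
            probs[g1, g2] += h[k1] * h[k2]
    return probs


@dataclass(frozen=True)
class AccpModel:
    """Antibody-status model for patients in the 2x4 layout.

    Among patients, the probability of being antibody-positive follows
    ``odds = baseline_p/(1-baseline_p) * or_cell`` with ``or_cell`` in
    {1, or10, or01, or11} according to the two binary-coded exposures.
    """

    e1: tuple  # (marker_name, coding)
    e2: tuple
    baseline_p: float = 0.673
    or10: float = 1.0
    or01: float = 1.0
    or11: float = 1.0

    def cell_probs(self) -> np.ndarray:
        base_odds = self.baseline_p / (1 - self.baseline_p)
        odds = base_odds * np.array([1.0, self.or10, self.or01, self.or11])
        return odds / (1 + odds)


@dataclass
class SimScenario:
    """Everything needed to simulate one deterministic cohort.

    ``markers`` maps each marker to its control minor-allele frequency
    (SNPs) or exposure-state frequency (binary kinds).  ``main_ors``
    maps marker name to ``(odds_ratio, coding)``; ``interaction``
    is ``(name1, name2, coding1, coding2, ror)`` with a multiplicative
    magnitude on the odds-ratio scale.  ``ld_r2`` applies to the first
    two SNP markers of the list.
    """

    n_cases: int = 1744
    n_controls: int = 1650
    markers: Sequence = ()  # list of (MarkerDef, freq)
    ld_r2: float = 0.0
    main_ors: dict = field(default_factory=dict)
    interaction: Optional[tuple] = None
    accp_model: Optional[AccpModel] = None
    seed: int = 0


def _marker_probs(marker: MarkerDef, freq: float) -> np.ndarray:
    if marker.kind == "snp":
        return hwe_probs(freq)
    return np.array([1 - freq, freq])


def _linear_predictor_weights(marker_block, scenario: SimScenario) -> np.ndarray:
    """exp(eta) per joint genotype combo of the markers in the block."""
    defs = {m.name: m for m, _ in scenario.markers}
    levels = [genotype_levels(m) for m, _ in marker_block]
    shape = tuple(len(lv) for lv in levels)
    weights = np.ones(shape)
    it = np.ndindex(*shape)
    names = [m.name for m, _ in marker_block]
    for idx in it:
        eta = 0.0
        genos = {names[a]: levels[a][idx[a]] for a in range(len(names))}
        for name, (orv, coding) in scenario.main_ors.items():
            if name in genos:
                eta += np.log(orv) * code_genotype(genos[name], coding, defs[name])
        if scenario.interaction is not None:
            n1, n2, c1, c2, ror = scenario.interaction
            if n1 in genos and n2 in genos:
                eta += (np.log(ror)
                        * code_genotype(genos[n1], c1, defs[n1])
                        * code_genotype(genos[n2], c2, defs[n2]))
        weights[idx] = np.exp(eta)
    return weights


def simulate_cohort(scenario: SimScenario) -> list:
    """Draw a full cohort of :class:`CohortRecord` objects.

    Markers named in ``main_ors`` or the interaction pair form the
    "effect block" (at most two markers) whose joint genotype
    distribution is re-weighted for cases; all other markers are drawn
    identically in cases and controls.  Patients get antibody status
    from ``accp_model`` (or missing antibody status when no model is
    given); controls always have missing antibody status.
    """
    if not scenario.markers:
        raise ValueError("scenario defines no markers")
    rng = np.random.default_rng(scenario.seed)
    defs = [m for m, _ in scenario.markers]
    freqs = {m.name: f for m, f in scenario.markers}

    effect_names = set(scenario.main_ors)
    if scenario.interaction is not None:
        effect_names |= {scenario.interaction[0], scenario.interaction[1]}
    block = [(m, freqs[m.name]) for m in defs if m.name in effect_names]
    if len(block) > 2:
        raise ValueError("at most two markers may carry effects")
    rest = [(m, freqs[m.name]) for m in defs if m.name not in effect_names]

    n_cases, n_controls = scenario.n_cases, scenario.n_controls
    geno_cols = {}

    def _draw(probs, n):
        flat = probs.ravel()
        return rng.choice(len(flat), size=n, p=flat / flat.sum())

    if block:
        if (len(block) == 2 and scenario.ld_r2 > 0
                and all(m.kind == "snp" for m, _ in block)):
            joint = _two_locus_genotype_probs(block[0][1], block[1][1],
                                              scenario.ld_r2)
        else:
            margs = [_marker_probs(m, f) for m, f in block]
            joint = margs[0] if len(block) == 1 else np.outer(margs[0], margs[1])
        weights = _linear_predictor_weights(block, scenario)
        case_joint = joint * weights
        shape = joint.shape
        ctrl_idx = _draw(joint, n_controls)
        case_idx = _draw(case_joint, n_cases)
        for a, (m, _) in enumerate(block):
            lv = genotype_levels(m)
            if len(shape) == 1:
                ctrl_g, case_g = ctrl_idx, case_idx
            else:
                ctrl_g = np.unravel_index(ctrl_idx, shape)[a]
                case_g = np.unravel_index(case_idx, shape)[a]
            geno_cols[m.name] = [lv[g] for g in np.concatenate([case_g, ctrl_g])]
    for m, f in rest:
        lv = genotype_levels(m)
        probs = _marker_probs(m, f)
        idx = rng.choice(len(lv), size=n_cases + n_controls, p=probs)
        geno_cols[m.name] = [lv[g] for g in idx]

    accp = [None] * (n_cases + n_controls)
    if scenario.accp_model is not None:
        am = scenario.accp_model
        mdefs = {m.name: m for m in defs}
        cell_p = am.cell_probs()
        cell_of = {(0, 0): 0, (1, 0): 1, (0, 1): 2, (1, 1): 3}
        u = rng.random(n_cases)
        for i in range(n_cases):
            x1 = code_genotype(geno_cols[am.e1[0]][i], am.e1[1], mdefs[am.e1[0]])
            x2 = code_genotype(geno_cols[am.e2[0]][i], am.e2[1], mdefs[am.e2[0]])
            accp[i] = "positive" if u[i] < cell_p[cell_of[(x1, x2)]] else "negative"

    records = []
    width = len(str(n_cases + n_controls))
    for i in range(n_cases + n_controls):
        status = "case" if i < n_cases else "control"
        records.append(
            CohortRecord(
                sample_id=f"S{i + 1:0{width}d}",
                status=status,
                accp=accp[i],
                genotypes={m.name: geno_cols[m.name][i] for m in defs},
            )
        )
    return records


# ---------------------------------------------------------------------------
# fast counts-level generators for replicate-heavy studies
# ---------------------------------------------------------------------------

def simulate_two_locus_tables(
    marker1: MarkerDef,
    marker2: MarkerDef,
    freq1: float,
    freq2: float,
    or1: float = 1.0,
    or2: float = 1.0,
    ror: float = 1.0,
    coding1: str = "dominant",
    coding2: str = "dominant",
    n_cases: int = 1744,
    n_controls: int = 1650,
    ld_r2: float = 0.0,
    rng=None,
):
    """Draw (case, control) joint genotype tables directly as counts.

    Statistically identical to cross-tabulating :func:`simulate_cohort`
    output for the two effect markers, but multinomial at the table
    level, so large replicate studies stay cheap.
    """
    rng = np.random.default_rng(rng)
    if ld_r2 > 0 and marker1.kind == marker2.kind == "snp":
        joint = _two_locus_genotype_probs(freq1, freq2, ld_r2)
    else:
        joint = np.outer(_marker_probs(marker1, freq1),
                         _marker_probs(marker2, freq2))
    lv1, lv2 = genotype_levels(marker1), genotype_levels(marker2)
    weights = np.ones_like(joint)
    for i, g1 in enumerate(lv1):
        for j, g2 in enumerate(lv2):
            x1 = code_genotype(g1, coding1, marker1)
            x2 = code_genotype(g2, coding2, marker2)
            weights[i, j] = or1 ** x1 * or2 ** x2 * ror ** (x1 * x2)
    case_p = (joint * weights).ravel()
    case_p /= case_p.sum()
    ctrl_counts = rng.multinomial(n_controls, joint.ravel()).reshape(joint.shape)
    case_counts = rng.multinomial(n_cases, case_p).reshape(joint.shape)
    return (
        JointGenotypeTable(marker1, marker2, "cases", case_counts),
        JointGenotypeTable(marker1, marker2, "controls", ctrl_counts),
    )


def simulate_two_by_four(
    n_patients: int,
    f_e1: float,
    f_e2: float,
    baseline_p: float,
    or10: float,
    or01: float,
    or11: float,
    e1_name: str = "E1",
    e2_name: str = "E2",
    rng=None,
) -> TwoByFourTable:
    """Draw a patients-only 2x4 antibody-by-exposures table as counts.

    Exposures are independent Bernoulli among patients; antibody
    positivity per exposure cell follows the odds model of
    :class:`AccpModel`.
    """
    rng = np.random.default_rng(rng)
    cell_p = np.array([
        (1 - f_e1) * (1 - f_e2), f_e1 * (1 - f_e2),
        (1 - f_e1) * f_e2, f_e1 * f_e2,
    ])
    totals = rng.multinomial(n_patients, cell_p)
    base_odds = baseline_p / (1 - baseline_p)
    odds = base_odds * np.array([1.0, or10, or01, or11])
    p_pos = odds / (1 + odds)
    pos = rng.binomial(totals, p_pos)
    counts = np.stack([pos, totals - pos], axis=1)
    return TwoByFourTable(e1_name, e2_name, "accp_pos", "accp_neg", counts)


# ---------------------------------------------------------------------------
# published-table fixtures
# ---------------------------------------------------------------------------

def fixture_markers() -> dict:
    """Marker definitions for the bundled fixtures."""
    snps = ["ptpn22_rs2476601", "rs7726839", "rs12573019", "rs1168587",
            "rs1895535", "rs7200573", "rs11865624"]
    markers = {name: MarkerDef(name, "snp") for name in snps}
    markers["gstm1"] = MarkerDef("gstm1", "presence_absence",
                                 minor_allele_label="null")
    markers["se"] = MarkerDef("se", "carrier_binary",
                              minor_allele_label="shared epitope")
    return markers


#: (cases common/het/hom, controls common/het/hom) per SNP.
_TABLE2_SNPS = {
    "ptpn22_rs2476601": ((1383, 325, 35), (1405, 235, 10)),
    "rs7726839": ((1012, 631, 100), (959, 592, 88)),
    "rs12573019": ((1302, 405, 37), (1264, 359, 27)),
    "rs1168587": ((652, 830, 260), (612, 762, 276)),
    "rs1895535": ((1602, 138, 4), (1503, 137, 7)),
    "rs7200573": ((940, 687, 116), (890, 633, 127)),
    "rs11865624": ((1532, 201, 10), (1424, 221, 3)),
}


def fixture_tables() -> dict:
    """Bundled published contingency tables, keyed by analysis name.

    * one ``{"cases": ..., "controls": ...}`` pair of
      :class:`GenotypeCountTable` per SNP association row;
    * ``"se"`` / ``"gstm1"`` — antibody-stratified binary-marker pairs
      (``accp_pos``/``accp_neg``); for the deletion marker the
      exposure state counted in ``n_minor_hom`` is the null homozygote;
    * ``"gstm1_se_2x4"`` — the patients-only 2x4 joint-exposure table
      (antibody-positive / antibody-negative columns).
    """
    m = fixture_markers()
    out = {}
    for name, (cs, ct) in _TABLE2_SNPS.items():
        out[name] = {
            "cases": GenotypeCountTable(m[name], "cases", *cs),
            "controls": GenotypeCountTable(m[name], "controls", *ct),
        }
    # shared-epitope carriage among antibody-positive/negative patients
    out["se"] = {
        "accp_pos": GenotypeCountTable(m["se"], "accp_pos", 174, 0, 279),
        "accp_neg": GenotypeCountTable(m["se"], "accp_neg", 153, 0, 116),
    }
    # deletion marker: common state = native carrier, exposure = null hom
    out["gstm1"] = {
        "accp_pos": GenotypeCountTable(m["gstm1"], "accp_pos", 402, 0, 376),
        "accp_neg": GenotypeCountTable(m["gstm1"], "accp_neg", 186, 0, 192),
    }
    out["gstm1_se_2x4"] = TwoByFourTable(
        "gstm1_null", "se_carrier", "accp_pos", "accp_neg",
        np.array([[84, 79], [90, 74], [130, 54], [148, 62]]),
    )
    return out
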