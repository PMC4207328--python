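"""Exhaustive two-locus genetic-model search ranked by AIC.

Each locus can enter the case-control logistic model under a dominant,
recessive, additive or codominant (two-indicator, 2-df) coding, or be
absent; two-locus models can add interaction terms built as all
pairwise products of the two loci's coding columns.  Every model is
fitted by maximum likelihood and scored with AIC = -2*loglik + 2k,
with k counting all coefficients including the intercept.  Models
within 2 AIC units of the best are conventionally considered not
meaningfully different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .logistic_interaction import (
    ConvergenceError,
    FitResult,
    SeparationError,
    fit_logistic,
    joint_tables_to_rows,
)
from .tables_io import JointGenotypeTable, MarkerDef, code_genotype

__all__ = ["ModelSpec", "ModelRanking", "enumerate_models", "rank_models",
           "LOCUS_CODINGS"]

LOCUS_CODINGS = ("dominant", "recessive", "additive", "codominant2df")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate two-locus genetic model."""

    locus1_coding: Optional[str]  # None = locus absent
    locus2_coding: Optional[str]
    interaction: bool = False

    def __post_init__(self):
        for c in (self.locus1_coding, self.locus2_coding):
            if c is not None and c not in LOCUS_CODINGS:
                raise ValueError(f"unknown coding {c!r}")
        if self.interaction and (
            self.locus1_coding is None or self.locus2_coding is None
        ):
            raise ValueError("interaction requires both loci in the model")

    def label(self) -> str:
        l1 = self.locus1_coding or "-"
        l2 = self.locus2_coding or "-"
        return f"{l1}+{l2}" + ("+ixn" if self.interaction else "")


@dataclass
class ModelRanking:
    """AIC-sorted model fits; ``entries`` are (spec, fit, delta_aic)."""

    entries: list
    best: ModelSpec


def enumerate_models(include_null: bool = True) -> list:
    """Deterministic, duplicate-free grid of candidate models.

    Null + 8 single-locus + 16 two-locus + 16 two-locus-with-interaction
    = 41 specs.
    """
    specs = []
    if include_null:
        specs.append(ModelSpec(None, None, False))
    for c in LOCUS_CODINGS:
        specs.append(ModelSpec(c, None, False))
    for c in LOCUS_CODINGS:
        specs.append(ModelSpec(None, c, False))
    for c1 in LOCUS_CODINGS:
        for c2 in LOCUS_CODINGS:
            specs.append(ModelSpec(c1, c2, False))
    for c1 in LOCUS_CODINGS:
        for c2 in LOCUS_CODINGS:
            specs.append(ModelSpec(c1, c2, True))
    return specs


def _coding_columns(g, coding: str, marker: MarkerDef) -> np.ndarray:
    """Design columns contributed by one locus for one genotype level."""
    if coding == "codominant2df":
        if marker.kind != "snp":
            raise ValueError(
                f"codominant coding needs three observable genotypes "
                f"({marker.kind} marker {marker.name!r} has two)"
            )
        return np.array([float(g == 1), float(g == 2)])
    return np.array([float(code_genotype(g, coding, marker))])


def _design_for_spec(rows, spec: ModelSpec, m1: MarkerDef, m2: MarkerDef):
    X, y, w = [], [], []
    for g1, g2, yy, ww in rows:
        cols = [np.array([1.0])]
        c1 = c2 = None
        if spec.locus1_coding:
            c1 = _coding_columns(g1, spec.locus1_coding, m1)
            cols.append(c1)
        if spec.locus2_coding:
            c2 = _coding_columns(g2, spec.locus2_coding, m2)
            cols.append(c2)
        if spec.interaction:
            cols.append(np.outer(c1, c2).ravel())
        X.append(np.concatenate(cols))
        y.append(yy)
        w.append(ww)
    return np.array(X), np.array(y, dtype=float), np.array(w, dtype=float)


def rank_models(
    joint_cases: JointGenotypeTable,
    joint_controls: JointGenotypeTable,
    specs: Optional[Sequence[ModelSpec]] = None,
) -> ModelRanking:
    """Fit every candidate model and rank by AIC.

    Ties are broken by fewer parameters, then by enumeration order.
    Models whose fit fails (separation, non-convergence) are excluded
    with a warning; if all fail, an error is raised.
    """
    if specs is None:
        specs = enumerate_models()
    m1, m2 = joint_cases.marker1, joint_cases.marker2
    rows = joint_tables_to_rows(joint_cases, joint_controls)
    fitted = []
    for order, spec in enumerate(specs):
        X, y, w = _design_for_spec(rows, spec, m1, m2)
        try:
            fit = fit_logistic(X, y, weights=w)
        except (SeparationError, ConvergenceError) as exc:
            warnings.warn(f"model {spec.label()} excluded: {exc}", stacklevel=2)
            continue
        fitted.append((spec, fit, order))
    if not fitted:
        raise RuntimeError("every candidate model failed to fit")
    fitted.sort(key=lambda t: (t[1].aic, t[1].k, t[2]))
    best_aic = fitted[0][1].aic
    entries = [(spec, fit, fit.aic - best_aic) for spec, fit, _ in fitted]
    return ModelRanking(entries=entries, best=entries[0][0])
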