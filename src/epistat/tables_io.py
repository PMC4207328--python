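"""Shared data model and I/O for two-locus case-control interaction analyses.

The package handles three kinds of markers that arise in candidate-gene
replication work:

* ``snp`` — biallelic SNPs stored as minor-allele dosage ``0/1/2``;
* ``presence_absence`` — gene-deletion polymorphisms (e.g. a GSTM1-type
  null allele) where heterozygotes are unobservable: only the
  ``"null"`` homozygote can be distinguished from ``"carrier"`` of at
  least one native allele;
* ``carrier_binary`` — pre-called binary carriage of an allele group
  (e.g. the HLA-DRB1 shared epitope), stored as ``"pos"``/``"neg"``.

Missing genotypes are ``None`` in memory and ``"NA"`` on disk.  Every
downstream statistic also accepts aggregated count tables directly, so
published contingency tables are first-class inputs alongside
individual-level cohort files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "MarkerDef",
    "CohortRecord",
    "GenotypeCountTable",
    "JointGenotypeTable",
    "TwoByFourTable",
    "EffectEstimate",
    "ParseError",
    "MISSING_TOKEN",
    "GROUP_SELECTORS",
    "EXPOSURE_ORDER",
    "genotype_levels",
    "parse_genotype",
    "format_genotype",
    "code_genotype",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "aggregate_counts",
    "aggregate_joint",
    "build_two_by_four",
    "call_rate",
    "save_tables_yaml",
    "load_tables_yaml",
]

MISSING_TOKEN = "NA"

MARKER_KINDS = ("snp", "presence_absence", "carrier_binary")
CODING_MODELS = ("dominant", "additive", "recessive")


class ParseError(ValueError):
    """Raised for malformed cohort files, with line/column context."""


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one genotyped marker.

    ``minor_allele_label`` is purely descriptive.  For
    ``presence_absence`` markers the "minor"/risk state is the null
    homozygote; for ``carrier_binary`` markers it is positive carriage.
    """

    name: str
    kind: str = "snp"
    minor_allele_label: str = ""
    risk_coding_default: str = "dominant"

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.risk_coding_default not in CODING_MODELS:
            raise ValueError(
                f"unknown risk coding {self.risk_coding_default!r}"
            )


def genotype_levels(marker: MarkerDef) -> tuple:
    """Observable genotype states of a marker, reference state first."""
    if marker.kind == "snp":
        return (0, 1, 2)
    if marker.kind == "presence_absence":
        return ("carrier", "null")
    return ("neg", "pos")


def parse_genotype(token: str, marker: MarkerDef):
    """Parse one genotype token; raises ``ValueError`` on an illegal code."""
    token = token.strip()
    if token == MISSING_TOKEN or token == "":
        return None
    if marker.kind == "snp":
        if token in ("0", "1", "2"):
            return int(token)
    elif token in genotype_levels(marker):
        return token
    raise ValueError(
        f"illegal genotype {token!r} for {marker.kind} marker {marker.name!r}"
    )


def format_genotype(g) -> str:
    return MISSING_TOKEN if g is None else str(g)


def code_genotype(g, model: str, marker: MarkerDef) -> int:
    """Numeric risk coding of one non-missing genotype.

    dominant  -> 1 if at least one minor/risk allele (carriage of the
                 exposure state for binary marker kinds);
    additive  -> minor-allele dosage 0/1/2 (SNPs only: heterozygotes are
                 unobservable for the other kinds);
    recessive -> 1 only for the minor-allele homozygote.
    """
    if g is None:
        raise ValueError("cannot code a missing genotype")
    if model not in CODING_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if marker.kind == "snp":
        if model == "dominant":
            return int(g > 0)
        if model == "recessive":
            return int(g == 2)
        return int(g)
    if model == "additive":
        raise ValueError(
            f"additive coding undefined for {marker.kind} marker "
            f"{marker.name!r}: heterozygotes are unobservable"
        )
    exposed = "null" if marker.kind == "presence_absence" else "pos"
    return int(g == exposed)


@dataclass
class CohortRecord:
    """One study participant.

    ``status`` is ``"case"``/``"control"``; ``accp`` (anti-CCP antibody
    status) is ``"positive"``/``"negative"`` for patients and ``None``
    for controls, for whom it is never measured.
    """

    sample_id: str
    status: str
    accp: Optional[str]
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.accp not in ("positive", "negative", None):
            raise ValueError(f"unknown anti-CCP status {self.accp!r}")
        if self.status == "control" and self.accp is not None:
            raise ValueError("controls must have missing anti-CCP status")


@dataclass
class GenotypeCountTable:
    """Genotype counts of one marker in one group of people.

    For binary marker kinds (``presence_absence``, ``carrier_binary``)
    the reference state is counted in ``n_common_hom``, the exposure
    state in ``n_minor_hom``, and ``n_het`` must be zero.
    """

    marker: MarkerDef
    group_label: str
    n_common_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        for c in (self.n_common_hom, self.n_het, self.n_minor_hom):
            if c < 0:
                raise ValueError("negative genotype count")
        if self.marker.kind != "snp" and self.n_het != 0:
            raise ValueError(
                f"{self.marker.kind} marker {self.marker.name!r} cannot have "
                "heterozygote counts"
            )

    @property
    def total(self) -> int:
        return self.n_common_hom + self.n_het + self.n_minor_hom

    def as_array(self) -> np.ndarray:
        if self.marker.kind == "snp":
            return np.array(
                [self.n_common_hom, self.n_het, self.n_minor_hom], dtype=int
            )
        return np.array([self.n_common_hom, self.n_minor_hom], dtype=int)


@dataclass
class JointGenotypeTable:
    """Cross-tabulation of two markers within one outcome group.

    ``counts[i, j]`` counts people with ``genotype_levels(marker1)[i]``
    and ``genotype_levels(marker2)[j]``.
    """

    marker1: MarkerDef
    marker2: MarkerDef
    group_label: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k1 = len(genotype_levels(self.marker1))
        k2 = len(genotype_levels(self.marker2))
        if self.counts.shape != (k1, k2):
            raise ValueError(
                f"joint table shape {self.counts.shape} does not match marker "
                f"level counts ({k1}, {k2})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative joint genotype count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def margin(self, which: int) -> GenotypeCountTable:
        """Per-marker genotype count table implied by the joint counts."""
        marker = self.marker1 if which == 1 else self.marker2
        m = self.counts.sum(axis=2 - which)
        if marker.kind == "snp":
            return GenotypeCountTable(
                marker, self.group_label, int(m[0]), int(m[1]), int(m[2])
            )
        return GenotypeCountTable(marker, self.group_label, int(m[0]), 0, int(m[1]))

    def transposed(self) -> "JointGenotypeTable":
        return JointGenotypeTable(
            self.marker2, self.marker1, self.group_label, self.counts.T
        )


#: Order of the four joint-exposure categories in a 2x4 table; the
#: doubly-unexposed category (0, 0) is always the reference.
EXPOSURE_ORDER = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass
class TwoByFourTable:
    """Joint counts of two binary exposures against a binary outcome.

    ``counts`` has one row per exposure category in :data:`EXPOSURE_ORDER`
    and two columns (outcome positive, outcome negative).
    """

    e1_name: str
    e2_name: str
    outcome_pos_label: str
    outcome_neg_label: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 2):
            raise ValueError("2x4 table requires a 4x2 count array")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EffectEstimate:
    """Point estimate with its confidence interval on the reported scale.

    ``scale`` tags the estimand (OR, ROR, RERI, AP, S); ``flags`` carries
    non-fatal analysis annotations such as continuity corrections.
    """

    scale: str
    est: float
    lo: float
    hi: float
    p: float = float("nan")
    model_tag: str = ""
    alpha: float = 0.05
    flags: tuple = ()

    def ci_contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


# ---------------------------------------------------------------------------
# cohort TSV I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ("sample_id", "status", "accp")
_STATUS_TOKENS = {"case": "case", "control": "control"}
_ACCP_TOKENS = {"pos": "positive", "neg": "negative", MISSING_TOKEN: None}
_ACCP_OUT = {"positive": "pos", "negative": "neg", None: MISSING_TOKEN}


def read_cohort_tsv(path, marker_defs: Sequence[MarkerDef]) -> list:
    """Read a tab-separated cohort file into :class:`CohortRecord` objects.

    The header must contain ``sample_id  status  accp`` followed by one
    column per marker.  Every malformed token raises :class:`ParseError`
    naming the offending line and column; duplicate sample ids are
    rejected.
    """
    defs = {m.name: m for m in marker_defs}
    records = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(header[:3]) != _BASE_COLUMNS:
            raise ParseError(
                f"{path}: header must start with {_BASE_COLUMNS}, got {header[:3]}"
            )
        marker_cols = header[3:]
        for name in marker_cols:
            if name not in defs:
                raise ParseError(f"{path}: undefined marker column {name!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            sample_id = row[0].strip()
            if sample_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            if row[1] not in _STATUS_TOKENS:
                raise ParseError(
                    f"{path}:{lineno}: column 'status': unknown token {row[1]!r}"
                )
            status = _STATUS_TOKENS[row[1]]
            if row[2] not in _ACCP_TOKENS:
                raise ParseError(
                    f"{path}:{lineno}: column 'accp': unknown token {row[2]!r}"
                )
            accp = _ACCP_TOKENS[row[2]]
            genotypes = {}
            for name, token in zip(marker_cols, row[3:]):
                try:
                    genotypes[name] = parse_genotype(token, defs[name])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: column {name!r}: {exc}") from None
            try:
                records.append(
                    CohortRecord(sample_id, status, accp, genotypes)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return records


def write_cohort_tsv(records: Iterable[CohortRecord], path, marker_defs) -> None:
    """Write records to TSV; inverse of :func:`read_cohort_tsv`."""
    names = [m.name for m in marker_defs]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_BASE_COLUMNS) + names)
        for rec in records:
            writer.writerow(
                [rec.sample_id, rec.status, _ACCP_OUT[rec.accp]]
                + [format_genotype(rec.genotypes.get(n)) for n in names]
            )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

GROUP_SELECTORS = {
    "cases": lambda r: r.status == "case",
    "controls": lambda r: r.status == "control",
    "accp_pos": lambda r: r.status == "case" and r.accp == "positive",
    "accp_neg": lambda r: r.status == "case" and r.accp == "negative",
}


def _select(records, group):
    if callable(group):
        return [r for r in records if group(r)], getattr(group, "__name__", "custom")
    try:
        pred = GROUP_SELECTORS[group]
    except KeyError:
        raise ValueError(
            f"unknown group selector {group!r}; expected one of {sorted(GROUP_SELECTORS)}"
        ) from None
    return [r for r in records if pred(r)], group


def _check_marker_present(records, marker: MarkerDef) -> None:
    if records and not any(marker.name in r.genotypes for r in records):
        raise KeyError(f"marker {marker.name!r} absent from records")


def aggregate_counts(records, marker: MarkerDef, group) -> GenotypeCountTable:
    """Tally a marker's genotype counts within one group.

    Missing genotypes are excluded (complete-case per marker), so the
    table total can be below the group size.
    """
    subset, label = _select(records, group)
    _check_marker_present(records, marker)
    levels = genotype_levels(marker)
    tally = {lv: 0 for lv in levels}
    for r in subset:
        g = r.genotypes.get(marker.name)
        if g is not None:
            tally[g] += 1
    if marker.kind == "snp":
        return GenotypeCountTable(marker, label, tally[0], tally[1], tally[2])
    return GenotypeCountTable(marker, label, tally[levels[0]], 0, tally[levels[1]])


def aggregate_joint(records, marker1: MarkerDef, marker2: MarkerDef, group) -> JointGenotypeTable:
    """Cross-tabulate two markers within one group (complete-case on both)."""
    subset, label = _select(records, group)
    _check_marker_present(records, marker1)
    _check_marker_present(records, marker2)
    lv1 = genotype_levels(marker1)
    lv2 = genotype_levels(marker2)
    counts = np.zeros((len(lv1), len(lv2)), dtype=int)
    idx1 = {g: i for i, g in enumerate(lv1)}
    idx2 = {g: i for i, g in enumerate(lv2)}
    for r in subset:
        g1 = r.genotypes.get(marker1.name)
        g2 = r.genotypes.get(marker2.name)
        if g1 is not None and g2 is not None:
            counts[idx1[g1], idx2[g2]] += 1
    return JointGenotypeTable(marker1, marker2, label, counts)


def build_two_by_four(records, e1, e2, outcome) -> TwoByFourTable:
    """Build the 2x4 joint-exposure table for two binary-coded exposures.

    ``e1`` and ``e2`` are ``(MarkerDef, coding)`` pairs whose coding must
    be binary (dominant or recessive); ``outcome`` is a pair of group
    selectors ``(positive_group, negative_group)``.  Records missing any
    of the two genotypes, or falling in neither outcome group, are
    dropped (complete-case).
    """
    (m1, c1), (m2, c2) = e1, e2
    for m, c in ((m1, c1), (m2, c2)):
        if c == "additive":
            raise ValueError("2x4 exposures must be binary-coded, not additive")
    pos, pos_label = _select(records, outcome[0])
    neg, neg_label = _select(records, outcome[1])
    if not pos or not neg:
        raise ValueError(
            f"empty outcome group ({pos_label}: {len(pos)}, {neg_label}: {len(neg)})"
        )
    counts = np.zeros((4, 2), dtype=int)
    cell = {combo: i for i, combo in enumerate(EXPOSURE_ORDER)}
    for col, subset in ((0, pos), (1, neg)):
        for r in subset:
            g1 = r.genotypes.get(m1.name)
            g2 = r.genotypes.get(m2.name)
            if g1 is None or g2 is None:
                continue
            x1 = code_genotype(g1, c1, m1)
            x2 = code_genotype(g2, c2, m2)
            counts[cell[(x1, x2)], col] += 1
    return TwoByFourTable(m1.name, m2.name, pos_label, neg_label, counts)


def call_rate(records, marker: MarkerDef) -> float:
    """Fraction of records with a non-missing genotype for a marker."""
    if not records:
        raise ValueError("no records")
    _check_marker_present(records, marker)
    called = sum(1 for r in records if r.genotypes.get(marker.name) is not None)
    return called / len(records)


# ---------------------------------------------------------------------------
# aggregated-table YAML round trip (counts-only entry path)
# ---------------------------------------------------------------------------

def _marker_to_dict(m: MarkerDef) -> dict:
    return {
        "name": m.name,
        "kind": m.kind,
        "minor_allele_label": m.minor_allele_label,
        "risk_coding_default": m.risk_coding_default,
    }


def _table_to_dict(obj) -> dict:
    if isinstance(obj, GenotypeCountTable):
        return {
            "type": "genotype_counts",
            "marker": _marker_to_dict(obj.marker),
            "group_label": obj.group_label,
            "n_common_hom": int(obj.n_common_hom),
            "n_het": int(obj.n_het),
            "n_minor_hom": int(obj.n_minor_hom),
        }
    if isinstance(obj, JointGenotypeTable):
        return {
            "type": "joint_genotype",
            "marker1": _marker_to_dict(obj.marker1),
            "marker2": _marker_to_dict(obj.marker2),
            "group_label": obj.group_label,
            "counts": obj.counts.tolist(),
        }
    if isinstance(obj, TwoByFourTable):
        return {
            "type": "two_by_four",
            "e1_name": obj.e1_name,
            "e2_name": obj.e2_name,
            "outcome_pos_label": obj.outcome_pos_label,
            "outcome_neg_label": obj.outcome_neg_label,
            "counts": obj.counts.tolist(),
        }
    raise TypeError(f"cannot serialise {type(obj).__name__}")


def _table_from_dict(d: Mapping):
    kind = d.get("type")
    if kind == "genotype_counts":
        return GenotypeCountTable(
            MarkerDef(**d["marker"]),
            d["group_label"],
            d["n_common_hom"],
            d["n_het"],
            d["n_minor_hom"],
        )
    if kind == "joint_genotype":
        return JointGenotypeTable(
            MarkerDef(**d["marker1"]),
            MarkerDef(**d["marker2"]),
            d["group_label"],
            np.array(d["counts"]),
        )
    if kind == "two_by_four":
        return TwoByFourTable(
            d["e1_name"],
            d["e2_name"],
            d["outcome_pos_label"],
            d["outcome_neg_label"],
            np.array(d["counts"]),
        )
    raise ValueError(f"unknown table type {kind!r}")


def save_tables_yaml(tables: Mapping[str, object], path) -> None:
    """Serialise a name -> table mapping (any of the three table types)."""
    payload = {name: _table_to_dict(t) for name, t in tables.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_tables_yaml(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: _table_from_dict(d) for name, d in payload.items()}
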