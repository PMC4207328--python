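"""Cohort parsing, genotype coding and count aggregation."""

import numpy as np
import pytest

from epistat import (
    CohortRecord,
    MarkerDef,
    ParseError,
    aggregate_counts,
    aggregate_joint,
    build_two_by_four,
    code_genotype,
    read_cohort_tsv,
    write_cohort_tsv,
)
from epistat.tables_io import call_rate, load_tables_yaml, save_tables_yaml

SNP = MarkerDef("snp1")
DEL = MarkerDef("gstm1", "presence_absence")
CAR = MarkerDef("se", "carrier_binary")
DEFS = [SNP, DEL, CAR]


def _write(tmp_path, text):
    p = tmp_path / "cohort.tsv"
    p.write_text(text)
    return p


HEADER = "sample_id\tstatus\taccp\tsnp1\tgstm1\tse\n"


def test_basic_parse_and_missing(tmp_path):
    p = _write(
        tmp_path,
        HEADER
        + "a\tcase\tpos\t2\tnull\tpos\n"
        + "b\tcase\tneg\tNA\tcarrier\tneg\n"
        + "c\tcontrol\tNA\t0\tNA\tpos\n",
    )
    recs = read_cohort_tsv(p, DEFS)
    assert len(recs) == 3
    assert recs[0].genotypes == {"snp1": 2, "gstm1": "null", "se": "pos"}
    assert recs[1].genotypes["snp1"] is None
    assert recs[2].status == "control" and recs[2].accp is None


@pytest.mark.parametrize(
    "row, fragment",
    [
        ("a\tcase\tpos\t3\tnull\tpos", "snp1"),          # dosage out of range
        ("a\tcase\tpos\t1\t2\tpos", "gstm1"),            # numeric code for deletion marker
        ("a\tsick\tpos\t1\tnull\tpos", "status"),
        ("a\tcase\tmaybe\t1\tnull\tpos", "accp"),
        ("a\tcontrol\tpos\t1\tnull\tpos", "anti-CCP"),   # controls are never antibody-typed
    ],
)
def test_parse_errors_name_line_and_column(tmp_path, row, fragment):
    p = _write(tmp_path, HEADER + row + "\n")
    with pytest.raises(ParseError, match=fragment) as exc:
        read_cohort_tsv(p, DEFS)
    assert ":2" in str(exc.value)


def test_duplicate_sample_id_rejected(tmp_path):
    p = _write(
        tmp_path,
        HEADER + "a\tcase\tpos\t1\tnull\tpos\n" + "a\tcontrol\tNA\t0\tnull\tneg\n",
    )
    with pytest.raises(ParseError, match="duplicate"):
        read_cohort_tsv(p, DEFS)


def test_tsv_round_trip_is_identity(tmp_path):
    recs = [
        CohortRecord("a", "case", "positive", {"snp1": 1, "gstm1": "null", "se": "pos"}),
        CohortRecord("b", "case", "negative", {"snp1": None, "gstm1": "carrier", "se": "neg"}),
        CohortRecord("c", "control", None, {"snp1": 0, "gstm1": None, "se": "pos"}),
    ]
    p = tmp_path / "out.tsv"
    write_cohort_tsv(recs, p, DEFS)
    assert read_cohort_tsv(p, DEFS) == recs


@pytest.mark.parametrize(
    "g, model, marker, expected",
    [
        (1, "dominant", SNP, 1),
        (1, "recessive", SNP, 0),
        (2, "recessive", SNP, 1),
        (2, "additive", SNP, 2),
        ("null", "dominant", DEL, 1),
        ("carrier", "dominant", DEL, 0),
        ("pos", "dominant", CAR, 1),
        ("neg", "recessive", CAR, 0),
    ],
)
def test_code_genotype(g, model, marker, expected):
    assert code_genotype(g, model, marker) == expected


def test_additive_coding_rejected_without_heterozygotes():
    with pytest.raises(ValueError, match="unobservable"):
        code_genotype("null", "additive", DEL)
    with pytest.raises(ValueError, match="unobservable"):
        code_genotype("pos", "additive", CAR)


def _tiny_cohort():
    rows = [
        ("case", "positive", 0, "null", "pos"),
        ("case", "positive", 1, "carrier", "pos"),
        ("case", "negative", 2, "null", "neg"),
        ("case", "negative", 1, "null", "pos"),
        ("case", "positive", None, "carrier", "neg"),
        ("case", "negative", 0, None, "pos"),
        ("control", None, 0, "carrier", "neg"),
        ("control", None, 1, "null", "pos"),
        ("control", None, 2, "carrier", "neg"),
        ("control", None, 0, "null", None),
    ]
    return [
        CohortRecord(f"s{i}", st, ac, {"snp1": g, "gstm1": d, "se": c})
        for i, (st, ac, g, d, c) in enumerate(rows)
    ]


def test_aggregate_counts_matches_hand_tally():
    recs = _tiny_cohort()
    t = aggregate_counts(recs, SNP, "cases")
    assert (t.n_common_hom, t.n_het, t.n_minor_hom) == (2, 2, 1)  # missing excluded
    t = aggregate_counts(recs, DEL, "controls")
    assert (t.n_common_hom, t.n_minor_hom) == (2, 2)
    t = aggregate_counts(recs, CAR, "accp_pos")
    assert (t.n_common_hom, t.n_minor_hom) == (1, 2)


def test_aggregate_counts_group_margins_sum_to_cohort():
    recs = _tiny_cohort()
    whole = aggregate_counts(recs, SNP, lambda r: True)
    parts = [aggregate_counts(recs, SNP, g) for g in ("cases", "controls")]
    assert whole.as_array().tolist() == sum(p.as_array() for p in parts).tolist()


def test_aggregate_counts_empty_group_and_missing_marker():
    recs = [CohortRecord("x", "case", "positive", {"snp1": 1})]
    t = aggregate_counts(recs, SNP, "controls")
    assert t.total == 0
    with pytest.raises(KeyError):
        aggregate_counts(recs, DEL, "cases")


def test_simulated_maf_within_three_binomial_se(rng):
    from epistat import SimScenario, simulate_cohort
    from epistat.assoc_qc import maf

    scen = SimScenario(
        n_cases=0, n_controls=10_000, markers=[(SNP, 0.25)], seed=int(rng.integers(2**31))
    )
    t = aggregate_counts(simulate_cohort(scen), SNP, "controls")
    se = np.sqrt(0.25 * 0.75 / (2 * t.total))
    assert abs(maf(t) - 0.25) < 3 * se


def test_joint_table_margins_match_per_marker_tables():
    recs = [r for r in _tiny_cohort() if None not in
            (r.genotypes["snp1"], r.genotypes["gstm1"])]
    j = aggregate_joint(recs, SNP, DEL, "cases")
    assert j.margin(1).as_array().tolist() == \
        aggregate_counts(recs, SNP, "cases").as_array().tolist()
    assert j.margin(2).as_array().tolist() == \
        aggregate_counts(recs, DEL, "cases").as_array().tolist()


def test_build_two_by_four_hand_tally():
    recs = _tiny_cohort()
    t = build_two_by_four(
        recs, (DEL, "dominant"), (CAR, "dominant"), ("accp_pos", "accp_neg")
    )
    # complete-case patients: s0 (null,se+,accp+), s1 (carrier,se+,accp+),
    # s2 (null,se-,accp-), s3 (null,se+,accp-), s4 (carrier,se-,accp+);
    # s5 is dropped for its missing deletion genotype
    assert t.counts.tolist() == [[1, 0], [0, 1], [1, 0], [1, 1]]


def test_build_two_by_four_reproduces_published_counts(fixtures):
    """Records rebuilt from the bundled 2x4 table aggregate back to it."""
    t4 = fixtures["gstm1_se_2x4"]
    recs = []
    i = 0
    for row, (e1, e2) in zip(t4.counts, [(0, 0), (1, 0), (0, 1), (1, 1)]):
        for col, accp in ((0, "positive"), (1, "negative")):
            for _ in range(row[col]):
                recs.append(CohortRecord(
                    f"r{i}", "case", accp,
                    {"gstm1": "null" if e1 else "carrier",
                     "se": "pos" if e2 else "neg"},
                ))
                i += 1
    rebuilt = build_two_by_four(
        recs, (DEL, "dominant"), (CAR, "dominant"), ("accp_pos", "accp_neg")
    )
    assert rebuilt.counts.tolist() == [[84, 79], [90, 74], [130, 54], [148, 62]]


def test_build_two_by_four_empty_outcome_group_errors():
    recs = [CohortRecord("a", "case", "positive", {"gstm1": "null", "se": "pos"})]
    with pytest.raises(ValueError, match="empty outcome group"):
        build_two_by_four(recs, (DEL, "dominant"), (CAR, "dominant"),
                          ("accp_pos", "accp_neg"))


def test_call_rate():
    recs = _tiny_cohort()
    assert call_rate(recs, SNP) == pytest.approx(0.9)


def test_tables_yaml_round_trip(tmp_path, fixtures):
    path = tmp_path / "tables.yaml"
    bundle = {
        "cases": fixtures["ptpn22_rs2476601"]["cases"],
        "t4": fixtures["gstm1_se_2x4"],
    }
    save_tables_yaml(bundle, path)
    back = load_tables_yaml(path)
    assert back["cases"].as_array().tolist() == [1383, 325, 35]
    assert back["t4"].counts.tolist() == bundle["t4"].counts.tolist()
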