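"""Pseudonymized extraction: request parsing, key tables, leak-freedom."""

import re

import numpy as np
import pytest

from mds.errors import (
    AmbiguousExtension,
    BadHeader,
    DuplicatePatient,
    KeyPathMissing,
    MalformedToken,
    OutputNotEmpty,
)
from mds.extract import (
    KeyRow,
    KeyTable,
    RequestRow,
    extract_dataset,
    make_key_table,
    read_key_table,
    read_request,
    write_key_table,
)

from conftest import tree_checksums

PATIENT_TOKEN = re.compile(r"H\d{3,}")

ANNOTATION_REQUEST = "Pat,Mod,Phase,Cl 1\n" + "".join(
    f"H{i:03d},CT001,Porto,IM\n" for i in range(1, 8)
)
TRAINING_REQUEST = "Pat,Mod,Phase,Cl 1,Cl 2\n" + "".join(
    f"H{i:03d},CT001,Porto,IM,LP\n" for i in range(1, 8)
)


def _request_rows(n, tags=("IM",)):
    return [RequestRow(f"H{i:03d}", "CT001", "Porto", tuple(tags)) for i in range(1, n + 1)]


# ---- request CSV ---------------------------------------------------------


def test_read_annotation_request(tmp_path):
    path = tmp_path / "req.csv"
    path.write_text(ANNOTATION_REQUEST)
    rows = read_request(path)
    assert len(rows) == 7
    assert all(r.tags == ("IM",) for r in rows)
    assert rows[0] == RequestRow("H001", "CT001", "Porto", ("IM",))


def test_read_training_request_with_two_classes(tmp_path):
    path = tmp_path / "req.csv"
    path.write_text(TRAINING_REQUEST)
    rows = read_request(path)
    assert len(rows) == 7
    assert all(r.tags == ("IM", "LP") for r in rows)


def test_read_request_accepts_cl1_spelling_and_header_only(tmp_path):
    path = tmp_path / "req.csv"
    path.write_text("Pat,Mod,Phase,Cl1,Cl2\nH001,MR001,T1,IM,HV\n")
    assert read_request(path)[0].tags == ("IM", "HV")
    empty = tmp_path / "empty.csv"
    empty.write_text("Pat,Mod,Phase,Cl 1\n")
    assert read_request(empty) == []


def test_read_request_rejects_bad_input(tmp_path):
    bad_header = tmp_path / "a.csv"
    bad_header.write_text("Patient,Mod,Phase,Cl 1\nH001,CT001,Porto,IM\n")
    with pytest.raises(BadHeader):
        read_request(bad_header)

    bad_token = tmp_path / "b.csv"
    bad_token.write_text("Pat,Mod,Phase,Cl 1\nP01,CT001,Porto,IM\n")
    with pytest.raises(MalformedToken):
        read_request(bad_token)

    no_tags = tmp_path / "c.csv"
    no_tags.write_text("Pat,Mod,Phase,Cl 1\nH001,CT001,Porto,\n")
    with pytest.raises(MalformedToken):
        read_request(no_tags)


# ---- key table -----------------------------------------------------------


def test_single_patient_gets_case001():
    kt = make_key_table(["H001"], seed=123)
    assert kt.mapping == {"H001": "Case001"}


def test_key_assignment_matches_reference_shuffle():
    """The pseudonym draw is: shuffle 1..N with the seeded generator, then
    consume front-first in patient order."""
    patients = [f"H{i:03d}" for i in range(1, 8)]
    for seed in (11, 99):
        kt = make_key_table(patients, seed=seed)
        expected = np.random.default_rng(seed).permutation(np.arange(1, 8))
        assert [kt.mapping[p] for p in patients] == [f"Case{n:03d}" for n in expected]


def test_key_bijection_and_seed_sensitivity():
    patients = [f"H{i:03d}" for i in range(1, 101)]
    kt1 = make_key_table(patients, seed=5)
    cases = sorted(kt1.mapping.values())
    assert cases == [f"Case{i:03d}" for i in range(1, 101)]
    kt2 = make_key_table(patients, seed=5)
    assert kt1.mapping == kt2.mapping  # deterministic for a fixed seed
    kt3 = make_key_table(patients, seed=6)
    assert kt1.mapping != kt3.mapping  # distinct seeds give distinct orders


def test_duplicate_patients_rejected():
    with pytest.raises(DuplicatePatient):
        make_key_table(["H001", "H001"], seed=1)


def test_key_table_round_trip_identity(tmp_path):
    rng = np.random.default_rng(42)
    for i in range(50):
        n = int(rng.integers(1, 20))
        rows = [
            KeyRow(f"H{j:03d}", "CT001", "Porto", "IM", f"Case{int(p):03d}")
            for j, p in enumerate(rng.permutation(np.arange(1, n + 1)), start=1)
        ]
        kt = KeyTable(rows=rows, seed_record=int(rng.integers(0, 2**31)))
        path = tmp_path / f"key_{i}.csv"
        write_key_table(kt, path)
        back = read_key_table(path)
        assert back.rows == kt.rows
        assert back.seed_record == kt.seed_record


def test_key_table_csv_dialect(tmp_path):
    kt = make_key_table(["H001", "H002"], seed=0, context=[
        ("H001", "CT001", "Porto", "IM"),
        ("H002", "CT001", "Porto", "IM"),
    ])
    path = tmp_path / "key.csv"
    write_key_table(kt, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "# seed=0"
    assert lines[1] == "Pat,Mod,Phase,Cl 1,Ns"
    with pytest.raises(BadHeader):
        bad = tmp_path / "bad.csv"
        bad.write_text("Pat,Mod,Ns\n")
        read_key_table(bad)


# ---- extraction ----------------------------------------------------------


def test_extract_replaces_patient_tokens_everywhere(tmp_path, small_cohort):
    main, _ = small_cohort
    out = tmp_path / "OUT"
    report = extract_dataset(main, _request_rows(7), out, mode="anonymize", seed=3)
    assert len(report.copied) == 6  # H006 has no data
    assert report.n_patients == 7
    assert [(r.patient_id, t) for r, t in report.missing] == [("H006", "IM")]
    # leak-freedom: nothing under the export mentions a patient token
    for path in out.rglob("*"):
        assert not PATIENT_TOKEN.search(str(path.relative_to(out)))
    # the export mirrors the four-level tree shape
    copied_dest = report.copied[0][1]
    assert copied_dest.parent.parent.parent.parent == out


def test_extract_leaves_source_untouched(tmp_path, small_cohort):
    main, _ = small_cohort
    before = tree_checksums(main)
    extract_dataset(main, _request_rows(7), tmp_path / "OUT", mode="anonymize", seed=3)
    assert tree_checksums(main) == before


def test_extract_is_deterministic_per_seed(tmp_path, small_cohort):
    main, _ = small_cohort
    r1 = extract_dataset(main, _request_rows(7), tmp_path / "o1", mode="anonymize", seed=17)
    r2 = extract_dataset(main, _request_rows(7), tmp_path / "o2", mode="anonymize", seed=17)
    layout1 = sorted(d.relative_to(tmp_path / "o1") for _, d in r1.copied)
    layout2 = sorted(d.relative_to(tmp_path / "o2") for _, d in r2.copied)
    assert layout1 == layout2
    r3 = extract_dataset(main, _request_rows(7), tmp_path / "o3", mode="anonymize", seed=18)
    layout3 = sorted(d.relative_to(tmp_path / "o3") for _, d in r3.copied)
    assert layout1 != layout3


def test_anonymize_writes_no_key_deidentify_does(tmp_path, small_cohort):
    main, _ = small_cohort
    extract_dataset(main, _request_rows(3), tmp_path / "anon", mode="anonymize", seed=1)
    assert not list((tmp_path / "anon").rglob("*.csv"))

    key_path = tmp_path / "key.csv"
    extract_dataset(
        main, _request_rows(3), tmp_path / "deid", mode="deidentify", seed=1, key_path=key_path
    )
    kt = read_key_table(key_path)
    assert sorted(kt.mapping) == ["H001", "H002", "H003"]
    assert kt.seed_record == 1

    with pytest.raises(KeyPathMissing):
        extract_dataset(main, _request_rows(3), tmp_path / "d2", mode="deidentify", seed=1)


def test_empty_request(tmp_path, small_cohort):
    main, _ = small_cohort
    report = extract_dataset(main, [], tmp_path / "OUT", mode="anonymize", seed=1)
    assert report.copied == [] and report.missing == [] and report.n_patients == 0


def test_output_must_be_empty(tmp_path, small_cohort):
    main, _ = small_cohort
    out = tmp_path / "OUT"
    out.mkdir()
    (out / "stale").write_text("x")
    with pytest.raises(OutputNotEmpty):
        extract_dataset(main, _request_rows(1), out, mode="anonymize", seed=1)


def test_ambiguous_extension_is_an_error(tmp_path, small_cohort):
    main, _ = small_cohort
    leaf = main / "H001" / "CT001" / "Porto"
    (leaf / "H001_CT001_Porto_IM.nii").write_bytes(b"dup")
    with pytest.raises(AmbiguousExtension):
        extract_dataset(main, _request_rows(1), tmp_path / "OUT", mode="anonymize", seed=1)


def test_case_ids_shared_across_a_patients_rows(tmp_path, small_cohort):
    main, _ = small_cohort
    request = [
        RequestRow("H001", "CT001", "Porto", ("IM",)),
        RequestRow("H001", "CT001", "Porto", ("LP",)),
        RequestRow("H002", "CT001", "Porto", ("IM",)),
    ]
    key_path = tmp_path / "key.csv"
    extract_dataset(
        main, request, tmp_path / "OUT", mode="deidentify", seed=2, key_path=key_path
    )
    kt = read_key_table(key_path)
    h1_cases = {r.case_id for r in kt.rows if r.patient_id == "H001"}
    assert len(h1_cases) == 1  # one pseudonym per patient, not per row
    assert len(kt.mapping) == 2
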