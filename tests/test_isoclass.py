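"""Classifier behavior, canonical naming, quantification, summaries."""

import logging

import pytest
from hypothesis import given, strategies as st

from conftest import oracle_classify, random_instances
from isomirkit import (
    ClassifierConfig,
    IsoMiRCall,
    NameParseError,
    Unassigned,
    classify_read,
    is_seed_shifted,
    name_call,
    parse_name,
    quantify,
    seed_of,
    type_distribution,
)
from isomirkit.isoclass import FastqError


@pytest.mark.parametrize(
    "read, parent, category, o5, o3",
    [
        ("UUCACAGUGGCUAAGUUCUGC", "miR-27b-3p", "refseq", 0, 0),
        ("UCACAGUGGCUAAGUUCUGC", "miR-27b-3p", "iso5", 1, 0),
        ("CCAGUGUUCAGACUACCUGUUC", "miR-199a-5p", "iso5", 1, 0),
        ("CUGUACAGGCCACUGCCUUGC", "let-7g-5p", "refseq", 0, 0),
    ],
)
def test_observed_variant_reads(refset, read, parent, category, o5, o3):
    call = classify_read(read, refset)
    assert isinstance(call, IsoMiRCall)
    assert (call.parent, call.category, call.offset5, call.offset3) == (
        parent, category, o5, o3,
    )


def test_nontemplated_tail_detected(refset):
    # fixture flanks start with C/G, so an AA suffix is never templated
    call = classify_read("UUCACAGUGGCUAAGUUCUGC" + "AA", refset)
    assert call.category == "nontemplate"
    assert (call.offset5, call.offset3, call.tail) == (0, 2, "AA")
    assert call.name == "miR-27b-3p_nont_0_+2_AA"


def test_unassignable_reads(refset):
    too_long_tail = classify_read("UUCACAGUGGCUAAGUUCUGC" + "AAAAAA", refset)
    assert too_long_tail == Unassigned(
        read_sequence="UUCACAGUGGCUAAGUUCUGCAAAAAA", reason="tail_too_long"
    )
    assert classify_read("ACGU" * 4, refset).reason == "no_match"
    assert classify_read("ACGUACGUACGUACG", refset).reason == "length"  # 15 nt
    with pytest.raises(ValueError, match="non-RNA"):
        classify_read("UUCACAGUGGCUAAGUUCUGN", refset)


@pytest.mark.parametrize(
    "fields, expected",
    [
        (("miR-449c-5p", "iso3", 0, -2, ""), "miR-449c-5p_t_0_-2"),
        (("miR-127-3p", "nontemplate", 0, 2, "AU"), "miR-127-3p_nont_0_+2_AU"),
        (("let-7g-5p", "refseq", 0, 0, ""), "let-7g-5p"),
        (("miR-30d-5p", "iso5_3", 1, 2, ""), "miR-30d-5p_t_+1_+2"),
    ],
)
def test_canonical_names(fields, expected):
    parent, category, o5, o3, tail = fields
    call = IsoMiRCall(
        parent=parent, category=category, offset5=o5, offset3=o3, tail=tail,
        read_sequence="",
    )
    assert name_call(call) == expected


@pytest.mark.parametrize(
    "bad", ["miR-92a-3p_x_0_0", "miR-92a-3p_t_0_0_AA", "miR-92a-3p_nont_0_+2"]
)
def test_malformed_names_rejected(bad):
    with pytest.raises(NameParseError):
        parse_name(bad)


@given(
    parent=st.from_regex(r"(let|miR)-[0-9]{1,3}[a-z]?-(5p|3p)", fullmatch=True),
    o5=st.integers(-5, 5),
    o3=st.integers(-5, 8),
    tail=st.text(alphabet="ACGU", min_size=0, max_size=3),
)
def test_name_roundtrip_property(parent, o5, o3, tail):
    if tail:
        category = "nontemplate"
    elif (o5, o3) == (0, 0):
        category = "refseq"
    elif o3 == 0:
        category = "iso5"
    elif o5 == 0:
        category = "iso3"
    else:
        category = "iso5_3"
    call = IsoMiRCall(
        parent=parent, category=category, offset5=o5, offset3=o3, tail=tail,
        read_sequence="",
    )
    parsed = parse_name(name_call(call))
    assert (parsed.parent, parsed.category, parsed.offset5, parsed.offset3, parsed.tail) == (
        parent, category, o5, o3, tail,
    )


def test_classifier_agrees_with_bruteforce_oracle_smoke():
    config = ClassifierConfig()
    n_assigned = 0
    for read, single in random_instances(seed=20240917, n=800):
        got = classify_read(read, single, config)
        expected = oracle_classify(read, single, config)
        assert got == expected
        if isinstance(got, IsoMiRCall):
            n_assigned += 1
            arm = single.arm(got.parent)
            assert len(read) == len(arm.sequence) - got.offset5 + got.offset3
    assert n_assigned > 100  # both outcomes must actually be exercised


def test_reference_reads_always_classified_refseq(refset):
    for name, arm in refset.arms_by_name.items():
        call = classify_read(arm.sequence, refset)
        assert (call.parent, call.category, call.offset5, call.offset3) == (
            name, "refseq", 0, 0,
        )


def _write_fastq(path, sequences):
    with open(path, "w") as handle:
        for i, seq in enumerate(sequences):
            handle.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def test_quantify_collapses_copies(refset, tmp_path):
    ref = "UUCACAGUGGCUAAGUUCUGC"
    var = "UCACAGUGGCUAAGUUCUGC"
    _write_fastq(tmp_path / "s1.fastq", [ref, var, ref, ref, var])
    _write_fastq(tmp_path / "s2.fastq", [ref])
    counts, unassigned = quantify(
        [("s1", tmp_path / "s1.fastq"), ("s2", tmp_path / "s2.fastq")], refset
    )
    assert counts.loc["miR-27b-3p", "s1"] == 3
    assert counts.loc["miR-27b-3p_t_+1_0", "s1"] == 2
    assert counts.loc["miR-27b-3p", "s2"] == 1
    assert counts.loc["miR-27b-3p_t_+1_0", "s2"] == 0
    assert unassigned.empty


def test_quantify_empty_fastq_warns(refset, tmp_path, caplog):
    (tmp_path / "empty.fastq").write_text("")
    with caplog.at_level(logging.WARNING):
        counts, _ = quantify([("s1", tmp_path / "empty.fastq")], refset)
    assert "no reads" in caplog.text
    assert counts.shape == (0, 1)


def test_quantify_truncated_fastq_names_file(refset, tmp_path):
    bad = tmp_path / "trunc.fastq"
    bad.write_text("@r0\nACGUACGUACGUACGUA\n+\nIIII\n")  # quality shorter than read
    with pytest.raises(FastqError, match="trunc.fastq"):
        quantify([("s1", bad)], refset)


def test_quantify_rejects_duplicate_sample_names(refset, tmp_path):
    _write_fastq(tmp_path / "a.fastq", [])
    with pytest.raises(ValueError, match="unique"):
        quantify([("s", tmp_path / "a.fastq"), ("s", tmp_path / "a.fastq")], refset)


def test_seed_definition_and_shift():
    assert seed_of("UUCACAGUGGCUAAGUUCUGC") == "UCACAGU"
    with pytest.raises(ValueError):
        seed_of("UUCACAG")
    assert is_seed_shifted("miR-27b-3p_t_+1_0") is True
    assert is_seed_shifted("miR-449c-5p_t_0_-2") is False
    assert is_seed_shifted("miR-92a-3p_nont_0_+2_AA") is False


def test_type_distribution_counts_features_not_reads():
    import pandas as pd

    matrix = pd.DataFrame(
        {"s1": [1000, 1, 1, 1]},
        index=["miR-1-5p", "miR-1-5p_t_+1_0", "miR-1-5p_t_0_-1", "miR-2-3p_nont_0_+1_A"],
    )
    dist = type_distribution(matrix)
    assert dist["refseq"] == pytest.approx(25.0)
    assert dist["iso5"] == pytest.approx(25.0)
    assert dist["iso3"] == pytest.approx(25.0)
    assert dist["nontemplate"] == pytest.approx(25.0)
    assert dist.sum() == pytest.approx(100.0, abs=1e-9)
    templated_only = type_distribution(matrix, ["miR-1-5p_t_+1_0", "miR-1-5p_t_0_-1"])
    assert templated_only["nontemplate"] == 0.0
    with pytest.raises(ValueError, match="empty"):
        type_distribution(matrix, [])
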