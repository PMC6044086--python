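"""Locator matching and read reformatting for both adapter layouts."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umikit.extract import (
    ExtractionReport,
    FastqRecord,
    parse_umi_from_name,
    read_fastq,
    reformat_fastq_files,
    reformat_rnaseq_pair,
    reformat_smallrna_read,
    reformat_smallrna_file,
    tag_read_name,
)
from umikit.layouts import LocatorScheme, RnaSeqLayout, SmallRnaLayout, match_locator

ADAPTER = SmallRnaLayout().adapter3


def smallrna_seq(block5="AAACGACCCTACGGG", insert="A" * 22, block3="TTTGTCAAATAGCCC"):
    return block5 + insert + block3 + ADAPTER


def fq(name, seq):
    return FastqRecord(name, seq, "I" * len(seq))


# ---------------------------------------------------------------------------
# match_locator


@pytest.mark.parametrize(
    "window,pattern,max_mm,expected_mm,expected_ok",
    [
        ("ATC", "ATC", 0, 0, True),
        ("AAACGACCCTACGGG", "NNNCGANNNTACNNN", 1, 0, True),
        ("AAACGTCCCTACGGG", "NNNCGANNNTACNNN", 1, 1, True),
        ("AAACGTCCCTACGGG", "NNNCGANNNTACNNN", 0, 1, False),
        ("AAACGTCCCTGCGGG", "NNNCGANNNTACNNN", 1, 2, False),
    ],
)
def test_match_locator(window, pattern, max_mm, expected_mm, expected_ok):
    mm, ok = match_locator(window, LocatorScheme(pattern, max_mm))
    assert (mm, ok) == (expected_mm, expected_ok)


def test_match_locator_length_mismatch_is_error():
    with pytest.raises(ValueError):
        match_locator("AT", LocatorScheme("ATC"))


def test_scheme_u_equals_t():
    # RNA adapters may be written with U; pattern fixed bases normalise to T
    scheme = LocatorScheme("NNNAUCNNNAGUNNN", 1)
    assert scheme.pattern == "NNNATCNNNAGTNNN"
    assert match_locator("GGGATCCCCAGTTTT", scheme) == (0, True)


def test_scheme_invariants():
    with pytest.raises(ValueError):
        LocatorScheme("")
    with pytest.raises(ValueError):
        LocatorScheme("NNN", max_mismatches=1)  # no non-N positions to mismatch
    with pytest.raises(ValueError):
        LocatorScheme("AXC")


def test_umi_space_sizes():
    assert RnaSeqLayout().umi_space_size == 4**5 * 4**5 == 1_048_576
    assert SmallRnaLayout().umi_space_size == 4**18


# ---------------------------------------------------------------------------
# RNA-seq pairs


def test_rnaseq_pair_accepted():
    r1 = fq("p1", "AACGTGGGTCCCCACGT")
    r2 = fq("p1", "TTGCATCATAAAAGTCA")
    x1, x2 = reformat_rnaseq_pair(r1, r2)
    assert x1.accepted and x2.accepted
    assert x1.umi == x2.umi == "AACGTTTGCA"
    assert x1.insert_seq.startswith("CCCC")
    assert x2.insert_seq.startswith("AAAA")
    assert len(x1.insert_seq) == len(x1.insert_quals)


@pytest.mark.parametrize(
    "seq1,reason",
    [
        ("AACGTAAATCCCCACGT", "bad_locator"),  # AAA not in {GGG,TCA,ATC}
        ("AACGTGGG", "short_read"),  # 8 nt < 9-nt prefix
        ("AACGNGGGTCCCCACGT", "n_in_umi"),
    ],
)
def test_rnaseq_pair_rejections(seq1, reason):
    r2 = fq("p1", "TTGCATCATAAAAGTCA")
    x1, x2 = reformat_rnaseq_pair(fq("p1", seq1), r2)
    assert x1.status == x2.status == reason
    assert not x1.accepted


def test_rnaseq_mismatched_ids_error():
    with pytest.raises(ValueError, match="mismatched read IDs"):
        reformat_rnaseq_pair(fq("a", "A" * 20), fq("b", "A" * 20))


def test_rnaseq_mate_suffixes_tolerated():
    x1, _ = reformat_rnaseq_pair(
        fq("p1/1", "AACGTGGGTCCCCACGT"), fq("p1/2", "TTGCATCATAAAAGTCA")
    )
    assert x1.accepted


def test_rnaseq_ligation_base_not_validated():
    # a sequencing error at the ligation position must not discard the pair
    r1 = fq("p1", "AACGTGGGGCCCCACGT")  # position 9 is G, not T
    r2 = fq("p1", "TTGCATCATAAAAGTCA")
    x1, _ = reformat_rnaseq_pair(r1, r2)
    assert x1.accepted


# ---------------------------------------------------------------------------
# small RNA-seq reads


def test_smallrna_accepted():
    x = reformat_smallrna_read(fq("s1", smallrna_seq()))
    assert x.accepted
    assert x.umi == "AAACCCGGG" + "TTTAAACCC"
    assert x.insert_seq == "A" * 22
    assert len(x.umi) == 18


def test_smallrna_one_locator_error_tolerated():
    # one fixed-position error in the 5' block stays accepted
    x = reformat_smallrna_read(fq("s1", smallrna_seq(block5="AAACGTCCCTACGGG")))
    assert x.accepted


@pytest.mark.parametrize(
    "kwargs,reason",
    [
        ({"block5": "AAACGTCCCTGCGGG"}, "bad_locator"),  # 2 errors, both 5' schemes fail
        ({"insert": "A" * 10}, "length_filter"),
        ({"insert": "A" * 40}, "length_filter"),
        ({"block5": "NAACGACCCTACGGG"}, "n_in_umi"),
    ],
)
def test_smallrna_rejections(kwargs, reason):
    x = reformat_smallrna_read(fq("s1", smallrna_seq(**kwargs)))
    assert x.status == reason


def test_smallrna_no_adapter_and_short():
    x = reformat_smallrna_read(fq("s1", "ACGT" * 20))
    assert x.status == "no_adapter"
    x = reformat_smallrna_read(fq("s1", "ACGTACGT" + ADAPTER))
    assert x.status == "short_read"


def test_smallrna_second_scheme_accepted():
    x = reformat_smallrna_read(fq("s1", smallrna_seq(block5="AAAATCCCCAGTGGG")))
    assert x.accepted
    assert x.umi.startswith("AAACCCGGG")


def test_smallrna_total_budget_switch():
    # one error in each block: fine per-block, fails a shared budget of 1
    seq = smallrna_seq(block5="AAACGTCCCTACGGG", block3="TTTGTGAAATAGCCC")
    assert reformat_smallrna_read(fq("s", seq)).accepted
    layout = SmallRnaLayout(mismatch_budget="total")
    assert reformat_smallrna_read(fq("s", seq), layout).status == "bad_locator"


def test_smallrna_reconstruction():
    """Accepted reads re-concatenate to the post-adapter-removal input."""
    seq = smallrna_seq()
    x = reformat_smallrna_read(fq("s1", seq))
    trimmed = seq[: seq.find(ADAPTER[:10])]
    assert trimmed[:15] + x.insert_seq + trimmed[-15:] == trimmed
    assert trimmed[15:-15] == x.insert_seq


@given(st.integers(0, 5), st.data())
@settings(max_examples=100, deadline=None)
def test_smallrna_locator_tolerance(which, data):
    """Flipping one non-N locator base never changes acceptance; two do."""
    base = smallrna_seq()
    scheme = SmallRnaLayout().five_prime_schemes[0]
    positions = scheme.fixed_positions
    p1 = positions[which]
    alt = data.draw(st.sampled_from([b for b in "ACGT" if b != base[p1]]))
    one_flip = base[:p1] + alt + base[p1 + 1 :]
    assert reformat_smallrna_read(fq("s", one_flip)).accepted

    p2 = data.draw(st.sampled_from([p for p in positions if p != p1]))
    alt2 = data.draw(st.sampled_from([b for b in "ACGT" if b != one_flip[p2]]))
    two_flips = one_flip[:p2] + alt2 + one_flip[p2 + 1 :]
    assert reformat_smallrna_read(fq("s", two_flips)).status == "bad_locator"


# ---------------------------------------------------------------------------
# read-name tagging


@pytest.mark.parametrize(
    "read_id,umi,expected",
    [
        ("SRR1.1", "AACGTTTGCA", "SRR1.1_AACGTTTGCA"),
        ("read7 1:N:0", "AAA", "read7_AAA 1:N:0"),
    ],
)
def test_tag_read_name(read_id, umi, expected):
    assert tag_read_name(read_id, umi) == expected


@given(
    st.from_regex(r"[A-Za-z0-9.:-]{1,20}", fullmatch=True),
    st.text(alphabet="ACGT", min_size=1, max_size=18),
)
@settings(max_examples=100, deadline=None)
def test_tag_parse_round_trip(read_id, umi):
    assert parse_umi_from_name(tag_read_name(read_id, umi)) == umi


def test_parse_umi_rejects_untagged():
    with pytest.raises(ValueError):
        parse_umi_from_name("plainname")


# ---------------------------------------------------------------------------
# file drivers and accounting


def write_fastq_file(path, records):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def test_rnaseq_file_driver_and_report(tmp_path):
    good1 = fq("p1", "AACGTGGGTCCCCACGT")
    good2 = fq("p1", "TTGCATCATAAAAGTCA")
    bad1 = fq("p2", "AACGTAAATCCCCACGT")  # bad locator
    write_fastq_file(tmp_path / "r1.fastq", [good1, bad1])
    write_fastq_file(tmp_path / "r2.fastq", [good2, fq("p2", good2.sequence)])
    report = reformat_fastq_files(
        str(tmp_path / "r1.fastq"), str(tmp_path / "r2.fastq"),
        str(tmp_path / "o1.fastq"), str(tmp_path / "o2.fastq"),
    )
    assert report.total == 2 and report.accepted == 1
    assert report.rejected["bad_locator"] == 1
    assert report.total == report.accepted + sum(report.rejected.values())
    out = list(read_fastq(str(tmp_path / "o1.fastq")))
    assert len(out) == 1
    assert out[0].name.split()[0].endswith("_AACGTTTGCA")


def test_gzipped_roundtrip(tmp_path):
    recs = [fq("s1", smallrna_seq()), fq("s2", "ACGT" * 30)]
    write_fastq_file(tmp_path / "in.fastq.gz", recs)
    report = reformat_smallrna_file(
        str(tmp_path / "in.fastq.gz"), str(tmp_path / "out.fastq.gz")
    )
    assert report.total == 2 and report.accepted == 1
    out = list(read_fastq(str(tmp_path / "out.fastq.gz")))
    assert len(out) == 1 and len(out[0].sequence) == 22


def test_unpaired_input_is_error(tmp_path):
    write_fastq_file(tmp_path / "r1.fastq", [fq("p1", "A" * 20), fq("p2", "A" * 20)])
    write_fastq_file(tmp_path / "r2.fastq", [fq("p1", "A" * 20)])
    with pytest.raises(ValueError, match="ended before"):
        reformat_fastq_files(
            str(tmp_path / "r1.fastq"), str(tmp_path / "r2.fastq"),
            str(tmp_path / "o1.fastq"), str(tmp_path / "o2.fastq"),
        )


def test_report_tsv_shape():
    rep = ExtractionReport()
    for s in ("accepted", "bad_locator", "accepted"):
        rep.add(s)
    text = rep.to_tsv()
    assert "total\t3" in text and "accepted\t2" in text and "rejected_bad_locator\t1" in text
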