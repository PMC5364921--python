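"""Read merging, demultiplexing, content filters and dereplication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mockrep import FilterRules, ReadPair, UniqueSequence
from mockrep.readqc import (
    content_filters,
    demultiplex,
    dereplicate,
    expected_errors,
    iupac_match,
    merge_pair,
    precluster,
    remove_singletons,
    reverse_complement,
    run_read_qc,
    stop_codon_screen,
)

RULES = FilterRules()


def _pair(fwd, rev, q=40):
    return ReadPair("r1", fwd, (q,) * len(fwd), rev, (q,) * len(rev))


def test_exact_overlap_merge_length():
    rng = np.random.default_rng(0)
    left = "".join(rng.choice(list("ACGT"), 30))
    overlap = "".join(rng.choice(list("ACGT"), 20))
    right = "".join(rng.choice(list("ACGT"), 30))
    fwd = left + overlap
    rev = reverse_complement(overlap + right)
    res = merge_pair(_pair(fwd, rev), RULES)
    assert res.ok
    assert res.merged == left + overlap + right
    assert len(res.merged) == len(fwd) + len(rev) - 20


def test_full_overlap_mate_merges_to_forward():
    fwd = "ACGTACGTACGTACGTACGTACGT"
    res = merge_pair(_pair(fwd, reverse_complement(fwd)), RULES)
    assert res.ok and res.merged == fwd


def test_mismatch_cap_enforced():
    rng = np.random.default_rng(1)
    overlap = "".join(rng.choice(list("ACGT"), 40))
    bad = list(overlap)
    for i in range(6):  # six substitutions in the overlap
        bad[3 * i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[3 * i]]
    fwd = "ACGTACGTAC" + overlap
    rev = reverse_complement("".join(bad) + "TTGGCCAATG")
    res = merge_pair(_pair(fwd, rev), RULES)
    assert not res.ok and res.reason == "merge_mismatches"
    assert merge_pair(_pair(fwd, rev), FilterRules(max_merge_mismatches=6)).ok


def test_merge_consensus_quality_rule():
    # disagreeing base: higher-quality call wins with quality |Qf-Qr|
    fwd = "A" * 16 + "C" * 4
    rev_seq = reverse_complement("A" * 16 + "G" * 4)
    pair = ReadPair("r", fwd, (30,) * 20, rev_seq, (10,) * 20)
    res = merge_pair(pair, RULES)
    assert res.ok and res.merged.endswith("C" * 4)
    assert set(res.qualities[-4:]) == {20}


@pytest.mark.parametrize(
    "quals, expected",
    [
        ((10,), 0.1),
        ((30,) * 313, 0.313),  # 313 x 10^-3
        ((), 0.0),
        ((93,) * 100, 100 * 10 ** -9.3),
    ],
)
def test_expected_errors_closed_form(quals, expected):
    assert expected_errors(quals) == pytest.approx(expected, rel=1e-12)


INDEX_MAP = {"s1": "AGACGC", "s2": "AGTGTA"}
FWD = "GGWACWGGWTGAACWGTWTAYCCYCC"
REV = "TAIACYTCIGGRTGICCRAARAAYCA"


def _amplicon(idx_f, idx_r, insert="ATG" * 40):
    fwd_concrete = FWD.replace("W", "A").replace("Y", "C")
    rev_concrete = REV.replace("I", "A").replace("Y", "C").replace("R", "A")
    return (idx_f + fwd_concrete + insert
            + reverse_complement(idx_r + rev_concrete))


def test_demultiplex_assigns_and_trims():
    insert = "ATG" * 40
    res = demultiplex(_amplicon("AGACGC", "AGACGC", insert), INDEX_MAP, FWD, REV, RULES)
    assert res.ok and res.sample_id == "s1" and res.trimmed == insert


def test_demultiplex_rejects_index_conflict():
    res = demultiplex(_amplicon("AGACGC", "AGTGTA"), INDEX_MAP, FWD, REV, RULES)
    assert res.reason == "index_conflict"


def test_demultiplex_rejects_primer_mismatch():
    read = _amplicon("AGACGC", "AGACGC")
    # substitute one base inside the forward primer region (position 6+3)
    mutated = read[:9] + ("C" if read[9] != "C" else "G") + read[10:]
    res = demultiplex(mutated, INDEX_MAP, FWD, REV, RULES)
    assert res.reason == "unknown_index"


def test_iupac_degeneracies_match_base_sets():
    assert iupac_match("W", "A") and iupac_match("W", "T") and not iupac_match("W", "C")
    assert iupac_match("I", "G")  # inosine matches everything
    assert not iupac_match("A", "G")


@pytest.mark.parametrize(
    "seq, reason",
    [
        ("ACGT" + "A" * 9 + "CGT", "homopolymer"),
        ("ACGT" + "A" * 8 + "CGT", None),  # boundary: run of 8 passes
        ("ACGTNACGT", "ambiguous_base"),
        ("ACGTACGT", None),
    ],
)
def test_content_filters(seq, reason):
    assert content_filters(seq, RULES) == reason


@pytest.mark.parametrize(
    "seq, frame, expected",
    [
        ("ATGATGATG", 0, None),
        ("ATGTAAATG", 0, "stop_codon"),  # TAA stops in table 5
        ("ATGAGAATG", 0, None),  # AGA codes serine in table 5, not a stop
        ("ATGTGAATG", 0, None),  # TGA codes tryptophan in table 5
        ("ATAGCC", 0, None),     # TAG present but out of frame 0 (ATA|GCC)
        ("AT", 0, "too_short"),
    ],
)
def test_stop_codon_screen_table5(seq, frame, expected):
    assert stop_codon_screen(seq, genetic_code=5, reading_frame=frame) == expected


def test_stop_codon_screen_flags_length_offsets():
    assert (
        stop_codon_screen("ATG" * 10 + "A", expected_length=30)
        == "possible_frameshift"
    )


def test_dereplicate_groups_and_orders():
    out = dereplicate(["AAA", "AAA", "CCC"], ids=["r1", "r2", "r3"])
    assert [(u.sequence, u.abundance) for u in out] == [("AAA", 2), ("CCC", 1)]
    assert out[0].member_ids == ("r1", "r2")
    assert dereplicate([]) == []


def test_precluster_absorbs_within_three_mismatches():
    u = [UniqueSequence("AAAAAAAAAA", 10), UniqueSequence("AAAAAAAATT", 2)]
    out = precluster(u)
    assert [(x.sequence, x.abundance) for x in out] == [("AAAAAAAAAA", 12)]


def test_precluster_beyond_threshold_unchanged():
    u = [UniqueSequence("AAAAAAAAAA", 10), UniqueSequence("TTTTTAAAAA", 9)]
    out = precluster(u)
    assert len(out) == 2 and sum(x.abundance for x in out) == 19


def test_precluster_chain_absorbs_into_most_abundant():
    # hand-trace: both rarer variants are within 3 of the top sequence
    u = [
        UniqueSequence("AAAAAAAAAA", 10),
        UniqueSequence("AAAAAAAAGG", 3),
        UniqueSequence("TTAAAAAAAA", 2),
    ]
    out = precluster(u)
    assert [(x.sequence, x.abundance) for x in out] == [("AAAAAAAAAA", 15)]


def test_precluster_never_merges_unequal_lengths():
    u = [UniqueSequence("AAAAAAAAAA", 5), UniqueSequence("AAAAAAAAA", 4)]
    assert len(precluster(u)) == 2


def test_remove_singletons():
    u = [UniqueSequence("A", 5), UniqueSequence("C", 1)]
    assert [x.sequence for x in remove_singletons(u)] == ["A"]
    assert remove_singletons([UniqueSequence("A", 1)]) == []
    assert remove_singletons(u[:1]) == u[:1]


@given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5), max_size=30))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_dereplicate_conserves_reads(seqs):
    out = dereplicate(seqs)
    assert sum(u.abundance for u in out) == len(seqs)
    assert len({u.sequence for u in out}) == len(out)


@given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=1, max_size=20))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_precluster_conserves_abundance_and_shrinks(seqs):
    uniques = dereplicate(seqs)
    out = precluster(uniques)
    assert sum(u.abundance for u in out) == len(seqs)
    assert len(out) <= len(uniques)


def test_qc_ledger_conserves_reads():
    good = _amplicon("AGACGC", "AGACGC")
    pairs = [
        _pair(good[:120], reverse_complement(good[-120:])),  # passes
        _pair(good[:120], reverse_complement(good[-120:])),  # duplicate, passes
        ReadPair("low_q", good[:120], (2,) * 120,
                 reverse_complement(good[-120:]), (2,) * 120),  # expected errors
    ]
    res = run_read_qc(pairs, INDEX_MAP, FWD, REV, drop_singletons=False)
    assert sum(res.ledger.values()) == len(pairs)
    assert res.ledger["expected_errors"] == 1
    assert res.ledger["passed"] == 2
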