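"""Unit and property tests for amplicon repair-junction calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoej import (
    align_fallback,
    apply_filters,
    call_junction,
    call_read,
    classify_deletion_bin,
    gen_reference_locus,
    longest_common_prefix,
    longest_common_suffix,
    revcomp,
    summarize_sample,
)
from mitoej.junctions import (
    DELETION,
    DELETION_WITH_INSERTION,
    JunctionCall,
    MISSING_BOTH,
    MISSING_FWD,
    MISSING_REV,
    PASS,
    PURE_INSERTION,
    SITE_RETAINED,
    UNCLASSIFIED,
    UNMODIFIED,
)

from .conftest import make_mini_locus
from .oracles import oracle_deletion, oracle_deletion_insertion

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


# ---------------------------------------------------------------------------
# prefix/suffix primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACCT", 2),
        ("ACGT", "ACGT", 4),
        ("", "ACGT", 0),
        ("ACGT", "", 0),
        ("TTT", "TTTT", 3),
    ],
)
def test_lcp_examples(a, b, expected):
    assert longest_common_prefix(a, b) == expected


def test_lcp_rejects_non_acgt_unless_n_tolerant():
    with pytest.raises(ValueError):
        longest_common_prefix("ACXT", "ACGT")
    with pytest.raises(ValueError):
        longest_common_prefix("ACNT", "ACNT")
    # N never matches, not even N itself
    assert longest_common_prefix("ACNT", "ACNT", n_tolerant=True) == 2


@given(dna, dna)
@settings(max_examples=100, derandomize=True)
def test_lcp_lcs_bounds(a, b):
    p = longest_common_prefix(a, b)
    s = longest_common_suffix(a, b)
    assert 0 <= p <= min(len(a), len(b))
    assert 0 <= s <= min(len(a), len(b))
    assert a[:p] == b[:p]
    assert (a[len(a) - s :] == b[len(b) - s :]) if s else True


# ---------------------------------------------------------------------------
# exact decomposition
# ---------------------------------------------------------------------------


def test_pure_deletion_with_microhomology():
    locus = make_mini_locus("ACGGTTACGGCA")
    call = call_junction(locus, "ACGGCA")
    assert call.event_class == DELETION
    assert (call.d, call.m) == (6, 4)
    assert call.mh_seq == locus.amplicon[call.p - call.m : call.p]
    # the ambiguity interval spans the m + 1 equivalent placements
    assert call.junction_interval[1] - call.junction_interval[0] == call.m + 1
    assert (call.d, call.m) == oracle_deletion(locus.amplicon, "ACGGCA")


def test_unmodified_read():
    locus = make_mini_locus("ACGGTTACGGCA")
    call = call_junction(locus, locus.amplicon)
    assert call.event_class == UNMODIFIED
    assert call.d == 0 and call.m == 0


def test_deletion_with_insertion():
    locus = make_mini_locus("AAAACCCCGGGG")
    call = call_junction(locus, "AAAATTGGGG")
    assert call.event_class == DELETION_WITH_INSERTION
    assert (call.d, call.i, call.insertion_seq, call.m) == (4, 2, "TT", 0)
    assert oracle_deletion_insertion(locus.amplicon, "AAAATTGGGG") == (4, 2)


def test_pure_insertion():
    locus = make_mini_locus("AAAACCCCGGGG")
    call = call_junction(locus, "AAAACCTTCCGGGG")
    assert call.event_class == PURE_INSERTION
    assert (call.d, call.i) == (0, 2)


def test_short_read_unclassified():
    locus = make_mini_locus("ACGGTTACGGCA", fwd_len=4, rev_len=4)
    assert call_junction(locus, "ACG").event_class == UNCLASSIFIED


def test_tandem_duplication_unclassified():
    # p + s exceeds both lengths: no single-junction decomposition
    locus = make_mini_locus("ACGTACGT")
    call = call_junction(locus, "ACGTACGTACGT")
    assert call.event_class == UNCLASSIFIED


def test_oracle_equivalence_exhaustive_deletions():
    """(d, m) equals brute-force enumeration for every single-segment
    deletion of seeded random amplicons up to 40 bp."""
    rng = np.random.default_rng(42)
    for _ in range(40):
        length = int(rng.integers(10, 41))
        amplicon = "".join(rng.choice(list("ACGT"), size=length))
        locus = make_mini_locus(amplicon)
        for d in range(1, length - 4):
            for start in range(0, length - d + 1):
                read = amplicon[:start] + amplicon[start + d :]
                if len(read) < 4 or read == amplicon:
                    continue
                call = call_junction(locus, read)
                assert call.event_class == DELETION
                assert (call.d, call.m) == oracle_deletion(amplicon, read), (
                    amplicon,
                    read,
                )


def test_deletion_reconstruction_property():
    """Removing amplicon[p : p + d) reproduces every pure-deletion read."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        amplicon = "".join(rng.choice(list("ACGT"), size=30))
        locus = make_mini_locus(amplicon)
        d = int(rng.integers(1, 12))
        start = int(rng.integers(0, 30 - d))
        read = amplicon[:start] + amplicon[start + d :]
        call = call_junction(locus, read)
        if call.event_class == DELETION:
            assert (
                amplicon[: call.p] + amplicon[call.p + call.d :] == read
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def test_unmodified_read_retains_site(locus):
    verdict, _ = apply_filters(locus, locus.amplicon)
    assert verdict == SITE_RETAINED


def test_missing_rev_primer(locus):
    verdict, _ = apply_filters(locus, locus.amplicon[:-30])
    assert verdict == MISSING_REV


def test_missing_fwd_primer(locus):
    verdict, _ = apply_filters(locus, locus.amplicon[30:])
    assert verdict == MISSING_FWD


def test_unrelated_read_missing_both(locus):
    verdict, _ = apply_filters(locus, "ACGT" * 30)
    assert verdict == MISSING_BOTH


def test_deletion_destroying_site_passes(locus):
    lo, hi = locus.recognition_site_span
    read = locus.amplicon[: lo - 5] + locus.amplicon[hi + 10 :]
    verdict, trimmed = apply_filters(locus, read)
    assert verdict == PASS
    assert locus.enzyme_recognition not in trimmed


def test_filter_monotone_site_restoration(locus):
    """Re-inserting the recognition sequence flips a passing read to
    site_retained."""
    lo, hi = locus.recognition_site_span
    read = locus.amplicon[: lo - 5] + locus.amplicon[hi + 10 :]
    assert apply_filters(locus, read).verdict == PASS
    restored = read[: lo - 5] + locus.enzyme_recognition + read[lo - 5 :]
    assert apply_filters(locus, restored).verdict == SITE_RETAINED


def test_orientation_recovered_from_reverse_strand(locus):
    lo, hi = locus.recognition_site_span
    read = locus.amplicon[: lo - 5] + locus.amplicon[hi + 10 :]
    fwd = apply_filters(locus, read)
    rev = apply_filters(locus, revcomp(read))
    assert fwd == rev


def test_ambiguous_orientation_raises(locus):
    chimera = locus.amplicon[:60] + revcomp(locus.amplicon[:60])
    with pytest.raises(ValueError, match="ambiguous"):
        apply_filters(locus, chimera, read_name="chimera1")


def test_coordinate_invariance_full_call(locus):
    """Calling the reverse-complemented read yields identical (d, i, m)."""
    lo, hi = locus.recognition_site_span
    read = locus.amplicon[: lo - 3] + locus.amplicon[hi + 17 :]
    a = call_read(locus, read)
    b = call_read(locus, revcomp(read))
    assert (a.d, a.i, a.m) == (b.d, b.i, b.m)
    assert a.event_class == b.event_class


# ---------------------------------------------------------------------------
# alignment fallback
# ---------------------------------------------------------------------------


def test_fallback_matches_exact_on_clean_deletion(locus):
    lo, hi = locus.recognition_site_span
    read = locus.amplicon[: lo - 2] + locus.amplicon[hi + 13 :]
    exact = call_junction(locus, read)
    fb = align_fallback(locus, read)
    assert exact.event_class == fb.event_class == DELETION
    assert (exact.d, exact.m, exact.p) == (fb.d, fb.m, fb.p)


def test_fallback_absorbs_prefix_substitution(locus):
    lo, hi = locus.recognition_site_span
    clean = locus.amplicon[: lo - 2] + locus.amplicon[hi + 13 :]
    truth = call_junction(locus, clean)
    pos = 40  # inside the prefix, away from primers and junction
    base = "A" if clean[pos] != "A" else "C"
    noisy = clean[:pos] + base + clean[pos + 1 :]
    call = align_fallback(locus, noisy)
    assert (call.d, call.m) == (truth.d, truth.m)


def test_fallback_two_separated_gaps_unclassified(locus):
    amp = locus.amplicon
    read = amp[:50] + amp[60:150] + amp[165:]
    assert align_fallback(locus, read).event_class == UNCLASSIFIED


# ---------------------------------------------------------------------------
# bins and summaries
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d,label", [(1, "<10"), (9, "<10"), (10, "10-60"), (60, "10-60"), (61, ">60")]
)
def test_deletion_bins(d, label):
    assert classify_deletion_bin(d) == label


def test_deletion_bin_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_deletion_bin(0)


def test_summarize_sample_mh_fraction():
    calls = [
        JunctionCall(DELETION, d=12, m=3) for _ in range(4)
    ] + [JunctionCall(DELETION, d=12, m=0) for _ in range(6)]
    summary = summarize_sample(calls, mh_min=2)
    assert summary.n_events == 10
    assert summary.fraction_mh == pytest.approx(0.4)
    assert summary.deletion_size_histogram["10-60"] == 10
    assert summary.median_deletion == 12


def test_summarize_all_excluded():
    calls = [
        JunctionCall(UNCLASSIFIED, filter_verdict=SITE_RETAINED)
        for _ in range(5)
    ]
    summary = summarize_sample(calls)
    assert summary.n_events == 0
    assert summary.n_excluded_by_filter[SITE_RETAINED] == 5


def test_summarize_empty():
    summary = summarize_sample([])
    assert summary.n_reads_in == 0
    assert summary.n_events == 0
    assert summary.fraction_mh == 0.0
    assert summary.median_deletion is None
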