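"""Repair-junction classification for CRISPR-cut amplicon products.

Mutagenic double-strand-break repair in mitosis is read out by PCR-amplifying
the region around a Cas9 cut, cloning single products and Sanger sequencing
them.  Each read is decomposed against the reference amplicon into an event
class (unmodified / deletion / deletion with insertion / pure insertion),
a deletion length ``d``, an insertion length ``i`` and a junction
microhomology length ``m``.  Microhomology -- a short identical sequence on
both flanks of the deleted segment -- makes the exact deletion placement
ambiguous; the caller reports the ambiguity interval and canonicalises to
the leftmost placement.

Exclusion filters mirror the experimental design: reads missing one or both
PCR primers, or still containing the restriction-enzyme recognition sequence
(an intact, i.e. unrepaired-looking, site), are excluded before event
calling.

Coordinates are 0-based, half-open throughout; the cut position is a
between-base index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# basic sequence utilities
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGT")

#: deletion-size bin labels used in per-sample summaries
BIN_SMALL = "<10"
BIN_MID = "10-60"
BIN_LARGE = ">60"
DELETION_BINS = (BIN_SMALL, BIN_MID, BIN_LARGE)

#: filter verdicts
PASS = "pass"
MISSING_FWD = "missing_fwd_primer"
MISSING_REV = "missing_rev_primer"
MISSING_BOTH = "missing_both_primers"
SITE_RETAINED = "site_retained"
FILTER_VERDICTS = (PASS, MISSING_FWD, MISSING_REV, MISSING_BOTH, SITE_RETAINED)

#: event classes
UNMODIFIED = "unmodified"
DELETION = "deletion"
DELETION_WITH_INSERTION = "deletion_with_insertion"
PURE_INSERTION = "pure_insertion"
UNCLASSIFIED = "unclassified"


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, n_tolerant: bool = False, what: str = "sequence") -> None:
    allowed = VALID_BASES | ({"N"} if n_tolerant else frozenset())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT characters {sorted(bad)!r}"
            + ("" if n_tolerant else " (enable n_tolerant to accept N)")
        )


def longest_common_prefix(a: str, b: str, n_tolerant: bool = False) -> int:
    """Length of the longest common prefix of two DNA strings.

    With ``n_tolerant`` the ambiguity code N is accepted but never matches
    anything (including another N).
    """
    _check_dna(a, n_tolerant, "first sequence")
    _check_dna(b, n_tolerant, "second sequence")
    k = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        k += 1
    return k


def longest_common_suffix(a: str, b: str, n_tolerant: bool = False) -> int:
    """Length of the longest common suffix of two DNA strings."""
    return longest_common_prefix(a[::-1], b[::-1], n_tolerant=n_tolerant)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceLocus:
    """Amplicon reference frame for junction calling.

    ``amplicon`` is the sequenced strand; ``fwd_primer`` must be its prefix
    and ``rev_primer`` (as ordered for PCR) the reverse complement of its
    suffix.  ``cut_position`` is a 0-based between-base index.
    ``recognition_site_span`` locates the restriction-enzyme recognition
    sequence used to select mutagenic repair products, on the amplicon
    strand as written.
    """

    name: str
    amplicon: str
    cut_position: int
    fwd_primer: str
    rev_primer: str
    enzyme_recognition: str = "GGTGA"
    recognition_site_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for attr in ("amplicon", "fwd_primer", "rev_primer", "enzyme_recognition"):
            object.__setattr__(self, attr, getattr(self, attr).upper())
        _check_dna(self.amplicon, what="amplicon")
        if not self.amplicon.startswith(self.fwd_primer):
            raise ValueError("fwd_primer is not a prefix of the amplicon")
        if not self.amplicon.endswith(revcomp(self.rev_primer)):
            raise ValueError(
                "reverse complement of rev_primer is not a suffix of the amplicon"
            )
        if not 0 < self.cut_position < len(self.amplicon):
            raise ValueError("cut_position must lie strictly inside the amplicon")
        if self.recognition_site_span is not None:
            lo, hi = self.recognition_site_span
            if self.amplicon[lo:hi] != self.enzyme_recognition:
                raise ValueError(
                    "amplicon does not carry the enzyme recognition sequence at "
                    f"recognition_site_span [{lo}, {hi})"
                )

    @property
    def rev_primer_site(self) -> str:
        """The rev-primer binding site on the amplicon strand (its suffix)."""
        return revcomp(self.rev_primer)


@dataclass(frozen=True)
class JunctionCall:
    """Decomposition of one repair product against the reference amplicon.

    For pure deletions ``junction_interval`` is the half-open range of
    equivalent deletion start positions (width ``m + 1``); the canonical,
    leftmost deleted segment is ``amplicon[p : p + d)`` where ``p`` is the
    longest-common-prefix length after microhomology trimming.
    """

    event_class: str
    p: int = 0
    s: int = 0
    d: int = 0
    i: int = 0
    insertion_seq: str = ""
    m: int = 0
    mh_seq: str = ""
    junction_interval: Optional[tuple[int, int]] = None
    filter_verdict: str = PASS


class FilterResult(NamedTuple):
    verdict: str
    read: str  # oriented (and, when both primers were found, trimmed) read


@dataclass
class SampleSummary:
    """Per-sample event summary: exclusions, deletion-size bins, MH usage."""

    n_reads_in: int
    n_excluded_by_filter: dict[str, int]
    n_events: int
    deletion_size_histogram: dict[str, int]
    fraction_mh: float
    median_deletion: Optional[float]
    n_unmodified: int = 0
    n_unclassified: int = 0


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _find_approx(haystack: str, needle: str, max_mismatches: int) -> Optional[int]:
    """Leftmost position of ``needle`` in ``haystack`` allowing up to
    ``max_mismatches`` substitutions (no indels).  None if absent."""
    if max_mismatches == 0:
        pos = haystack.find(needle)
        return pos if pos >= 0 else None
    n = len(needle)
    best: Optional[tuple[int, int]] = None  # (mismatches, pos)
    for pos in range(len(haystack) - n + 1):
        mm = 0
        window = haystack[pos : pos + n]
        for x, y in zip(window, needle):
            if x != y:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            if best is None or mm < best[0]:
                best = (mm, pos)
                if mm == 0:
                    break
    return None if best is None else best[1]


def apply_filters(
    locus: ReferenceLocus,
    read: str,
    max_primer_mismatches: int = 0,
    read_name: str = "",
) -> FilterResult:
    """Orient a Sanger read and apply the exclusion filters.

    The read may come from either sequencing primer, so both strands are
    searched for the forward primer (and, failing that, for the rev-primer
    binding site).  Verdicts:

    * ``missing_fwd_primer`` / ``missing_rev_primer`` / ``missing_both_primers``
      -- a primer was not found within the mismatch budget;
    * ``site_retained`` -- the enzyme recognition sequence survives in the
      read (the product would have been digested away experimentally);
    * ``pass`` otherwise.

    The returned read is oriented to the amplicon strand and trimmed to the
    primer-to-primer interval (primers retained, preserving the amplicon
    coordinate frame).
    """
    read = read.upper()
    fwd = locus.fwd_primer
    tail = locus.rev_primer_site
    rc = revcomp(read)

    fwd_f = _find_approx(read, fwd, max_primer_mismatches)
    tail_f = _find_approx(read, tail, max_primer_mismatches)
    fwd_r = _find_approx(rc, fwd, max_primer_mismatches)
    tail_r = _find_approx(rc, tail, max_primer_mismatches)

    forward_evidence = fwd_f is not None or tail_f is not None
    reverse_evidence = fwd_r is not None or tail_r is not None
    if forward_evidence and reverse_evidence:
        raise ValueError(
            f"ambiguous orientation for read {read_name or '<unnamed>'}: "
            "primer sequences match both strands"
        )
    if not forward_evidence and not reverse_evidence:
        return FilterResult(MISSING_BOTH, read)

    if reverse_evidence:
        read = rc
        fwd_f, tail_f = fwd_r, tail_r

    if fwd_f is None:
        trimmed = read[: tail_f + len(tail)] if tail_f is not None else read
        return FilterResult(MISSING_FWD, trimmed)
    if tail_f is None or tail_f + len(tail) <= fwd_f + len(fwd):
        return FilterResult(MISSING_REV, read[fwd_f:])
    trimmed = read[fwd_f : tail_f + len(tail)]
    if locus.enzyme_recognition in trimmed:
        return FilterResult(SITE_RETAINED, trimmed)
    return FilterResult(PASS, trimmed)


# ---------------------------------------------------------------------------
# exact junction decomposition
# ---------------------------------------------------------------------------


def call_junction(
    locus: ReferenceLocus,
    read: str,
    n_tolerant: bool = False,
    filter_verdict: str = PASS,
) -> JunctionCall:
    """Decompose a primer-anchored read into a junction call.

    With ``p`` / ``s`` the longest common prefix / suffix lengths between
    amplicon (length ``R``) and read (length ``S``):

    * ``read == amplicon`` -> unmodified;
    * ``S < R`` and ``p + s >= S`` -> pure deletion with ``d = R - S`` and
      microhomology ``m = min(p + s - S, d)``; the equivalent deletion start
      positions form the half-open interval ``[p - m, p + 1)``;
    * ``p + s < S`` and ``p + s <= R`` -> deletion with insertion
      (``d = R - p - s``, ``i = S - p - s``); ``d == 0`` is a pure insertion;
    * anything else (e.g. rearranged or duplicated products) -> unclassified.
    """
    amp = locus.amplicon
    read = read.upper()
    R, S = len(amp), len(read)
    if S < len(locus.fwd_primer) + len(locus.rev_primer):
        logger.warning(
            "read shorter than the combined primer lengths (%d < %d); unclassified",
            S,
            len(locus.fwd_primer) + len(locus.rev_primer),
        )
        return JunctionCall(UNCLASSIFIED, filter_verdict=filter_verdict)

    p = longest_common_prefix(amp, read, n_tolerant)
    s = longest_common_suffix(amp, read, n_tolerant)

    if read == amp:
        return JunctionCall(
            UNMODIFIED, p=p, s=s, filter_verdict=filter_verdict
        )
    if S < R and p + s >= S:
        d = R - S
        m = min(p + s - S, d)
        start = max(p - m, 0)
        return JunctionCall(
            DELETION,
            p=p,
            s=s,
            d=d,
            m=m,
            mh_seq=amp[p - m : p],
            junction_interval=(start, p + 1),
            filter_verdict=filter_verdict,
        )
    if p + s < S and p + s <= R:
        d = R - p - s
        i = S - p - s
        cls = PURE_INSERTION if d == 0 else DELETION_WITH_INSERTION
        return JunctionCall(
            cls,
            p=p,
            s=s,
            d=d,
            i=i,
            insertion_seq=read[p : S - s],
            junction_interval=(p, p + 1),
            filter_verdict=filter_verdict,
        )
    # p + s exceeds both R and S: no single-junction decomposition exists
    return JunctionCall(UNCLASSIFIED, p=p, s=s, filter_verdict=filter_verdict)


# ---------------------------------------------------------------------------
# alignment fallback for reads with base-call errors
# ---------------------------------------------------------------------------


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_fallback(
    locus: ReferenceLocus,
    read: str,
    match: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    filter_verdict: str = PASS,
) -> JunctionCall:
    """Junction call via global alignment, tolerant of isolated mismatches.

    Sanger base-call errors break the exact prefix/suffix decomposition, so
    the read is globally aligned to the amplicon and an error-free surrogate
    read is reconstructed from the alignment (aligned segments replaced by
    the corresponding amplicon sequence; inserted segments kept verbatim).
    The surrogate is then decomposed exactly, so microhomology is computed
    on the exact flanking sequences with the same leftmost convention.
    Biopython's dynamic-programming aligner enumerates co-optimal alignments
    in a fixed order; taking the first gives leftmost gap placement.

    Products with more than one gap of >= 3 bases are reported unclassified
    (complex products).
    """
    amp = locus.amplicon
    read = read.upper()
    if len(read) < len(locus.fwd_primer) + len(locus.rev_primer):
        return JunctionCall(UNCLASSIFIED, filter_verdict=filter_verdict)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(amp, read)[0]
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return JunctionCall(UNCLASSIFIED, filter_verdict=filter_verdict)

    # Gap events in alignment order: the two ends plus every inter-block
    # junction, each with the aligned-block length separating it from the
    # next event.  A deletion and an insertion at one repair junction can be
    # rendered by the aligner as two gap events split by a few co-optimally
    # aligned bases, so events separated by < 8 aligned bases are merged
    # into one compound junction before the complexity rule is applied.
    events = [(t_blocks[0][0], q_blocks[0][0])]  # leading end-gaps
    separations = []
    for k in range(len(t_blocks) - 1):
        separations.append(t_blocks[k][1] - t_blocks[k][0])
        events.append(
            (
                t_blocks[k + 1][0] - t_blocks[k][1],
                q_blocks[k + 1][0] - q_blocks[k][1],
            )
        )
    separations.append(t_blocks[-1][1] - t_blocks[-1][0])
    events.append((len(amp) - t_blocks[-1][1], len(read) - q_blocks[-1][1]))

    merged = [events[0]]
    for sep, event in zip(separations, events[1:]):
        prev = merged[-1]
        if max(prev) > 0 and max(event) > 0 and sep < 8:
            merged[-1] = (prev[0] + event[0], prev[1] + event[1])
        else:
            merged.append(event)
    big_gaps = sum(1 for t_gap, q_gap in merged if max(t_gap, q_gap) >= 3)
    if big_gaps > 1:
        return JunctionCall(UNCLASSIFIED, filter_verdict=filter_verdict)

    parts = []
    if q_blocks[0][0] > 0:  # unaligned read prefix = leading insertion
        parts.append(read[: q_blocks[0][0]])
    for k in range(len(t_blocks)):
        t0, t1 = t_blocks[k]
        parts.append(amp[t0:t1])
        if k + 1 < len(t_blocks):
            parts.append(read[q_blocks[k][1] : q_blocks[k + 1][0]])
    if q_blocks[-1][1] < len(read):
        parts.append(read[q_blocks[-1][1] :])
    surrogate = "".join(parts)
    return call_junction(locus, surrogate, filter_verdict=filter_verdict)


# ---------------------------------------------------------------------------
# binning and summaries
# ---------------------------------------------------------------------------


def classify_deletion_bin(d: int) -> str:
    """Deletion-size bin: ``<10`` / ``10-60`` / ``>60`` bp."""
    if d <= 0:
        raise ValueError(f"deletion size must be >= 1, got {d}")
    if d < 10:
        return BIN_SMALL
    if d <= 60:
        return BIN_MID
    return BIN_LARGE


def summarize_sample(calls: Sequence[JunctionCall], mh_min: int = 2) -> SampleSummary:
    """Aggregate junction calls for one sample.

    Events are passing, classified, non-unmodified calls.  The deletion-size
    histogram and the microhomology-use fraction (``m >= mh_min``) are
    computed over pure deletions, where junction microhomology is defined.
    """
    excluded: dict[str, int] = {v: 0 for v in FILTER_VERDICTS if v != PASS}
    hist = {b: 0 for b in DELETION_BINS}
    dels: list[int] = []
    n_mh = 0
    n_events = 0
    n_unmod = 0
    n_unclass = 0
    for call in calls:
        if call.filter_verdict != PASS:
            excluded[call.filter_verdict] += 1
            continue
        if call.event_class == UNMODIFIED:
            n_unmod += 1
            continue
        if call.event_class == UNCLASSIFIED:
            n_unclass += 1
            continue
        n_events += 1
        if call.event_class == DELETION:
            hist[classify_deletion_bin(call.d)] += 1
            dels.append(call.d)
            if call.m >= mh_min:
                n_mh += 1
    fraction_mh = n_mh / len(dels) if dels else 0.0
    return SampleSummary(
        n_reads_in=len(calls),
        n_excluded_by_filter=excluded,
        n_events=n_events,
        deletion_size_histogram=hist,
        fraction_mh=fraction_mh,
        median_deletion=float(np.median(dels)) if dels else None,
        n_unmodified=n_unmod,
        n_unclassified=n_unclass,
    )


# ---------------------------------------------------------------------------
# per-sample pipeline
# ---------------------------------------------------------------------------


def call_read(
    locus: ReferenceLocus,
    read: str,
    max_primer_mismatches: int = 0,
    use_fallback: bool = True,
    read_name: str = "",
) -> JunctionCall:
    """Filter, orient and decompose a single read.

    The exact decomposition is attempted first; the alignment fallback is
    invoked when the exact call is unclassified or implies an insertion
    (isolated substitutions masquerade as short deletion-with-insertion
    events under the exact rule)."""
    verdict, oriented = apply_filters(
        locus, read, max_primer_mismatches=max_primer_mismatches, read_name=read_name
    )
    if verdict != PASS:
        return JunctionCall(UNCLASSIFIED, filter_verdict=verdict)
    call = call_junction(locus, oriented, filter_verdict=verdict)
    if use_fallback and (call.event_class == UNCLASSIFIED or call.i > 0):
        call = align_fallback(locus, oriented, filter_verdict=verdict)
    return call


def analyze_sample(
    locus: ReferenceLocus,
    reads: Sequence[tuple[str, str]],
    mh_min: int = 2,
    max_primer_mismatches: int = 0,
    use_fallback: bool = True,
) -> tuple[pd.DataFrame, SampleSummary]:
    """Call every read of a sample and summarise.

    Returns a per-read table (one row per input read, deterministic column
    order) and the :class:`SampleSummary`.
    """
    rows = []
    calls = []
    for name, seq in reads:
        call = call_read(
            locus,
            seq,
            max_primer_mismatches=max_primer_mismatches,
            use_fallback=use_fallback,
            read_name=name,
        )
        calls.append(call)
        rows.append(
            {
                "read_id": name,
                "filter_verdict": call.filter_verdict,
                "event_class": call.event_class,
                "deletion_length": call.d,
                "insertion_length": call.i,
                "insertion_seq": call.insertion_seq,
                "mh_length": call.m,
                "mh_seq": call.mh_seq,
                "junction_start": call.junction_interval[0]
                if call.junction_interval
                else "",
                "junction_end": call.junction_interval[1]
                if call.junction_interval
                else "",
            }
        )
    columns = [
        "read_id",
        "filter_verdict",
        "event_class",
        "deletion_length",
        "insertion_length",
        "insertion_seq",
        "mh_length",
        "mh_seq",
        "junction_start",
        "junction_end",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table, summarize_sample(calls, mh_min=mh_min)
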