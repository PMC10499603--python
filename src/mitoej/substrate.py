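"""Extrachromosomal end-joining substrate model and ΔΔCt repair efficiency.

The repair substrate mimics a resected double-strand break: a
double-stranded core (a GFP PCR product cut with BsaI to expose 4-nt
ligation overhangs) is flanked on both sides by oligonucleotide duplexes
whose long strands carry ~70-nt 3' single-stranded overhangs.  Inside
cells, two such duplex1--core--duplex2 fragments can anneal head-to-tail
through a short microhomology near the overhang 3' ends (a 4-mer in the
published design), and flap trimming plus fill-in synthesis creates a
covalent end-joining junction.  Junction abundance is quantified by qPCR
across the junction, normalised to a qPCR on the core (transfection
control), and expressed as a relative efficiency via ΔΔCt.

The printed oligo and primer sequences of the published substrate are
provided as module constants so the model can be validated against the
designed geometry (17/69 nt and 15/71 nt duplex segmentation, GCAG
annealing microhomology with 2-nt terminal flaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .junctions import revcomp

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# published substrate sequences (Methods of the source study)
# ---------------------------------------------------------------------------

OLIGO_1A = "CATCGCTTAGCTGTATA"
OLIGO_1B = (
    "TGACTATACAGCTAAGCGATGCTCTCACCGAGCGTATCTGCTGGG"
    "TTGTGGATGAATTACATATGCTGGGAGAACCAAGATTGGGCAGTT"
)
OLIGO_2A = "CTCACACCCATCTCA"
OLIGO_2B = (
    "AGTCTGAGATGGGTGTGAGAGTGAAGATCCTCACCTTCGGAGTACTCC"
    "TTCTTTTGACCATTGATACGATACTTCTCAGCCGAGCTGCTT"
)

#: qPCR primers across the end-joining junction
PRIMER_EJ_FWD = "GGGTTGTGGATGAATTACATATGCTGG"
PRIMER_EJ_REV = "CGGAGTACTCCTTCTTTTGACCATTGATAC"
#: qPCR primers on the core (transfection normaliser)
PRIMER_CORE_FWD = "CTCACACCCATCTCAGACTGTGAGCAA"
PRIMER_GFP_REV = "CAGCTTGCCGTAGGTGGCATCG"

# BsaI-digested core ends, derived from the printed core PCR primers:
# the top strand of the cut core starts with its 4-nt 5' overhang (GACT)
# and ends recessed, 4 nt short of the bottom strand's GTCA overhang.
CORE_TOP_PREFIX = "GACTGTGAGCAAGGGCGAGGAGCTG"
CORE_TOP_SUFFIX = revcomp("GCTTGTACAGCTCGTCCATGCCGAG")


# ---------------------------------------------------------------------------
# duplex segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OligoDuplex:
    """Annealed oligo pair: ligation overhang + double-stranded core + 3' ss tail.

    ``oligo_long`` is segmented as ``[ligation overhang][ds region][ss tail]``
    where the ds region is the reverse complement of ``oligo_short``.
    """

    oligo_short: str
    oligo_long: str
    ligation_overhang_len: int
    ds_len: int
    ss_len: int
    ss_seq: str

    @property
    def ligation_overhang(self) -> str:
        return self.oligo_long[: self.ligation_overhang_len]


def anneal_duplex(
    oligo_short: str, oligo_long: str, ligation_overhang_len: int = 4
) -> OligoDuplex:
    """Segment a long/short oligo pair into overhang, ds region and ss tail.

    The reverse complement of the short oligo must occur exactly once in the
    long oligo, immediately after the ligation overhang.
    """
    oligo_short = oligo_short.upper()
    oligo_long = oligo_long.upper()
    ds = revcomp(oligo_short)
    n_hits = oligo_long.count(ds)
    if n_hits == 0:
        raise ValueError(
            "short oligo does not anneal: its reverse complement is absent "
            "from the long oligo"
        )
    if n_hits > 1:
        raise ValueError(
            f"ambiguous annealing: reverse complement of the short oligo "
            f"occurs {n_hits} times in the long oligo"
        )
    offset = oligo_long.find(ds)
    if offset != ligation_overhang_len:
        raise ValueError(
            f"ds region found at offset {offset}, expected it immediately "
            f"after the {ligation_overhang_len}-nt ligation overhang"
        )
    ds_len = len(oligo_short)
    ss_seq = oligo_long[ligation_overhang_len + ds_len :]
    return OligoDuplex(
        oligo_short=oligo_short,
        oligo_long=oligo_long,
        ligation_overhang_len=ligation_overhang_len,
        ds_len=ds_len,
        ss_len=len(ss_seq),
        ss_seq=ss_seq,
    )


# ---------------------------------------------------------------------------
# annealing microhomology search
# ---------------------------------------------------------------------------


class AnnealingResult(NamedTuple):
    """Microhomology annealing solution between two 3' overhangs.

    ``mh_seq`` is the k-mer as read on the left overhang; the right overhang
    carries its reverse complement.  Flaps are the unannealed 3'-terminal
    bases left on each overhang."""

    mh_len: int
    mh_seq: str
    flap_left: Optional[int]
    flap_right: Optional[int]

    @property
    def annealed(self) -> bool:
        return self.mh_len > 0


NO_ANNEALING = AnnealingResult(0, "", None, None)


def find_annealing_microhomology(
    ss_left: str, ss_right: str, window: int = 10, k_min: int = 3
) -> AnnealingResult:
    """Find the maximal annealing microhomology between two 3' overhangs.

    Searches the 3'-terminal ``window`` of each overhang for a k-mer on the
    left whose reverse complement occurs on the right, for the largest
    ``k >= k_min``.  Ties are broken by the smallest combined flap length
    (bases 3' of the k-mer on each side), then by leftmost position.
    Returns an explicit no-annealing result when nothing pairs.
    """
    ss_left = ss_left.upper()
    ss_right = ss_right.upper()
    wl = ss_left[-window:] if window < len(ss_left) else ss_left
    wr = ss_right[-window:] if window < len(ss_right) else ss_right
    off_l = len(ss_left) - len(wl)
    off_r = len(ss_right) - len(wr)
    k_max = min(len(wl), len(wr))
    for k in range(k_max, k_min - 1, -1):
        candidates = []
        for i in range(len(wl) - k + 1):
            kmer = wl[i : i + k]
            target = revcomp(kmer)
            for j in range(len(wr) - k + 1):
                if wr[j : j + k] == target:
                    flap_l = len(ss_left) - (off_l + i + k)
                    flap_r = len(ss_right) - (off_r + j + k)
                    candidates.append((flap_l + flap_r, i, j, kmer, flap_l, flap_r))
        if candidates:
            _, _, _, kmer, flap_l, flap_r = min(candidates)
            return AnnealingResult(k, kmer, flap_l, flap_r)
    return NO_ANNEALING


# ---------------------------------------------------------------------------
# substrate assembly and predicted end-joining product
# ---------------------------------------------------------------------------


class NoAnnealingError(ValueError):
    """The two overhangs share no annealing microhomology."""


@dataclass(frozen=True)
class EJSubstrate:
    """Assembled duplex1--core--duplex2 repair substrate.

    ``left_duplex`` (duplex 1) contributes the overhang forming the left
    flank of the end-joining junction; ``right_duplex`` (duplex 2) the right
    flank, which carries the reverse complement of ``mh_seq``.
    ``core_insert`` is the top strand of the BsaI-cut core, written 5'->3'
    starting with its 4-nt ligation overhang.
    """

    core_insert: str
    left_duplex: OligoDuplex
    right_duplex: OligoDuplex
    mh_len: int
    mh_seq: str
    flap_left: Optional[int] = None
    flap_right: Optional[int] = None

    @property
    def annealed(self) -> bool:
        return self.mh_len > 0


def build_substrate(
    core_insert: str,
    left_duplex: OligoDuplex,
    right_duplex: OligoDuplex,
    window: int = 10,
    k_min: int = 3,
) -> EJSubstrate:
    """Assemble a substrate and locate its annealing microhomology."""
    ann = find_annealing_microhomology(
        left_duplex.ss_seq, right_duplex.ss_seq, window=window, k_min=k_min
    )
    return EJSubstrate(
        core_insert=core_insert.upper(),
        left_duplex=left_duplex,
        right_duplex=right_duplex,
        mh_len=ann.mh_len,
        mh_seq=ann.mh_seq,
        flap_left=ann.flap_left,
        flap_right=ann.flap_right,
    )


def fragment_top(substrate: EJSubstrate) -> str:
    """Top strand of a single ligated duplex1--core--duplex2 fragment.

    Reading 5'->3': short oligo of duplex 2, the core top strand, then the
    full long oligo of duplex 1 whose ss tail forms the fragment's 3'
    overhang.  (Duplex 2's long-oligo tail is the bottom-strand 3' overhang
    at the other end.)
    """
    return (
        substrate.right_duplex.oligo_short
        + substrate.core_insert
        + substrate.left_duplex.oligo_long
    )


def amplifiable(template_top: str, fwd_primer: str, rev_primer: str) -> bool:
    """True if the primer pair amplifies the double-stranded template.

    Requires one primer to match the top strand and the other primer's
    reverse complement to occur downstream of it (either assignment of the
    two primers to the two strands is accepted).
    """
    template_top = template_top.upper()
    for a, b in ((fwd_primer, rev_primer), (rev_primer, fwd_primer)):
        i = template_top.find(a.upper())
        j = template_top.find(revcomp(b.upper()))
        if i >= 0 and j >= 0 and i <= j:
            return True
    return False


def predict_ej_product(
    substrate: EJSubstrate, junction_primers: tuple[str, str]
) -> tuple[str, bool]:
    """Predict the head-to-tail end-joining product and validate primers.

    Two fragments anneal through the overhang microhomology; the 3' flaps
    are trimmed and the gaps filled by copying each overhang template,
    yielding a double-stranded junction.  The returned string is the product
    top strand; the flag is True iff the junction qPCR primers amplify it in
    opposite-strand orientation.
    """
    if not substrate.annealed:
        raise NoAnnealingError(
            "overhangs share no annealing microhomology; no end-joining "
            "product can form"
        )
    frag = fragment_top(substrate)
    ss_right = substrate.right_duplex.ss_seq
    fl, fr = substrate.flap_left, substrate.flap_right
    # fragment A trimmed of its 3' flap (top strand now ends in the MH),
    # fill-in copies the partner overhang up to fragment B's ds region,
    # then fragment B's own top strand continues seamlessly.
    filled = revcomp(ss_right[: len(ss_right) - fr - substrate.mh_len])
    product = frag[: len(frag) - fl] + filled + frag
    fwd, rev = junction_primers
    return product, amplifiable(product, fwd, rev)


def synthetic_core_insert(interior_len: int = 680, seed: int = 0) -> str:
    """Synthetic stand-in for the BsaI-cut GFP core top strand.

    The published core is a 747-bp GFP PCR product whose interior sequence
    (beyond the printed primers) is not part of the model; this builder
    keeps the exact printed BsaI-cut ends and plants the printed GFP qPCR
    reverse-primer site in seeded random filler, so primer-validity checks
    behave like the real core.
    """
    rng = np.random.default_rng(seed)
    site = revcomp(PRIMER_GFP_REV)
    if interior_len < len(site):
        raise ValueError("interior too short to carry the GFP qPCR primer site")
    guard = [PRIMER_EJ_FWD, PRIMER_EJ_REV, PRIMER_CORE_FWD, PRIMER_GFP_REV]
    for _ in range(100):
        filler = "".join(rng.choice(list("ACGT"), size=interior_len - len(site)))
        half = (interior_len - len(site)) // 2
        interior = filler[:half] + site + filler[half:]
        core = CORE_TOP_PREFIX + interior + CORE_TOP_SUFFIX
        if all(p not in core and revcomp(p) not in core for p in guard[:2]) and (
            core.count(site) == 1
        ):
            return core
    raise RuntimeError("could not build a clean synthetic core insert")


def printed_substrate(interior_len: int = 680, seed: int = 0) -> EJSubstrate:
    """The published substrate: printed oligos around a synthetic core."""
    d1 = anneal_duplex(OLIGO_1A, OLIGO_1B)
    d2 = anneal_duplex(OLIGO_2A, OLIGO_2B)
    return build_substrate(synthetic_core_insert(interior_len, seed), d1, d2)


# ---------------------------------------------------------------------------
# ΔΔCt repair efficiency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrRecord:
    """One sample's paired Ct values: junction qPCR and core (GFP) qPCR."""

    sample: str
    condition: str
    ct_target: float
    ct_norm: float


def ddct_efficiency(
    records: Union[pd.DataFrame, Sequence[QpcrRecord]],
    reference_condition: str,
    amplification_efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative end-joining efficiency from paired Ct values via ΔΔCt.

    Per sample, ΔCt = ct_target - ct_norm; ΔΔCt = ΔCt - mean ΔCt of the
    reference condition; efficiency = E^(-ΔΔCt) with E the per-cycle
    amplification factor (2 = perfect doubling).  The reference condition
    therefore averages to efficiency 1 on the log scale.  Samples missing a
    Ct value are dropped with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    required = {"sample", "condition", "ct_target", "ct_norm"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"qPCR table lacks columns {sorted(missing_cols)}")
    bad = df["ct_target"].isna() | df["ct_norm"].isna()
    if bad.any():
        logger.warning(
            "dropping %d sample(s) with missing Ct values: %s",
            int(bad.sum()),
            ", ".join(df.loc[bad, "sample"].astype(str)),
        )
        df = df[~bad].copy()
    if not ((df["ct_target"] > 0) & (df["ct_norm"] > 0)).all():
        raise ValueError("Ct values must be finite and > 0")
    if reference_condition not in set(df["condition"]):
        raise ValueError(
            f"reference condition {reference_condition!r} absent from the table"
        )
    df["dct"] = df["ct_target"] - df["ct_norm"]
    ref_mean = df.loc[df["condition"] == reference_condition, "dct"].mean()
    df["ddct"] = df["dct"] - ref_mean
    df["efficiency"] = amplification_efficiency ** (-df["ddct"])
    return df.reset_index(drop=True)
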