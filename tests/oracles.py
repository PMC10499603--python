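"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive exhaustive enumeration and share no code with
the package's decomposition or search routines.
"""

from __future__ import annotations

from typing import Optional

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_deletion(amplicon: str, read: str) -> Optional[tuple[int, int]]:
    """(d, m) of a pure-deletion read by trying every deletion placement.

    Enumerates all start positions whose deletion reproduces the read; the
    junction microhomology is the number of equivalent placements minus one,
    capped at the deletion length.  Returns None if the read is not a pure
    deletion of the amplicon.
    """
    d = len(amplicon) - len(read)
    if d <= 0:
        return None
    starts = [
        s
        for s in range(len(read) + 1)
        if amplicon[:s] + amplicon[s + d :] == read
    ]
    if not starts:
        return None
    return d, min(len(starts) - 1, d)


def oracle_deletion_insertion(
    amplicon: str, read: str, max_i: int = 30
) -> Optional[tuple[int, int]]:
    """Minimal (d, i) over all prefix+insertion+suffix decompositions.

    Enumerates every (start, deletion length, insertion length) triple with
    ``read == amplicon[:start] + ins + amplicon[start+d:]`` and returns the
    decomposition minimising the inserted length (equivalently the deleted
    length, as d - i is fixed by the read length).
    """
    R, S = len(amplicon), len(read)
    best = None
    for i in range(0, max_i + 1):
        d = R - S + i
        if d < 0:
            continue
        for start in range(0, min(R - d, S - i) + 1):
            if amplicon[:start] + read[start : start + i] + amplicon[start + d :] == read:
                best = (d, i)
                break
        if best is not None:
            break
    return best


def oracle_annealing(
    ss_left: str, ss_right: str, window: int = 10, k_min: int = 3
) -> Optional[tuple[int, str, int, int]]:
    """Maximal annealing k-mer by enumerating every (i, j, k) triple.

    Returns (k, kmer, flap_left, flap_right) with ties broken by smallest
    combined flap then leftmost, or None when nothing pairs.
    """
    wl = ss_left[-window:]
    wr = ss_right[-window:]
    best = None
    for k in range(min(len(wl), len(wr)), k_min - 1, -1):
        hits = []
        for i in range(len(wl) - k + 1):
            for j in range(len(wr) - k + 1):
                if wr[j : j + k] == _rc(wl[i : i + k]):
                    fl = len(wl) - (i + k)
                    fr = len(wr) - (j + k)
                    hits.append((fl + fr, i, j, wl[i : i + k], fl, fr))
        if hits:
            _, _, _, kmer, fl, fr = min(hits)
            return k, kmer, fl, fr
    return None
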