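"""Seeded synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its seed and returns both the data
and a truth table, so each pipeline stage can be tested by parameter
recovery without any external download:

* :func:`gen_reference_locus` -- a random amplicon with unique primers and a
  single restriction recognition site spanning the cut;
* :func:`simulate_repair_reads` -- Sanger-like repair products drawn from a
  genotype profile (deletion-size mixture, junction microhomologies,
  unmodified contaminants, primer truncations, substitution noise);
* :func:`simulate_plate` -- a 384-well siRNA screen with additive row and
  column positional effects and planted hit genes;
* :func:`simulate_qpcr` -- paired Ct values encoding programmed relative
  end-joining efficiencies;
* :func:`simulate_bli` -- one-site binding isotherms with Gaussian noise.

Repair-read truth labels record the *generating* junction (event class,
deletion length, insertion length, microhomology), derived from direct
flank comparison on the amplicon -- never from the junction caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import BindingSeries, one_site
from .junctions import ReferenceLocus, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# event-class names used in repair profiles and truth tables
EV_UNMODIFIED = "unmodified"
EV_SMALL_DEL = "small_del"
EV_MMEJ_DEL = "mmej_del"
EV_LARGE_DEL = "large_del"
EV_INSERTION = "junction_insertion"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# repair profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepairProfile:
    """Genotype-specific mixture over repair-event classes.

    The wild-type profile is dominated by microhomology-mediated deletions
    in the 10-60 bp range; the Polθ-null profile lacks that class entirely
    (its hallmark deletions are absent) and shows only chance-level junction
    microhomology.  Substitution noise emulates Sanger base-call errors and
    is kept away from the junction so the generated truth stays exact.
    """

    name: str
    weights: dict[str, float]
    mh_length_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.2, 3: 0.3, 4: 0.3, 5: 0.15, 6: 0.05}
    )
    small_del_range: tuple[int, int] = (1, 9)
    mmej_del_range: tuple[int, int] = (10, 60)
    large_del_range: tuple[int, int] = (61, 90)
    insertion_len_range: tuple[int, int] = (1, 8)
    insertion_del_range: tuple[int, int] = (0, 6)
    substitution_rate: float = 0.002
    primer_truncation_fraction: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("mixture weights must lie in [0, 1]")
        if not np.isclose(sum(self.mh_length_probs.values()), 1.0):
            raise ValueError("MH-length probabilities must sum to 1")


def wt_profile(**overrides) -> RepairProfile:
    """Wild-type repair spectrum: MMEJ deletions with microhomology dominate."""
    prof = RepairProfile(
        name="wt",
        weights={
            EV_UNMODIFIED: 0.10,
            EV_SMALL_DEL: 0.25,
            EV_MMEJ_DEL: 0.45,
            EV_LARGE_DEL: 0.10,
            EV_INSERTION: 0.10,
        },
    )
    return replace(prof, **overrides) if overrides else prof


def polq_ko_profile(**overrides) -> RepairProfile:
    """Polθ-null spectrum: no 10-60 bp MMEJ deletions, chance-level MH only."""
    prof = RepairProfile(
        name="polq_ko",
        weights={
            EV_UNMODIFIED: 0.15,
            EV_SMALL_DEL: 0.50,
            EV_MMEJ_DEL: 0.0,
            EV_LARGE_DEL: 0.20,
            EV_INSERTION: 0.15,
        },
    )
    return replace(prof, **overrides) if overrides else prof


# ---------------------------------------------------------------------------
# reference locus
# ---------------------------------------------------------------------------


def gen_reference_locus(
    length: int = 400,
    cut_fraction: float = 0.5,
    seed: int = 0,
    primer_len: int = 20,
    enzyme_recognition: str = "GGTGA",
    max_tries: int = 500,
) -> ReferenceLocus:
    """Random amplicon satisfying all reference-locus constraints.

    The enzyme recognition sequence is planted exactly once, spanning the
    cut position (so any cut-straddling repair event destroys it); the
    terminal ``primer_len``-mers serve as primers and are required to be
    unique on both strands (so read orientation is unambiguous).
    """
    if length < 200:
        raise ValueError("amplicon length must be >= 200")
    rng = np.random.default_rng(seed)
    cut = int(round(length * cut_fraction))
    site = enzyme_recognition.upper()
    site_start = cut - len(site) // 2
    for _ in range(max_tries):
        amp = list(_random_dna(rng, length))
        amp[site_start : site_start + len(site)] = site
        amplicon = "".join(amp)
        fwd = amplicon[:primer_len]
        tail = amplicon[-primer_len:]
        rc_amp = revcomp(amplicon)
        if amplicon.count(site) != 1:
            continue
        if amplicon.count(fwd) != 1 or fwd in rc_amp:
            continue
        if amplicon.count(tail) != 1 or tail in rc_amp:
            continue
        return ReferenceLocus(
            name=f"synthetic_locus_L{length}_seed{seed}",
            amplicon=amplicon,
            cut_position=cut,
            fwd_primer=fwd,
            rev_primer=revcomp(tail),
            enzyme_recognition=site,
            recognition_site_span=(site_start, site_start + len(site)),
        )
    raise RuntimeError(
        f"could not satisfy locus constraints after {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# repair reads
# ---------------------------------------------------------------------------


def _flank_homology(amp: str, a: int, b: int) -> int:
    """Junction microhomology of deleting ``amp[a:b)``, by flank comparison.

    Counts how far the junction can slide left plus how far it can slide
    right while reproducing the same product; capped at the deletion length.
    Independent of the caller's prefix/suffix decomposition.
    """
    d = b - a
    left = 0
    while a - left - 1 >= 0 and amp[a - left - 1] == amp[b - left - 1]:
        left += 1
    right = 0
    while b + right < len(amp) and amp[a + right] == amp[b + right]:
        right += 1
    return min(left + right, d)


def _deletion_catalog(
    locus: ReferenceLocus, d_min: int, d_max: int
) -> list[tuple[int, int, int]]:
    """All (start, d, mh) cut-straddling deletions keeping both primers intact
    and leaving no recognition site in the product."""
    amp = locus.amplicon
    cut = locus.cut_position
    site = locus.enzyme_recognition
    lo = len(locus.fwd_primer)
    hi = len(amp) - len(locus.rev_primer)
    out = []
    for d in range(d_min, d_max + 1):
        for a in range(max(lo, cut - d), min(cut, hi - d) + 1):
            b = a + d
            read = amp[:a] + amp[b:]
            if site in read:
                continue
            out.append((a, d, _flank_homology(amp, a, b)))
    return out


def _gap_cost(length: int, gap_open: float = -8.0, gap_extend: float = -1.0) -> float:
    return 0.0 if length <= 0 else gap_open + gap_extend * (length - 1)


def _insertion_identifiable(amp: str, read: str, d: int, i: int) -> bool:
    """True if the generating del+ins interpretation is the optimal alignment.

    An insertion whose sequence chance-resembles the deleted segment can be
    explained more parsimoniously as a shorter event plus substitutions; such
    a read does not carry its intended truth and must not be emitted.  The
    check compares the generating interpretation's alignment score (all
    non-inserted bases match; one deletion gap, one insertion gap) with the
    optimal global alignment score under the standard scoring
    (match +1 / mismatch -4 / gap open -8 / extend -1).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    truth_score = (len(read) - i) * 1.0 + _gap_cost(d) + _gap_cost(i)
    return aligner.score(amp, read) <= truth_score + 1e-9


def _apply_noise(
    rng: np.random.Generator,
    read: str,
    rate: float,
    protect: set[int],
    forbidden: str,
    max_tries: int = 20,
) -> tuple[str, int]:
    """Per-base substitutions outside protected positions; redraws if the
    noise spells out the forbidden (recognition) sequence."""
    if rate <= 0:
        return read, 0
    n = len(read)
    for _ in range(max_tries):
        hits = np.flatnonzero(rng.random(n) < rate)
        hits = [h for h in hits if h not in protect]
        if not hits:
            return read, 0
        chars = list(read)
        for h in hits:
            alternatives = [b for b in "ACGT" if b != chars[h]]
            chars[h] = alternatives[rng.integers(3)]
        noisy = "".join(chars)
        if forbidden not in noisy:
            return noisy, len(hits)
    logger.warning("noise kept recreating the recognition site; emitting clean read")
    return read, 0


def simulate_repair_reads(
    locus: ReferenceLocus,
    profile: RepairProfile,
    n: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate Sanger repair products with an exact truth table.

    The amplicon is fixed, so junction microhomology cannot be written into
    it per read; instead all cut-straddling deletions are catalogued with
    their actual flanking homology and MMEJ events sample a junction whose
    homology equals the MH length drawn from the profile's categorical
    distribution (renormalised over the lengths the amplicon offers).
    Deletions that would exceed the primer-protected interval are resampled
    and counted (``resampled`` attribute on the truth table).

    Substitution noise is applied after the truth is fixed and is confined
    outside the junction +/- 10 bp, the primer regions and the recognition
    -site span; reads are emitted in random orientation.  Truncated reads
    lose part of one primer.

    Returns ``(reads, truth)`` where reads are (id, sequence) pairs and the
    truth table records the generating event per read.
    """
    rng = np.random.default_rng(seed)
    amp = locus.amplicon
    fwd_len = len(locus.fwd_primer)
    rev_len = len(locus.rev_primer)

    catalogs = {
        EV_SMALL_DEL: _deletion_catalog(locus, *profile.small_del_range),
        EV_MMEJ_DEL: _deletion_catalog(locus, *profile.mmej_del_range),
        EV_LARGE_DEL: _deletion_catalog(locus, *profile.large_del_range),
        EV_INSERTION: _deletion_catalog(locus, *profile.insertion_del_range),
    }
    mmej_by_m: dict[int, list[tuple[int, int, int]]] = {}
    for entry in catalogs[EV_MMEJ_DEL]:
        mmej_by_m.setdefault(entry[2], []).append(entry)

    classes = list(profile.weights)
    class_p = np.array([profile.weights[c] for c in classes])
    n_resampled = 0

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for idx in range(n):
        cls = classes[rng.choice(len(classes), p=class_p)]
        a = d = i = m = 0
        ins = ""
        if cls == EV_UNMODIFIED:
            read = amp
        elif cls in (EV_SMALL_DEL, EV_LARGE_DEL):
            cat = catalogs[cls]
            if not cat:
                raise RuntimeError(f"no feasible deletions for class {cls}")
            a, d, m = cat[rng.integers(len(cat))]
            read = amp[:a] + amp[a + d :]
        elif cls == EV_MMEJ_DEL:
            wanted = list(profile.mh_length_probs)
            probs = np.array([profile.mh_length_probs[k] for k in wanted])
            target = wanted[rng.choice(len(wanted), p=probs)]
            if not mmej_by_m.get(target):
                # the amplicon offers no junction of that homology; redraw
                # among the lengths it does offer (renormalised)
                n_resampled += 1
                avail = [k for k in wanted if mmej_by_m.get(k)]
                if not avail:
                    raise RuntimeError(
                        "amplicon offers no junction with the requested MH lengths"
                    )
                sub = np.array([profile.mh_length_probs[k] for k in avail])
                target = avail[rng.choice(len(avail), p=sub / sub.sum())]
            bucket = mmej_by_m[target]
            a, d, m = bucket[rng.integers(len(bucket))]
            read = amp[:a] + amp[a + d :]
        else:  # junction insertion
            cat = catalogs[EV_INSERTION]
            cut = locus.cut_position
            candidate = None
            for _ in range(50):
                # d = 0 entries are absent from the deletion catalog (they
                # retain the recognition site on their own); synthesise them
                if rng.random() < 0.4 or not cat:
                    a, d = cut, 0
                else:
                    a, d, _ = cat[rng.integers(len(cat))]
                b = a + d
                i = int(rng.integers(profile.insertion_len_range[0],
                                     profile.insertion_len_range[1] + 1))
                ins = _random_dna(rng, i)
                # the insertion ends must mismatch the amplicon flanks so the
                # generating decomposition stays the unique maximal one, and
                # the whole event must be the optimal-alignment interpretation
                if ins[0] == amp[a] or ins[-1] == amp[b - 1]:
                    continue
                trial = amp[:a] + ins + amp[b:]
                if locus.enzyme_recognition in trial:
                    continue
                if not _insertion_identifiable(amp, trial, d, i):
                    continue
                candidate = trial
                break
            if candidate is None:
                n_resampled += 1
                a, d, i = cut, 0, 1
                ins = next(
                    x for x in "ACGT" if x != amp[cut] and x != amp[cut - 1]
                )
                candidate = amp[:a] + ins + amp[a:]
            m = 0
            read = candidate

        expected_verdict = "site_retained" if cls == EV_UNMODIFIED else "pass"
        truncated = False
        n_subs = 0
        if cls != EV_UNMODIFIED:
            junction_lo = max(a - 10, 0)
            junction_hi = min(a + i + 10, len(read))
            protect = set(range(junction_lo, junction_hi))
            protect |= set(range(fwd_len))
            protect |= set(range(len(read) - rev_len, len(read)))
            read, n_subs = _apply_noise(
                rng, read, profile.substitution_rate, protect,
                locus.enzyme_recognition,
            )
        if rng.random() < profile.primer_truncation_fraction:
            truncated = True
            if rng.random() < 0.5:
                cut_len = int(rng.integers(1, fwd_len + 1))
                read = read[cut_len:]
                expected_verdict = "missing_fwd_primer"
            else:
                cut_len = int(rng.integers(1, rev_len + 1))
                read = read[: len(read) - cut_len]
                expected_verdict = "missing_rev_primer"
        flipped = bool(rng.random() < 0.5)
        if flipped:
            read = revcomp(read)
        read_id = f"read{idx:05d}"
        reads.append((read_id, read))
        truth_rows.append(
            {
                "read_id": read_id,
                "event_class": cls,
                "junction_start": a,
                "d": d,
                "i": i,
                "m": m,
                "insertion_seq": ins,
                "expected_verdict": expected_verdict,
                "truncated": truncated,
                "n_substitutions": n_subs,
                "revcomp": flipped,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["resampled"] = n_resampled
    if n_resampled:
        logger.info("%d events resampled against amplicon constraints", n_resampled)
    return reads, truth


# ---------------------------------------------------------------------------
# screen plates
# ---------------------------------------------------------------------------

PLATE_ROWS = 16
PLATE_COLS = 24
#: columns reserved for the in-plate reference population (reagent-only)
REFERENCE_COLS = (0, 23)


def simulate_plate(
    genes: int = 582,
    sirnas_per_gene: int = 3,
    hit_fraction: float = 0.01,
    effect_rz: float = 4.0,
    row_effect_sd: float = 6.0,
    col_effect_sd: float = 6.0,
    replicates: int = 3,
    seed: int = 0,
    baseline: float = 30.0,
    well_sd: float = 5.0,
    hit_direction: int = -1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a 384-well-format siRNA screen with planted hits.

    Library siRNAs are plated identically across replicates on as many
    384-well plates as needed, two columns per plate reserved for the
    reference population.  Every well receives additive row and column
    effects (drawn per plate instance) plus Gaussian well noise; planted
    hit genes shift *all* their siRNAs by ``effect_rz`` reference-scale
    units (``effect_rz * well_sd`` raw percentage points, signed by
    ``hit_direction``).  Values are clipped to the [0, 100] percentage
    scale.

    Returns ``(wells, truth)``: the well table (plate, row, col, replicate,
    gene, sirna, role, value) and the planted-hit table (gene, direction).
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sirnas = genes * sirnas_per_gene
    gene_names = [f"GENE{g + 1:04d}" for g in range(genes)]
    sirna_records = [
        (gene_names[g], f"{gene_names[g]}_s{s + 1}")
        for g in range(genes)
        for s in range(sirnas_per_gene)
    ]
    sample_cols = [c for c in range(PLATE_COLS) if c not in REFERENCE_COLS]
    wells_per_plate = PLATE_ROWS * len(sample_cols)
    n_plates = int(np.ceil(n_sirnas / wells_per_plate))

    n_hits = int(round(genes * hit_fraction))
    hit_idx = rng.choice(genes, size=n_hits, replace=False)
    hit_genes = {gene_names[g] for g in hit_idx}
    effect = {
        gene_names[g]: hit_direction * effect_rz * well_sd for g in hit_idx
    }

    rows = []
    for rep in range(1, replicates + 1):
        pos = 0
        for p in range(n_plates):
            plate_id = f"P{p + 1:02d}"
            row_eff = rng.normal(0.0, row_effect_sd, size=PLATE_ROWS)
            col_eff = rng.normal(0.0, col_effect_sd, size=PLATE_COLS)
            for r in range(PLATE_ROWS):
                for c in range(PLATE_COLS):
                    base = baseline + row_eff[r] + col_eff[c] + rng.normal(
                        0.0, well_sd
                    )
                    if c in REFERENCE_COLS:
                        rows.append(
                            (plate_id, r, c, rep, "", "", "reference",
                             float(np.clip(base, 0, 100)))
                        )
                        continue
                    if pos >= n_sirnas:
                        continue  # trailing empty wells on the last plate
                    gene, sirna = sirna_records[pos]
                    pos += 1
                    value = base + effect.get(gene, 0.0)
                    rows.append(
                        (plate_id, r, c, rep, gene, sirna, "sample",
                         float(np.clip(value, 0, 100)))
                    )
    wells = pd.DataFrame(
        rows,
        columns=["plate", "row", "col", "replicate", "gene", "sirna", "role",
                 "value"],
    )
    truth = pd.DataFrame(
        {
            "gene": sorted(hit_genes),
            "direction": [hit_direction] * len(hit_genes),
        }
    )
    return wells, truth


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_efficiencies: dict[str, float],
    ct_norm_mean: float = 20.0,
    sd: float = 0.1,
    n: int = 6,
    seed: int = 0,
    reference_condition: Optional[str] = None,
    dct_reference: float = 8.0,
) -> pd.DataFrame:
    """Paired Ct values encoding programmed relative efficiencies.

    Each sample's junction Ct is ``ct_norm + ΔCt_ref - log2(efficiency)``
    plus Gaussian noise, so condition ``c`` recovers efficiency
    ``true_efficiencies[c] / true_efficiencies[reference]`` under ΔΔCt.
    By default the first condition is the reference and should carry
    efficiency 1.
    """
    if sd < 0:
        raise ValueError("Ct noise sd must be non-negative")
    if any(e <= 0 for e in true_efficiencies.values()):
        raise ValueError("efficiencies must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, eff in true_efficiencies.items():
        for k in range(n):
            ct_norm = rng.normal(ct_norm_mean, sd)
            ct_target = (
                ct_norm + dct_reference - np.log2(eff) + rng.normal(0.0, sd)
            )
            rows.append(
                {
                    "sample": f"{cond}_{k + 1}",
                    "condition": cond,
                    "ct_target": float(ct_target),
                    "ct_norm": float(ct_norm),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binding isotherms
# ---------------------------------------------------------------------------


def simulate_bli(
    kd: float,
    rmax: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> BindingSeries:
    """One-site equilibrium responses with additive Gaussian noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    c = np.asarray(concentrations, dtype=float)
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    resp = one_site(c, kd, rmax)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=c.size)
    return BindingSeries(label=label or f"kd{kd:g}", concentrations_nM=c,
                         responses=resp)
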