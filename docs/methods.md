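# Methods

This note documents the models and procedures implemented in `mitoej`, the
assumptions behind them, the tunable parameters and their defaults, what
the synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Junction decomposition

**Model.** A repair product is assumed to derive from the reference
amplicon by a single junction event: a deleted segment, an inserted
segment, or both at one position. Coordinates are 0-based and half-open
everywhere; the cut position is a between-base index.

For amplicon length *R*, read length *S*, longest common prefix *p* and
suffix *s*:

* `read == amplicon` → unmodified (not a repair event; these correspond to
  uncut or precisely re-ligated molecules that the experimental
  HphI-digestion step removes physically, and the site-retention filter
  removes in silico);
* *S* < *R* and *p* + *s* ≥ *S* → pure deletion, *d* = *R* − *S*,
  microhomology *m* = min(*p* + *s* − *S*, *d*);
* *p* + *s* < *S* and *p* + *s* ≤ *R* → deletion-with-insertion
  (*d* = *R* − *p* − *s*, *i* = *S* − *p* − *s*; *d* = 0 is a pure
  insertion);
* anything else (tandem duplications, rearrangements) → unclassified.

**Microhomology definition.** *m* is the maximal exact homology between
the two deletion flanks, equivalently the number of alternative deletion
placements beyond the canonical one. It is capped at *d* (a deletion
inside a homopolymer run longer than itself cannot exhibit more
microhomology than deleted bases). The ambiguity interval of deletion
start positions, of width *m* + 1, is reported; the placement with the
microhomology assigned to the left flank is canonical. Microhomology is
reported only for pure deletions (*m* = 0 whenever *i* > 0): once an
insertion intervenes, flanking homology no longer reflects an
annealing-mediated junction, and templated-insertion analysis is out of
scope. An exhaustive oracle (every deletion placement enumerated) verifies
the closed-form (*d*, *m*) in the test suite and in the acceptance script.

**Filters.** Reads are oriented by searching both strands for the forward
primer (falling back to the reverse-primer binding site), then required to
contain both primers within a configurable Hamming budget
(`max_primer_mismatches`, default 0 — strict, matching the experimental
exclusion rule; raise it for noisy Sanger ends). Site retention is a
direct substring search for the recognition sequence (default `GGTGA`,
HphI) in the oriented read: any product still containing the site would
have been digested, wherever the site sits, so substring presence is the
biologically exact criterion. Cut-offset geometry (HphI cuts N8/N7
downstream) is deliberately not modelled. Orientation matching on both
strands is an error, not a verdict — it indicates a chimeric read.

**Alignment fallback.** Sanger base-call errors break the exact
prefix/suffix decomposition (a single substitution upstream of a deletion
masquerades as a deletion-with-insertion). Reads whose exact call is
unclassified or implies an insertion are therefore re-analysed by global
alignment (Biopython `PairwiseAligner`; match +1, mismatch −4, gap open
−8, gap extend −1; the first co-optimal alignment gives leftmost gap
placement). An error-free surrogate read is reconstructed from the
alignment — aligned segments replaced by amplicon sequence, inserted
segments kept — and decomposed exactly, so microhomology is always
computed on exact flanking sequence with the same convention. Two
remarks:

* the aligner may render one compound deletion+insertion junction as two
  gap events separated by a few co-optimally aligned bases; gap events
  separated by fewer than 8 aligned bases are merged into one compound
  junction before complexity is judged;
* after merging, more than one gap of ≥ 3 bases means a complex product
  (separated deletions, rearrangements) and the read is unclassified
  rather than forced into the single-junction model.

**Summaries.** Deletion sizes are binned `<10`, `10-60`, `>60` bp — the
middle bin is the Polθ signature. The microhomology-use fraction counts
pure deletions with *m* ≥ `mh_min` (default 2: 1-bp junction homology
occurs by chance in ¼ of random junctions and is not evidence of
microhomology-mediated joining; the threshold is configurable because the
annotation convention in the literature varies).

## End-joining substrate model

The substrate mimics two resected DSB ends: a double-stranded core
(a GFP PCR product cut by BsaI, exposing 4-nt 5′ overhangs) ligated
between two oligo duplexes whose long strands are segmented as
`[4-nt ligation overhang][ds region = revcomp(short oligo)][3′ ss tail]`.
Segment lengths are recovered by locating the short oligo's reverse
complement in the long oligo (required unique and immediately after the
ligation overhang). The published oligos give 17/69 nt (duplex 1) and
15/71 nt (duplex 2).

Annealing between the two 3′ overhangs is searched within a 3′-terminal
window (default 10 nt) for the largest k-mer (k ≥ `k_min`, default 3) on
one overhang whose reverse complement occurs on the other; ties prefer the
smallest combined 3′-flap length, then leftmost position. The published
design yields the 4-nt `GCAG`/`CTGC` pair with 2-nt terminal flaps. The
search is positional only — no thermodynamic (ΔG/melting) model — which is
adequate for detecting a designed microhomology, not for predicting
annealing kinetics.

The predicted end-joining product joins two fragments head-to-tail: the
fragment top strand is trimmed of its 3′ flap, extended by fill-in along
the partner overhang, and continues into the second fragment's top strand.
Primer validity requires one primer to match the product strand and the
other's reverse complement to occur downstream. The GFP-core interior
beyond the printed primers is not public; `synthetic_core_insert` is an
explicitly synthetic stand-in that keeps the exact printed BsaI-cut ends
and plants the printed core-qPCR primer sites in seeded random filler, so
all primer checks behave like the real core.

**ΔΔCt.** Per sample, ΔCt = Ct(junction) − Ct(core); ΔΔCt subtracts the
mean ΔCt of the user-named reference condition; efficiency =
E^(−ΔΔCt) with amplification factor E = 2 (perfect doubling) by default.
The reference condition is a required input because the matched control
(asynchronous vs untreated mitotic) is an experimental choice, not a
property of the data. Efficiency is invariant to any constant shift of a
sample's two Ct values.

## Screen scoring

**Median polish.** Each plate of each replicate is polished separately
(row and column medians iteratively swept out, NaN-aware, mirroring the
classical algorithm; `max_iter` 10, tolerance 1e-6 on the change in the
sum of absolute residuals). Corrected values are residuals plus the
overall effect. At the fixed point, column medians of residuals are
exactly zero (last sweep) and row medians small but generally nonzero —
an inherent property of median polish, shared with the reference R
implementation against which one test cross-checks numerically.

**Robust Z-scores.** Per plate, RZ = (x − median(ref)) / (c·MAD(ref)) over
the corrected values, where the reference population is the in-plate
transfection-reagent-only wells (≥ 8 required). The MAD scaling constant
defaults to 1.4826, the standard normal-consistency value; any other
value (e.g. the 1.14826 variant that appears in some screen
descriptions) is accepted via `mad_constant`, so either convention is
reproducible. A zero reference MAD raises an error directing the user to
a fallback scale — never a silent division.

**Hit calling.** A siRNA supports a direction when RZ > threshold
(positive) or RZ < −threshold (negative) in ≥ `min_replicates`
replicates; a gene is a hit when ≥ `min_sirnas` siRNAs support the same
direction (defaults 2/2/2 with threshold 2). Genes with a single siRNA
are flagged underpowered and never called. The rule is deliberately a
fixed threshold, not an FDR procedure. Gene-level summary score: median
across siRNAs of each siRNA's median RZ across replicates.

## Binding fits

The one-site isotherm R(C) = Rmax·C/(Kd + C) is fitted by unweighted
least squares on log-parameters (Levenberg–Marquardt; positivity by
construction; tolerances 1e-12). Initial guesses: Kd at the geometric
mid-point of the concentration range, Rmax at the maximum response. A fit
requires ≥ 5 concentrations spanning ≥ one order of magnitude; responses
decreasing beyond a 5%-of-maximum noise floor draw a warning without
aborting. Standard errors come from the Gauss–Newton covariance on the
log scale, delta-method-transformed; fold changes propagate the two
relative variances to first order assuming independent fits. Kinetic
(kon/koff) fitting, drift and reference-channel subtraction are out of
scope: the model addresses equilibrium plateaus only.

## Synthetic data

Every generator is a pure function of its seed (bit-identical reruns) and
returns truth labels fixed *before* noise is applied.

**Locus.** A random amplicon (default 400 bp) with unique 20-bp terminal
primers (both strands checked, so orientation is unambiguous) and the
recognition sequence planted exactly once, spanning the cut position —
hence any cut-straddling event destroys it, as in the real assay design
where the gRNA was chosen so that mutagenic repair kills the nearby site.

**Repair reads.** The amplicon is fixed across reads, so junction
microhomology cannot be written into it per read. Instead the generator
catalogues every cut-straddling deletion that keeps both primers intact
and leaves no recognition site, computing each junction's actual flanking
homology by direct flank comparison (independent of the caller's
prefix/suffix arithmetic). MMEJ events draw an MH length from a
categorical distribution (defaults {2: 0.2, 3: 0.3, 4: 0.3, 5: 0.15,
6: 0.05} — ranges are constrained by the biology, the distribution itself
is an illustrative choice) and sample uniformly among catalogued junctions
with exactly that homology (redrawing among available lengths when the
amplicon offers none; redraws are counted on the truth table). Deletion
sizes: MMEJ uniform on [10, 60]; small-deletion class [1, 9]; large
[61, 90]. Insertion events (1–8 random bases over a 0–6 bp deletion) are
constrained to be *identifiable*: their ends must mismatch the amplicon
flanks and the generating interpretation must be the optimal global
alignment of the read (checked with the aligner directly) — an insertion
that chance-resembles the deleted segment is more parsimoniously read as
substitutions and cannot carry its intended truth, so it is redrawn.

Sanger-like substitution noise (default 0.2%/base) is applied after the
truth is fixed, confined outside the junction ±10 bp (so truth
microhomology is preserved), outside the primers (so the strict primer
filter reflects true truncations only) and never recreating the
recognition sequence. Primer truncations (default 5% of reads) chop into
one primer; reads are emitted in random orientation. What this generator
does *not* emulate: chromatogram-level error structure (quality decay
along the read, peak mixing), multi-junction rearrangements,
templated insertions, and PCR chimeras — so passing tests demonstrate
correct decomposition and filtering logic, not robustness to every
artefact of real Sanger data.

**Plates.** The 1,746-siRNA library (582 genes × 3, the screen's design)
is plated identically across replicates on 384-well plates, two columns
per plate reserved for the reference population. Wells receive
baseline 30% ± 5% (well noise) plus additive row and column effects drawn
per plate instance. The positional-effect scale defaults to sd 6
raw percentage points per axis (≈ 1.2× well noise): positional artefacts
of this magnitude are exactly what positional correction exists for, and
at this scale scoring without the polish demonstrably loses planted hits
while polished scoring recovers them — the designed contrast the
end-to-end tests assert. Planted hit genes shift all their siRNAs by
`effect_rz` reference-scale units (default 4, inhibitory direction, like
a positive-control siRNA suppressing foci). Values are clipped to
[0, 100]. Not emulated: cell-count/viability covariation, batch drift
between replicates, non-additive (e.g. corner-specific) artefacts. The
default `hit_fraction` is 0.01; recovery tests plant 20 hits so that
recall has useful granularity. Because hits occupy consecutive wells,
configurations where hits dominate a plate row (small screens with high
hit fractions on sparsely filled plates) break the row-median's
robustness — a real limitation of median polish, which assumes effects
are sparse per row/column.

**qPCR / BLI.** Ct tables encode programmed relative efficiencies as
ct_target = ct_norm + ΔCt_ref − log2(efficiency) + N(0, sd), defaults
ΔCt_ref = 8 cycles, sd = 0.1; isotherms add N(0, sd) response noise to
the closed form over a two-fold dilution series.

## Problem sizes

Defaults were chosen so the full validation runs comfortably on a laptop:
junction-caller validation enumerates all deletions of 200 amplicons
(≈ 70,000 cases), read-set recovery uses 500 reads per genotype on a
400-bp locus, screen recovery uses the full 582 × 3 × 3 design, and
binding recovery uses 6–7-point dilution series matching the published
concentration ranges.

## Known limitations

* Single-junction model: multi-cut products, translocations and large
  templated insertions are reported unclassified, not resolved.
* Substring-based site retention assumes the recognition sequence is
  unique to the cut region (guaranteed for generated loci; real loci with
  a second site would need span-aware checking).
* Median polish per plate, not joint across plates of a replicate;
  replicate-level batch effects are not removed.
* The ΔΔCt model assumes equal amplification efficiency for both
  amplicons; no standard-curve calibration.
* Steady-state-only binding model; avidity and depletion effects are not
  represented.
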