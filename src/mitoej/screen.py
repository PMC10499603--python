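"""Plate-based siRNA screen scoring: median polish, robust Z-scores, hit calls.

High-content screens read out a per-well phenotype (here the percentage of
cells with at least a threshold number of Polθ foci).  Raw plate values
carry additive positional artefacts (row/column gradients from dispensing,
evaporation, imaging), which are removed by Tukey's two-way median polish.
Corrected values are then scored against an in-plate reference population
(transfection-reagent-only wells) as robust Z-scores,

    RZ = (x - median(ref)) / (c * MAD(ref)),    MAD = median(|ref - median(ref)|),

with c the MAD scaling constant (1.4826 makes the denominator a consistent
normal-scale estimate).  A gene is a hit when at least ``min_sirnas`` of its
siRNAs score beyond the threshold in the same direction in at least
``min_replicates`` replicate experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default MAD scaling constant (normal-consistency); the screen's printed
#: formula uses 1.14826, reproducible by passing that value explicitly.
DEFAULT_MAD_CONSTANT = 1.4826

#: well roles
ROLE_SAMPLE = "sample"
ROLE_REFERENCE = "reference"
WELL_COLUMNS = ["plate", "row", "col", "replicate", "gene", "sirna", "role", "value"]


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------


@dataclass
class MedianPolishResult:
    corrected: np.ndarray  # residuals + overall effect
    residuals: np.ndarray
    row_effects: np.ndarray
    col_effects: np.ndarray
    overall: float
    converged: bool
    n_iter: int


def _nanmedian0(a: np.ndarray, axis: int) -> np.ndarray:
    """nanmedian along an axis with all-NaN slices mapped to 0 (warned)."""
    mask = np.all(np.isnan(a), axis=axis)
    if mask.any():
        logger.warning(
            "%d fully-missing row(s)/column(s); their effects are set to 0",
            int(mask.sum()),
        )
    out = np.zeros(a.shape[1 - axis])
    if (~mask).any():
        sub = np.nanmedian(np.compress(~mask, a, axis=1 - axis), axis=axis)
        out[~mask] = sub
    return out


def median_polish(
    plate_matrix: Union[np.ndarray, Sequence[Sequence[float]]],
    max_iter: int = 10,
    tol: float = 1e-6,
) -> MedianPolishResult:
    """Tukey's two-way median polish of a rows x columns plate matrix.

    Iteratively sweeps row medians and column medians out of the matrix
    (the sweep order follows the classical algorithm, re-centring the
    running effects by their own median each half-step), accumulating row,
    column and overall effects.  Missing wells (NaN) are ignored by the
    medians and remain missing in the output.  Convergence is declared when
    the sum of absolute residuals changes by less than ``tol``.

    Returns residuals-plus-overall as the positionally corrected values.
    """
    z = np.asarray(plate_matrix, dtype=float).copy()
    if z.ndim != 2:
        raise ValueError("plate matrix must be two-dimensional")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = _nanmedian0(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = float(np.median(col))
        col -= delta
        overall += delta

        cdelta = _nanmedian0(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = float(np.median(row))
        row -= delta
        overall += delta

        newsum = float(np.nansum(np.abs(z)))
        if newsum == 0.0 or abs(newsum - oldsum) < tol:
            converged = True
            break
        oldsum = newsum
    return MedianPolishResult(
        corrected=z + overall,
        residuals=z,
        row_effects=row,
        col_effects=col,
        overall=overall,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# robust Z-scores
# ---------------------------------------------------------------------------


def rz_score(
    values: Union[float, Sequence[float], np.ndarray],
    reference_population: Sequence[float],
    mad_constant: float = DEFAULT_MAD_CONSTANT,
) -> np.ndarray:
    """Robust Z-score of well values against a reference population.

    RZ = (x - median(ref)) / (mad_constant * MAD(ref)).  Raises if the
    reference MAD is zero rather than dividing silently -- use a fallback
    scale (e.g. a standard-deviation-based score) for such degenerate
    plates.
    """
    ref = np.asarray(reference_population, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size < 8:
        raise ValueError(
            f"reference population too small ({ref.size} wells; need >= 8)"
        )
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad == 0.0:
        raise ValueError(
            "MAD of the reference population is zero; robust Z-scores are "
            "undefined -- use a fallback scale estimate for this plate"
        )
    return (np.asarray(values, dtype=float) - med) / (mad_constant * mad)


def multi_foci_fraction(
    foci_counts: Sequence[int], threshold: int = 5
) -> float:
    """Percentage of cells with at least ``threshold`` foci."""
    counts = np.asarray(foci_counts)
    if counts.size == 0:
        raise ValueError("no cells: multi-foci fraction is undefined")
    if (counts < 0).any():
        raise ValueError("foci counts must be non-negative")
    return 100.0 * float(np.count_nonzero(counts >= threshold)) / counts.size


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------


def call_hits(
    rz_results: pd.DataFrame,
    threshold: float = 2.0,
    min_sirnas: int = 2,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Replicate-aware gene-level hit calling from per-siRNA RZ scores.

    ``rz_results`` needs columns ``gene``, ``sirna``, ``replicate``, ``rz``.
    A siRNA supports a direction when its RZ exceeds ``threshold`` (positive)
    or ``-threshold`` (negative) in at least ``min_replicates`` replicates;
    a gene is a hit in a direction when at least ``min_sirnas`` of its
    siRNAs support that same direction.  Genes with fewer than
    ``min_sirnas`` siRNAs can never be hits and are flagged underpowered.

    Returns one row per gene with the hit verdict, direction (+1/-1/0) and
    the gene-level score (median across siRNAs of each siRNA's median RZ
    across replicates).
    """
    required = {"gene", "sirna", "replicate", "rz"}
    if not required.issubset(rz_results.columns):
        raise ValueError(f"rz_results needs columns {sorted(required)}")

    per_sirna = (
        rz_results.groupby(["gene", "sirna"])["rz"]
        .agg(
            median_rz="median",
            n_pos=lambda v: int((v > threshold).sum()),
            n_neg=lambda v: int((v < -threshold).sum()),
        )
        .reset_index()
    )
    per_sirna["supports_pos"] = per_sirna["n_pos"] >= min_replicates
    per_sirna["supports_neg"] = per_sirna["n_neg"] >= min_replicates

    rows = []
    for gene, grp in per_sirna.groupby("gene", sort=True):
        n_sirnas = len(grp)
        n_sup_pos = int(grp["supports_pos"].sum())
        n_sup_neg = int(grp["supports_neg"].sum())
        underpowered = n_sirnas < min_sirnas
        direction = 0
        if not underpowered:
            if n_sup_pos >= min_sirnas and n_sup_neg >= min_sirnas:
                # contradictory directions across siRNAs: not a coherent hit
                direction = 0
            elif n_sup_pos >= min_sirnas:
                direction = 1
            elif n_sup_neg >= min_sirnas:
                direction = -1
        rows.append(
            {
                "gene": gene,
                "n_sirnas": n_sirnas,
                "n_supporting_pos": n_sup_pos,
                "n_supporting_neg": n_sup_neg,
                "is_hit": direction != 0,
                "direction": direction,
                "median_rz": float(grp["median_rz"].median()),
                "underpowered": underpowered,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_sirnas",
            "n_supporting_pos",
            "n_supporting_neg",
            "is_hit",
            "direction",
            "median_rz",
            "underpowered",
        ],
    )


# ---------------------------------------------------------------------------
# end-to-end screen scoring
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    wells: pd.DataFrame  # input wells + corrected value + rz
    sirna_scores: pd.DataFrame  # per (gene, sirna, replicate) RZ
    sirna_medians: pd.DataFrame  # per (gene, sirna) median RZ across replicates
    hits: pd.DataFrame  # gene-level hit table


def score_screen(
    wells: pd.DataFrame,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
    threshold: float = 2.0,
    min_sirnas: int = 2,
    min_replicates: int = 2,
    polish: bool = True,
    polish_max_iter: int = 10,
    polish_tol: float = 1e-6,
) -> ScreenResult:
    """Score a well table end to end.

    ``wells`` needs columns plate, row, col, replicate, gene, sirna, role,
    value (rows/cols are integer indices; role is ``reference`` for the
    in-plate reference population and ``sample`` for library wells).  Each
    plate of each replicate is median-polished separately, reference wells
    included; RZ scores are computed per plate against its corrected
    reference wells.  ``polish=False`` skips positional correction (for
    assessing its contribution), scoring raw values directly.
    """
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"well table lacks columns {sorted(missing)}")
    df = wells.copy().reset_index(drop=True)
    df["corrected"] = np.nan
    df["rz"] = np.nan

    for (rep, plate), grp in df.groupby(["replicate", "plate"], sort=True):
        rows = np.sort(grp["row"].unique())
        cols = np.sort(grp["col"].unique())
        ridx = {r: k for k, r in enumerate(rows)}
        cidx = {c: k for k, c in enumerate(cols)}
        mat = np.full((len(rows), len(cols)), np.nan)
        for _, w in grp.iterrows():
            mat[ridx[w["row"]], cidx[w["col"]]] = w["value"]
        if polish:
            res = median_polish(mat, max_iter=polish_max_iter, tol=polish_tol)
            corrected = res.corrected
        else:
            corrected = mat
        corr_vals = [
            corrected[ridx[r], cidx[c]] for r, c in zip(grp["row"], grp["col"])
        ]
        df.loc[grp.index, "corrected"] = corr_vals
        ref_mask = grp["role"] == ROLE_REFERENCE
        ref_vals = df.loc[grp.index[ref_mask], "corrected"].to_numpy()
        df.loc[grp.index, "rz"] = rz_score(
            df.loc[grp.index, "corrected"].to_numpy(), ref_vals, mad_constant
        )

    samples = df[df["role"] == ROLE_SAMPLE]
    sirna_scores = samples[["gene", "sirna", "replicate", "rz"]].reset_index(
        drop=True
    )
    sirna_medians = (
        sirna_scores.groupby(["gene", "sirna"])["rz"]
        .median()
        .rename("median_rz")
        .reset_index()
    )
    hits = call_hits(
        sirna_scores,
        threshold=threshold,
        min_sirnas=min_sirnas,
        min_replicates=min_replicates,
    )
    return ScreenResult(
        wells=df, sirna_scores=sirna_scores, sirna_medians=sirna_medians, hits=hits
    )
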