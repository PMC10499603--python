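"""Tests for median polish, robust Z-scoring and hit calling."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoej import (
    call_hits,
    median_polish,
    multi_foci_fraction,
    rz_score,
    score_screen,
    simulate_plate,
)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------


def test_median_polish_2x2_residual_medians_zero():
    res = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert np.abs(np.median(res.residuals, axis=0)).max() < 1e-9
    assert np.abs(np.median(res.residuals, axis=1)).max() < 1e-9
    # decomposition reassembles the data
    fitted = (
        res.overall
        + res.row_effects[:, None]
        + res.col_effects[None, :]
        + res.residuals
    )
    assert fitted == pytest.approx(np.array([[1.0, 2.0], [3.0, 4.0]]))


def test_median_polish_constant_matrix():
    res = median_polish(np.full((5, 7), 3.25))
    assert res.residuals == pytest.approx(np.zeros((5, 7)))
    assert res.corrected == pytest.approx(np.full((5, 7), 3.25))


def test_median_polish_near_idempotent_at_fixed_point():
    """Polishing its own output leaves only negligible residual structure.

    Median polish converges when neither sweep reduces the absolute-residual
    sum; at that fixed point column medians are exactly zero (last sweep)
    and row medians are small but not exactly zero, so a second polish may
    move values by at most that small amount."""
    rng = np.random.default_rng(0)
    mat = rng.normal(10, 2, size=(8, 12))
    first = median_polish(mat, max_iter=50)
    scale = np.std(mat)
    assert np.abs(np.median(first.residuals, axis=0)).max() < 1e-9
    assert np.abs(np.median(first.residuals, axis=1)).max() < 0.05 * scale
    second = median_polish(first.corrected, max_iter=50)
    assert np.abs(second.row_effects).max() < 0.05 * scale
    assert np.abs(second.col_effects).max() < 0.05 * scale
    assert second.corrected == pytest.approx(first.corrected, abs=0.1 * scale)


def test_median_polish_removes_planted_gradient():
    rng = np.random.default_rng(1)
    row_grad = np.linspace(-6, 6, 16)
    col_grad = np.linspace(4, -4, 24)
    mat = 20 + row_grad[:, None] + col_grad[None, :] + rng.normal(0, 0.5, (16, 24))
    res = median_polish(mat, max_iter=20)
    assert res.corrected.mean(axis=1).std() < 0.5  # row gradient gone
    assert np.corrcoef(res.row_effects, row_grad)[0, 1] > 0.99


def test_median_polish_missing_wells_stay_missing():
    mat = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]])
    res = median_polish(mat)
    assert np.isnan(res.corrected[1, 1])
    assert np.isfinite(np.delete(res.corrected.ravel(), 4)).all()


def test_median_polish_matches_r_medpolish():
    """Independent oracle: R's stats::medpolish on the same seeded matrix."""
    rng = np.random.default_rng(42)
    mat = rng.normal(30, 5, size=(6, 8)).round(3)
    res = median_polish(mat, max_iter=100, tol=1e-10)
    r_code = (
        "x <- matrix(c(%s), nrow=6, byrow=TRUE);"
        "p <- medpolish(x, eps=1e-10, maxiter=100, trace.iter=FALSE);"
        "cat(jsonlite::toJSON(list(overall=p$overall, row=p$row, col=p$col,"
        " res=as.vector(t(p$residuals))), digits=NA))"
        % ",".join(f"{v}" for v in mat.ravel())
    )
    out = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
    )
    ref = json.loads(out.stdout)
    assert res.overall == pytest.approx(ref["overall"][0], abs=1e-6)
    assert res.row_effects == pytest.approx(np.array(ref["row"]), abs=1e-6)
    assert res.col_effects == pytest.approx(np.array(ref["col"]), abs=1e-6)
    assert res.residuals.ravel() == pytest.approx(np.array(ref["res"]), abs=1e-6)


# ---------------------------------------------------------------------------
# robust Z-scores
# ---------------------------------------------------------------------------


def test_rz_zero_at_reference_median():
    ref = [0, 1, 2, 3, 4, 5, 6, 7, 8]
    assert rz_score(4.0, ref) == pytest.approx(0.0)


def test_rz_unit_score_at_one_scaled_mad():
    ref = [0, 1, 2, 3, 4] * 2  # median 2, MAD 1
    assert rz_score(2 + 1.4826, ref) == pytest.approx(1.0)
    # the printed variant of the constant is equally supported
    assert rz_score(2 + 1.14826, ref, mad_constant=1.14826) == pytest.approx(1.0)


def test_rz_antisymmetry():
    rng = np.random.default_rng(3)
    ref = rng.normal(10, 2, size=50)
    med = np.median(ref)
    x = 13.7
    assert rz_score(x, ref) == pytest.approx(-rz_score(2 * med - x, ref))


def test_rz_reference_population_has_median_zero():
    rng = np.random.default_rng(4)
    ref = rng.normal(0, 1, size=41)
    assert np.median(rz_score(ref, ref)) == pytest.approx(0.0)


def test_rz_zero_mad_raises():
    with pytest.raises(ValueError, match="MAD"):
        rz_score(1.0, [5.0] * 10)


def test_rz_small_reference_raises():
    with pytest.raises(ValueError, match="reference"):
        rz_score(1.0, [1, 2, 3])


# ---------------------------------------------------------------------------
# multi-foci fraction
# ---------------------------------------------------------------------------


def test_multi_foci_examples():
    assert multi_foci_fraction([0, 0, 5, 7]) == 50.0
    assert multi_foci_fraction([0, 1, 2, 3, 4]) == 0.0
    with pytest.raises(ValueError):
        multi_foci_fraction([])


def test_multi_foci_matches_poisson_tail():
    rng = np.random.default_rng(8)
    counts = rng.poisson(2.0, size=10_000)
    observed = multi_foci_fraction(counts, threshold=5)
    expected = 100 * stats.poisson.sf(4, 2.0)
    # three-sigma binomial band around the closed-form tail probability
    sigma = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / 10_000)
    assert abs(observed - expected) < 3 * sigma


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------


def _rz_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "sirna", "replicate", "rz"])


def test_two_sirnas_two_replicates_negative_hit():
    rows = [
        ("G1", "s1", 1, -3.0),
        ("G1", "s1", 2, -3.0),
        ("G1", "s2", 1, -3.0),
        ("G1", "s2", 2, -3.0),
    ]
    hits = call_hits(_rz_frame(rows))
    assert hits.loc[0, "is_hit"]
    assert hits.loc[0, "direction"] == -1


def test_opposite_directions_not_a_hit():
    rows = [
        ("G1", "s1", r, 3.0) for r in (1, 2)
    ] + [("G1", "s2", r, -3.0) for r in (1, 2)]
    hits = call_hits(_rz_frame(rows))
    assert not hits.loc[0, "is_hit"]


def test_single_sirna_gene_underpowered():
    rows = [("G1", "s1", r, 5.0) for r in (1, 2, 3)]
    hits = call_hits(_rz_frame(rows))
    assert not hits.loc[0, "is_hit"]
    assert hits.loc[0, "underpowered"]


def test_one_replicate_insufficient():
    rows = [
        ("G1", "s1", 1, 3.0),
        ("G1", "s1", 2, 0.0),
        ("G1", "s2", 1, 3.0),
        ("G1", "s2", 2, 0.0),
    ]
    assert not call_hits(_rz_frame(rows)).loc[0, "is_hit"]


def test_hit_calling_monotone_in_rz_magnitude():
    """Raising a supporting siRNA's |RZ| never un-calls a hit."""
    rows = [
        ("G1", "s1", 1, 2.5),
        ("G1", "s1", 2, 2.5),
        ("G1", "s2", 1, 2.5),
        ("G1", "s2", 2, 2.5),
    ]
    base = call_hits(_rz_frame(rows))
    assert base.loc[0, "is_hit"]
    boosted = _rz_frame([(g, s, r, rz * 3) for g, s, r, rz in rows])
    assert call_hits(boosted).loc[0, "is_hit"]


# ---------------------------------------------------------------------------
# end-to-end screen scoring
# ---------------------------------------------------------------------------


def test_screen_recovery_with_positional_effects():
    """Planted hits are recovered on a positionally distorted mini-screen,
    and skipping the polish degrades recovery."""
    # 117 genes fill one 384-well plate exactly; 10 planted hits keep the
    # per-row hit density realistic (median polish assumes hits are rare)
    wells, truth = simulate_plate(
        genes=117, hit_fraction=10 / 117, effect_rz=4.0, seed=9
    )
    scored = score_screen(wells)
    called = set(scored.hits.loc[scored.hits.is_hit, "gene"])
    planted = set(truth.gene)
    recall = len(called & planted) / len(planted)
    assert recall >= 0.9
    false_pos = len(called - planted)
    assert false_pos <= 2
    # directionality matches the planted (inhibitory) effect
    directions = scored.hits.set_index("gene").loc[sorted(called & planted), "direction"]
    assert (directions == -1).all()


def test_screen_null_yields_no_hits():
    wells, _ = simulate_plate(genes=117, hit_fraction=0.0, seed=10)
    scored = score_screen(wells)
    assert int(scored.hits["is_hit"].sum()) <= 1


def test_sirna_median_is_median_of_replicates():
    wells, _ = simulate_plate(genes=30, hit_fraction=0.1, seed=12)
    scored = score_screen(wells)
    one = scored.sirna_scores[scored.sirna_scores.sirna == "GENE0001_s1"]
    expected = one["rz"].median()
    got = scored.sirna_medians.set_index("sirna").loc["GENE0001_s1", "median_rz"]
    assert got == pytest.approx(expected)
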