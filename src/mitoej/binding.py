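"""Steady-state one-site binding-isotherm fits for biosensor titrations.

At equilibrium a 1:1 interaction gives the Langmuir isotherm

    R(C) = Rmax * C / (Kd + C)

where C is the analyte concentration, Rmax the saturating response and Kd
the dissociation constant.  Bio-layer interferometry titrations read the
plateau response at each analyte concentration; fitting the isotherm by
least squares yields Kd.  Affinity changes between ligand variants (e.g. a
phosphorylated vs unmodified peptide) are expressed as Kd ratios with
first-order propagated errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSeries:
    """Equilibrium concentration/response pairs for one ligand."""

    label: str
    concentrations_nM: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be 1-D and equal length")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "concentrations_nM", c)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class KdFit:
    """One-site steady-state fit result (Kd in the concentration units)."""

    kd: float
    rmax: float
    rss: float
    kd_se: float
    rmax_se: float
    converged: bool
    n_points: int
    label: str = ""


class FoldChange(NamedTuple):
    ratio: float
    se: float


def one_site(concentration: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """Langmuir one-site isotherm R = Rmax*C/(Kd + C)."""
    c = np.asarray(concentration, dtype=float)
    return rmax * c / (kd + c)


def fit_steady_state(
    concentrations: Sequence[float],
    responses: Sequence[float],
    kd_guess: Optional[float] = None,
    rmax_guess: Optional[float] = None,
    max_iter: int = 500,
    label: str = "",
) -> KdFit:
    """Least-squares fit of the one-site isotherm to equilibrium responses.

    Parameters are log-transformed internally, constraining Kd and Rmax to
    be positive.  Default initial guesses: Kd at the geometric mid-point of
    the concentration range, Rmax at the maximum response.  At least five
    concentration points spanning an order of magnitude are required for a
    fit to be reported.  Responses that decrease with concentration beyond
    a small noise floor trigger a warning but the fit is still returned.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.ndim != 1 or c.shape != r.shape:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    if c.size < 5:
        raise ValueError(f"need at least 5 concentration points, got {c.size}")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if c.max() / c.min() < 10.0:
        raise ValueError(
            "concentration series must span at least one order of magnitude"
        )
    order = np.argsort(c)
    steps = np.diff(r[order])
    floor = 0.05 * max(r.max(), 1e-12)
    if (steps < -floor).any():
        warnings.warn(
            "responses are non-monotone in concentration beyond the noise "
            "floor; inspect the series",
            stacklevel=2,
        )
    kd0 = kd_guess if kd_guess is not None else float(np.sqrt(c.min() * c.max()))
    rmax0 = rmax_guess if rmax_guess is not None else float(max(r.max(), 1e-9))

    def resid(x: np.ndarray) -> np.ndarray:
        kd, rmax = np.exp(x)
        return one_site(c, kd, rmax) - r

    sol = least_squares(
        resid,
        x0=np.log([kd0, rmax0]),
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter * 4,
    )
    kd, rmax = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))
    dof = max(c.size - 2, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(jtj) * rss / dof
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    return KdFit(
        kd=float(kd),
        rmax=float(rmax),
        rss=rss,
        kd_se=float(kd * se_log[0]),  # delta method from the log scale
        rmax_se=float(rmax * se_log[1]),
        converged=bool(sol.status > 0),
        n_points=int(c.size),
        label=label,
    )


def fit_series(series: BindingSeries, **kwargs) -> KdFit:
    """Fit a :class:`BindingSeries` (convenience wrapper)."""
    return fit_steady_state(
        series.concentrations_nM, series.responses, label=series.label, **kwargs
    )


def affinity_fold_change(fit_a: KdFit, fit_b: KdFit) -> FoldChange:
    """Kd ratio fit_a/fit_b with first-order error propagation.

    The relative variance of the ratio is the sum of the two relative
    variances (fits assumed independent).  Both fits must have converged.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged to compare affinities")
    ratio = fit_a.kd / fit_b.kd
    rel = np.hypot(fit_a.kd_se / fit_a.kd, fit_b.kd_se / fit_b.kd)
    return FoldChange(ratio=float(ratio), se=float(ratio * rel))
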