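"""Validation statistics and accuracy metrics for site-level results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gridding import GridCell

__all__ = [
    "RegressionResult",
    "MissingPlantEvaluation",
    "linreg",
    "accuracy_percent",
    "pct_of_potential",
    "mean_canopy_volume_per_vine",
    "match_ground_truth",
    "round2",
]


@dataclass
class RegressionResult:
    """OLS fit of observed on estimated volumes."""

    slope: float
    intercept: float
    r_squared: float  # in [0, 1]
    rmse: float  # m^3
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass
class MissingPlantEvaluation:
    """Site-level missing-plant bookkeeping."""

    potential: int
    estimated: int
    observed: int

    @property
    def accuracy_pct(self) -> float:
        return accuracy_percent(self.estimated, self.observed)

    @property
    def pct_of_potential(self) -> float:
        return pct_of_potential(self.observed, self.potential)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def linreg(
    estimates: Sequence[float],
    observations: Sequence[float],
    *,
    rmse_kind: str = "agreement",
) -> RegressionResult:
    """Ordinary least squares of observed on estimated volumes.

    ``r_squared`` is the squared Pearson correlation.  By default the RMSE
    is the agreement RMSE between the paired values themselves (how far
    the two series are from the 1:1 line), not the regression-residual
    RMSE; pass ``rmse_kind="residual"`` for the latter.
    """
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if est.shape != obs.shape:
        raise ValueError("estimates and observations must have equal length")
    n = len(est)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if est.std() == 0 or obs.std() == 0:
        raise ValueError("zero variance in estimates or observations")
    fit = stats.linregress(est, obs)
    if rmse_kind == "agreement":
        rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    elif rmse_kind == "residual":
        resid = obs - (fit.slope * est + fit.intercept)
        rmse = float(np.sqrt(np.mean(resid**2)))
    else:
        raise ValueError("rmse_kind must be 'agreement' or 'residual'")
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=rmse,
        n=n,
    )


def accuracy_percent(estimated: float, observed: float) -> float:
    """Signed percentage error of an estimated count vs. the observed count.

    ``(estimated - observed) / observed * 100``, reported to 2 decimals.
    """
    if observed <= 0:
        raise ValueError("observed count must be positive")
    return round2((estimated - observed) / observed * 100.0)


def pct_of_potential(observed: float, potential: float) -> float:
    """Observed missing plants as a percentage of potential plant positions."""
    if potential <= 0:
        raise ValueError("potential count must be positive")
    return round2(observed / potential * 100.0)


def mean_canopy_volume_per_vine(
    total_volume: float, potential: int, estimated_missing: int
) -> float:
    """Total canopy volume divided by the detected plant count.

    Detected plants are potential positions minus estimated missing plants.
    """
    detected = potential - estimated_missing
    if detected <= 0:
        raise ValueError("potential minus estimated_missing must be positive")
    return total_volume / detected


def match_ground_truth(
    cells: Sequence,
    grid: Sequence[GridCell],
    truth_points: np.ndarray,
) -> dict:
    """Compare per-cell missing-plant counts against surveyed gap positions.

    ``cells`` expose ``cell_id`` and ``n_missing``; ``grid`` supplies the
    matching polygons (half-open membership, so a point on a shared edge
    counts once).  Returns site totals, per-cell signed errors, and counts
    of over-/under-detected cells; truth points falling outside every cell
    land in an ``unassigned`` bucket.
    """
    truth_points = np.asarray(truth_points, dtype=float).reshape(-1, 2)
    by_id = {c.cell_id: c for c in grid}
    observed = {c.cell_id: 0 for c in cells}
    assigned = np.zeros(len(truth_points), dtype=bool)
    for cid in observed:
        cell = by_id[cid]
        if len(truth_points):
            inside = cell.contains(truth_points)
            observed[cid] = int(inside.sum())
            assigned |= inside
    unassigned = int((~assigned).sum())
    if unassigned:
        warnings.warn(f"{unassigned} ground-truth points outside all cells", stacklevel=2)
    per_cell = {}
    over = under = exact = 0
    est_total = obs_total = 0
    for c in cells:
        err = c.n_missing - observed[c.cell_id]
        per_cell[c.cell_id] = {
            "estimated": c.n_missing,
            "observed": observed[c.cell_id],
            "error": err,
        }
        est_total += c.n_missing
        obs_total += observed[c.cell_id]
        if err > 0:
            over += 1
        elif err < 0:
            under += 1
        else:
            exact += 1
    return {
        "estimated_total": est_total,
        "observed_total": obs_total,
        "unassigned": unassigned,
        "cells_over": over,
        "cells_under": under,
        "cells_exact": exact,
        "per_cell": per_cell,
    }
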