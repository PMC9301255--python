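"""Data-driven estimation of the stimulation period δ.

The stimulation frequency is known in principle, but device clock
inaccuracies make the effective period (in samples) differ slightly from
fs / stim_freq, and sample-exact loss resolution needs δ to high precision.
The period is estimated by minimising the pooled harmonic-regression residual
over all runs, each run fitted with its own coefficients (phase is unknown
across an unresolved loss) but all sharing one candidate δ — runs are treated
like independent channels.  The search is stagewise: two successive grids
around the nominal period, then a bounded scalar refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .harmonics import fit_harmonic
from .packets import Run

logger = logging.getLogger(__name__)

__all__ = ["PeriodSearchConfig", "pooled_period_objective", "estimate_period"]


class PeriodSearchError(RuntimeError):
    """The period objective could not be minimised unambiguously."""


@dataclass
class PeriodSearchConfig:
    """Settings for the stagewise period search.

    nominal_delta : search centre, samples (fs / stimulation frequency).
    coarse_halfwidth : relative half-width of the stage-1 window (default
        1e-3, i.e. ±0.1% of the nominal period — generous for clock error).
    stage_grid_sizes : grid points per stage (two stages by default).
    samples_per_run_cap : at most this many leading samples of each run
        enter the objective.
    order : harmonics used during the search.
    """

    nominal_delta: float
    coarse_halfwidth: float = 1e-3
    stage_grid_sizes: tuple[int, ...] = (101, 101)
    samples_per_run_cap: int = 10_000
    order: int = 4
    final_rel_tol: float = 1e-7
    min_periods_per_run: int = 10

    def __post_init__(self) -> None:
        if self.nominal_delta <= 1:
            raise ValueError("nominal_delta must exceed 1 sample")
        if any(g < 3 for g in self.stage_grid_sizes):
            raise ValueError("every search grid needs at least 3 points")
        if self.samples_per_run_cap < 100:
            raise ValueError("samples_per_run_cap must be >= 100")


def _usable(run: Run, order: int) -> bool:
    return run.length >= 2 * order + 2


def pooled_period_objective(
    runs: list[Run], delta: float, order: int, samples_per_run_cap: int | None = None
) -> float:
    """Sum over runs of the per-run harmonic-fit residual sum of squares at δ.

    Each run is fitted with its own coefficient vector (phase continuity
    across losses cannot be assumed before the losses are resolved).  Runs
    too short to fit are skipped with a warning.
    """
    total = 0.0
    used = 0
    for run in runs:
        t, y = run.times, run.values
        if samples_per_run_cap is not None:
            t, y = t[:samples_per_run_cap], y[:samples_per_run_cap]
        if t.size < 2 * order + 2:
            logger.warning("run of %d samples too short for order %d; skipped", t.size, order)
            continue
        try:
            _, rss, _ = fit_harmonic(t, y, delta, order)
        except np.linalg.LinAlgError:
            logger.warning("rank-deficient fit at delta=%g; run skipped", delta)
            continue
        total += rss
        used += 1
    if used == 0:
        raise PeriodSearchError("no run was long enough to enter the period objective")
    return total


def _grid_stage(objective, lo: float, hi: float, n_points: int, check_unimodal: bool):
    grid = np.linspace(lo, hi, n_points)
    vals = np.array([objective(d) for d in grid])
    if check_unimodal:
        finite = np.isfinite(vals)
        interior = (
            (vals[1:-1] < vals[:-2])
            & (vals[1:-1] <= vals[2:])
            & finite[1:-1]
        ).nonzero()[0] + 1
        if interior.size >= 2:
            order_ = interior[np.argsort(vals[interior])]
            best, second = order_[0], order_[1]
            # nearly-touching minima are one valley split by a degenerate
            # grid point (e.g. an exactly-integer period); only well
            # separated comparable minima signal a genuinely ambiguous period
            separated = abs(int(best) - int(second)) > 3
            comparable = vals[best] > 0 and (vals[second] - vals[best]) / vals[best] < 0.05
            if separated and comparable:
                raise PeriodSearchError(
                    "period objective has two comparable minima across the coarse "
                    "grid; use more data or a narrower search window"
                )
    k = int(np.argmin(vals))
    lo_next = grid[max(k - 1, 0)]
    hi_next = grid[min(k + 1, n_points - 1)]
    return grid[k], lo_next, hi_next


def estimate_period(runs: list[Run], config: PeriodSearchConfig) -> float:
    """Estimate δ by stagewise grid search plus bounded refinement.

    Stage 1 scans ``nominal * (1 ± coarse_halfwidth)``; each later stage
    re-grids the bracket around the previous argmin; a final bounded scalar
    minimisation refines to ``final_rel_tol`` relative tolerance.  Runs
    shorter than ``min_periods_per_run`` periods are excluded (their phase is
    too poorly conditioned to help).
    """
    min_len = config.min_periods_per_run * config.nominal_delta
    usable = [r for r in runs if r.length >= min_len and _usable(r, config.order)]
    if not usable:
        raise PeriodSearchError(
            f"no run reaches {config.min_periods_per_run} periods "
            f"({min_len:.0f} samples); cannot estimate the period"
        )

    def objective(delta: float) -> float:
        try:
            return pooled_period_objective(
                usable, delta, config.order, config.samples_per_run_cap
            )
        except PeriodSearchError:
            # isolated degenerate candidate (e.g. an exactly-integer period
            # whose top harmonic vanishes on the sample grid)
            return float("inf")

    lo = config.nominal_delta * (1 - config.coarse_halfwidth)
    hi = config.nominal_delta * (1 + config.coarse_halfwidth)
    best = config.nominal_delta
    for stage, n_points in enumerate(config.stage_grid_sizes):
        best, lo, hi = _grid_stage(objective, lo, hi, n_points, check_unimodal=stage == 0)

    res = minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": config.nominal_delta * config.final_rel_tol},
    )
    delta_hat = float(res.x) if res.fun <= objective(best) else best
    logger.info("estimated period %.7f samples (nominal %.7f)", delta_hat, config.nominal_delta)
    return delta_hat
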