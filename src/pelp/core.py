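"""Loss-size resolution: pick the gap size that makes the artifact line up.

For the loss between runs r and r+1, each candidate integer gap size Δ places
run r+1 at shifted times n_r + Δ + t on the grid of run r (0-based sample
times).  One shared harmonic coefficient vector β is fitted by least squares
to both runs jointly — sharing β across the pair is what makes Δ
identifiable — and the candidate minimising the joint RMSE is selected:

    Δ̂ = argmin_{Δ in Ω} min_β [ Σ_k (y_{k,r} - f_β(t_{k,r}))²
                               + Σ_k (y_{k,r+1} - f_β(n_r + Δ + t_{k,r+1}))² ]

Ω is a window of integers centred on the metadata estimate, spanning its
uncertainty.  Candidates that differ by a near-integer multiple of the
period δ produce near-identical fits and cannot be distinguished; such
ambiguity is detected and reported rather than silently resolved.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .harmonics import design_matrix, fit_harmonic, phase_fold
from .packets import RecordingTimeline, Run

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "joint_fit_score",
    "score_profile",
    "estimate_loss",
    "resolve_all",
    "consolidation_report",
    "ConsolidationReport",
]


@dataclass
class CandidateSet:
    """Integer candidate loss sizes ``max(1, center-halfwidth) .. center+halfwidth``.

    ``center`` is the metadata-derived initial estimate; ``halfwidth`` the
    uncertainty (in samples) we allow around it.  ``halfwidth=0`` means the
    metadata is trusted outright.
    """

    center: int
    halfwidth: int

    def __post_init__(self) -> None:
        self.center = int(self.center)
        self.halfwidth = int(self.halfwidth)
        if self.center < 1:
            raise ValueError("center must be >= 1")
        if self.halfwidth < 0:
            raise ValueError("halfwidth must be >= 0")

    @property
    def members(self) -> np.ndarray:
        return np.arange(max(1, self.center - self.halfwidth), self.center + self.halfwidth + 1)


def _flanks(run_r: Run, run_r1: Run, max_flank: int | None):
    """Times/values entering the joint fit, optionally truncated near the loss."""
    t1, y1 = run_r.times, run_r.values
    t2, y2 = run_r1.times, run_r1.values
    if max_flank is not None:
        t1, y1 = t1[-max_flank:], y1[-max_flank:]
        t2, y2 = t2[:max_flank], y2[:max_flank]
    return t1, y1, t2, y2


def joint_fit_score(
    run_r: Run,
    run_r1: Run,
    delta: float,
    order: int,
    candidate: int,
    max_flank: int | None = None,
) -> float:
    """Joint RMSE of one shared harmonic fit to both flanking runs at gap Δ.

    Run r+1 samples are placed at ``n_r + Δ + t`` (0-based times), a single β
    is fitted by SVD least squares to the concatenated data, and the
    root-mean-squared residual over all points of both runs is returned.
    A rank-deficient joint design yields ``inf`` (candidate unusable).

    ``max_flank`` truncates each run to the samples nearest the loss, which
    bounds the influence of slow drift within long runs.
    """
    t1, y1, t2, y2 = _flanks(run_r, run_r1, max_flank)
    times = np.concatenate([t1, run_r.length + candidate + t2])
    values = np.concatenate([y1, y2])
    p = 2 * order + 1
    if times.size < p + 1:
        raise ValueError(f"flanking runs supply {times.size} samples; need {p + 1}")
    X = design_matrix(times, delta, order)
    beta, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < p:
        warnings.warn(
            f"rank-deficient joint design at candidate {candidate}", stacklevel=2
        )
        return float("inf")
    resid = values - X @ beta
    return float(np.sqrt(resid @ resid / values.size))


def _rotations(order: int, thetas: np.ndarray) -> np.ndarray:
    """Block-diagonal rotations mapping the Δ=0 design onto each candidate.

    Shifting every time by Δ multiplies the (sin, cos) pair of harmonic j by
    a rotation through θ_j = 2πjΔ/δ; the intercept is untouched.  Returns an
    array of shape (K, p, p) for K candidates.
    """
    K = thetas.shape[0]
    p = 2 * order + 1
    B = np.zeros((K, p, p))
    B[:, 0, 0] = 1.0
    for j in range(1, order + 1):
        c, s = np.cos(j * thetas), np.sin(j * thetas)
        B[:, 2 * j - 1, 2 * j - 1] = c
        B[:, 2 * j - 1, 2 * j] = s
        B[:, 2 * j, 2 * j - 1] = -s
        B[:, 2 * j, 2 * j] = c
    return B


def score_profile(
    run_r: Run,
    run_r1: Run,
    delta: float,
    order: int,
    candidates: np.ndarray,
    max_flank: int | None = None,
) -> np.ndarray:
    """Joint RMSE for every candidate gap at once.

    Equivalent to calling :func:`joint_fit_score` per candidate, but solved
    through the normal equations with the rotation identity: the candidate
    only rotates run r+1's sin/cos design columns, so the per-candidate cost
    is independent of the run lengths.  Falls back to the SVD path for any
    candidate whose normal equations are singular.
    """
    candidates = np.asarray(candidates, dtype=float)
    t1, y1, t2, y2 = _flanks(run_r, run_r1, max_flank)
    p = 2 * order + 1
    if t1.size + t2.size < p + 1:
        raise ValueError(f"flanking runs supply {t1.size + t2.size} samples; need {p + 1}")
    X1 = design_matrix(t1, delta, order)
    X2 = design_matrix(run_r.length + t2, delta, order)  # Δ = 0 baseline
    G1 = X1.T @ X1
    G2 = X2.T @ X2
    c1 = X1.T @ y1
    c2 = X2.T @ y2
    yty = float(y1 @ y1 + y2 @ y2)
    n = y1.size + y2.size

    B = _rotations(order, 2.0 * np.pi * candidates / delta)
    A = G1[None, :, :] + B @ G2 @ B.transpose(0, 2, 1)
    b = c1[None, :] + (B @ c2[:, None])[:, :, 0]
    try:
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        rss = yty - np.einsum("kp,kp->k", beta, b)
        out = np.sqrt(np.clip(rss, 0.0, None) / n)
    except np.linalg.LinAlgError:
        out = np.array(
            [
                joint_fit_score(run_r, run_r1, delta, order, int(d), max_flank)
                for d in candidates
            ]
        )
    return out


def estimate_loss(
    run_r: Run,
    run_r1: Run,
    delta: float,
    order: int,
    candidates,
    rel_tol: float = 1e-3,
    max_flank: int | None = None,
    exact: bool = False,
):
    """Resolve one loss: ``(best, profile, ambiguous)`` over the candidate set.

    ``candidates`` is a :class:`CandidateSet` or an iterable of integers.
    The argmin of the RMSE profile wins; ties (candidates within ``rel_tol``
    relative of the minimum, with a small absolute floor so a noiseless zero
    minimum still detects its aliases) are broken toward the candidate
    nearest the metadata centre, then toward the smaller gap, and flagged
    ``ambiguous``.  ``exact=True`` scores each candidate by the SVD path
    instead of the normal-equation fast path.
    """
    if isinstance(candidates, CandidateSet):
        members = candidates.members
        center = candidates.center
    else:
        members = np.asarray(sorted(int(c) for c in candidates))
        if members.size == 0 or members[0] < 1:
            raise ValueError("candidates must be a nonempty set of integers >= 1")
        center = int(members[(members.size - 1) // 2])

    if exact:
        scores = np.array(
            [joint_fit_score(run_r, run_r1, delta, order, int(d), max_flank) for d in members]
        )
    else:
        scores = score_profile(run_r, run_r1, delta, order, members, max_flank)
    profile = {int(d): float(s) for d, s in zip(members, scores)}
    if not np.isfinite(scores).any():
        raise RuntimeError("every candidate produced an unusable (infinite) score")

    smin = float(np.nanmin(np.where(np.isfinite(scores), scores, np.nan)))
    # Near-ties (within rel_tol relative, with a small absolute floor so a
    # noiseless zero minimum still recognises its aliases) are broken toward
    # the candidate nearest the metadata estimate, then the smaller gap.
    data_rms = float(
        np.sqrt(np.mean(np.concatenate([run_r.values, run_r1.values]) ** 2))
    )
    # the absolute floor must exceed the numerical noise of a zero rss
    # (cancellation error ~ sqrt(machine eps) times the data scale)
    threshold = smin * (1.0 + rel_tol) + 1e-6 * max(data_rms, 1.0)
    eligible = scores <= threshold
    pref = np.lexsort((members, np.abs(members - center)))
    best = int(members[pref[np.nonzero(eligible[pref])[0][0]]])
    ambiguous = bool(int(eligible.sum()) > 1)
    return best, profile, ambiguous


def resolve_all(
    timeline: RecordingTimeline,
    delta: float,
    order: int,
    uncertainty: int | None = None,
    rel_tol: float = 1e-3,
    max_flank: int | None = None,
) -> RecordingTimeline:
    """Resolve every loss in the timeline in place (and return it).

    Each loss is resolved independently from its two flanking runs, with a
    candidate window of half-width ``uncertainty`` (or the loss's own
    ``uncertainty`` field when ``uncertainty`` is None) around its initial
    estimate.  Per-loss failures are logged and leave that loss unresolved;
    the timeline's ``resolved`` flag is set only if every loss resolved.
    Run origins are updated cumulatively from the resolved sizes.
    """
    all_ok = True
    for loss in timeline.losses:
        u = loss.uncertainty if uncertainty is None else int(uncertainty)
        cands = CandidateSet(center=loss.initial_estimate, halfwidth=u)
        try:
            best, profile, ambiguous = estimate_loss(
                timeline.runs[loss.after_run],
                timeline.runs[loss.after_run + 1],
                delta,
                order,
                cands,
                rel_tol=rel_tol,
                max_flank=max_flank,
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("loss after run %d left unresolved: %s", loss.after_run, exc)
            all_ok = False
            continue
        loss.resolved = best
        loss.score_profile = profile
        loss.ambiguous = ambiguous
        loss.uncertainty = u
    timeline.resolved = all_ok
    timeline.update_global_starts()
    return timeline


ConsolidationReport = namedtuple(
    "ConsolidationReport", ["residual_sd", "phases", "values", "model"]
)


def consolidation_report(
    timeline: RecordingTimeline, delta: float, order: int
) -> ConsolidationReport:
    """Diagnostic: overlay every sample on one stimulation cycle.

    With the losses resolved, all samples sit on one global grid; folding
    their times modulo δ should collapse them onto the artifact waveform.
    Fits a single harmonic model to the full recording and returns the
    residual standard deviation plus the fold coordinates for plotting.
    A residual sd close to the stimulation-off noise level indicates the
    losses were accounted for correctly.
    """
    if not timeline.resolved:
        raise ValueError("timeline is unresolved; run resolve_all first")
    times = np.concatenate([r.global_times for r in timeline.runs])
    values = np.concatenate([r.values for r in timeline.runs])
    model, _, residual_sd = fit_harmonic(times, values, delta, order)
    return ConsolidationReport(
        residual_sd=residual_sd,
        phases=phase_fold(times, delta),
        values=values,
        model=model,
    )
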