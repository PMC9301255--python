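"""Model/Results interface tying the pipeline together.

:class:`PELP` is built from a packet stream (or an already-decomposed
timeline); :meth:`PELP.fit` estimates the stimulation period, selects the
harmonic order by AIC on the longest run, resolves every loss, and returns a
:class:`PELPResults` carrying the estimates, per-loss score profiles,
ambiguity flags and consolidation diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, harmonics, packets, period

__all__ = ["PELP", "PELPResults"]

SCHEMA_VERSION = "1"


class PELP:
    """Loss-size estimation model for a stimulation-on recording.

    Parameters
    ----------
    timeline : RecordingTimeline
        Run/loss decomposition of the recording (see
        :func:`pelp.packets.detect_losses`).
    stim_freq : float
        Nominal stimulation frequency, Hz; the period search is centred on
        ``fs / stim_freq``.
    uncertainty : int
        Half-width of the candidate window around each loss's metadata
        estimate, samples.
    order : int or "auto"
        Number of artifact harmonics; "auto" selects by AIC on the longest
        run (searching 1..max_order).

    Examples
    --------
    >>> tl = packets.detect_losses(packets.read_packets("stream.csv"), fs=1000)
    >>> res = PELP(tl, stim_freq=150.6, uncertainty=5).fit()
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(
        self,
        timeline: packets.RecordingTimeline,
        stim_freq: float,
        uncertainty: int = 5,
        order: int | str = "auto",
        max_order: int = 10,
        period_config: period.PeriodSearchConfig | None = None,
        max_flank: int | None = None,
        rel_tol: float = 1e-3,
    ) -> None:
        if uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        self.timeline = timeline
        self.fs = timeline.fs
        self.stim_freq = float(stim_freq)
        self.uncertainty = int(uncertainty)
        self.order = order
        self.max_order = int(max_order)
        self.max_flank = max_flank
        self.rel_tol = rel_tol
        self.period_config = period_config or period.PeriodSearchConfig(
            nominal_delta=self.fs / self.stim_freq
        )

    @classmethod
    def from_packets(cls, pkts, fs: float, stim_freq: float, **kwargs) -> "PELP":
        return cls(packets.detect_losses(pkts, fs), stim_freq, **kwargs)

    @classmethod
    def from_file(cls, path, fs: float, stim_freq: float, **kwargs) -> "PELP":
        return cls.from_packets(packets.read_packets(path), fs, stim_freq, **kwargs)

    def fit(self, delta: float | None = None) -> "PELPResults":
        """Estimate δ (unless given), pick the order, resolve all losses."""
        tl = self.timeline
        if delta is None:
            delta = period.estimate_period(tl.runs, self.period_config)
        if self.order == "auto":
            longest = max(tl.runs, key=lambda r: r.length)
            order = harmonics.select_order_aic(
                longest.times, longest.values, delta, self.max_order
            )
        else:
            order = int(self.order)
        if tl.losses:
            core.resolve_all(
                tl,
                delta,
                order,
                uncertainty=self.uncertainty,
                rel_tol=self.rel_tol,
                max_flank=self.max_flank,
            )
        else:
            tl.resolved = True
        report = core.consolidation_report(tl, delta, order) if tl.resolved else None
        return PELPResults(model=self, delta=float(delta), order=order,
                           timeline=tl, consolidation=report)


@dataclass
class PELPResults:
    """Fitted loss-size estimates and diagnostics."""

    model: PELP
    delta: float
    order: int
    timeline: packets.RecordingTimeline
    consolidation: core.ConsolidationReport | None = None

    @property
    def residual_sd(self) -> float | None:
        return None if self.consolidation is None else self.consolidation.residual_sd

    @property
    def n_ambiguous(self) -> int:
        return sum(l.ambiguous for l in self.timeline.losses)

    @property
    def loss_table(self) -> pd.DataFrame:
        """One row per loss: estimate, resolution, minimum RMSE, ambiguity."""
        rows = []
        for i, l in enumerate(self.timeline.losses):
            rows.append(
                {
                    "loss": i,
                    "after_run": l.after_run,
                    "initial_estimate": l.initial_estimate,
                    "uncertainty": l.uncertainty,
                    "resolved": l.resolved,
                    "rmse": min(l.score_profile.values()) if l.score_profile else np.nan,
                    "ambiguous": l.ambiguous,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "loss",
                "after_run",
                "initial_estimate",
                "uncertainty",
                "resolved",
                "rmse",
                "ambiguous",
            ],
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        tl = self.timeline
        lines = [
            "Periodic Estimation of Lost Packets",
            "=" * 51,
            f"Sampling rate          {tl.fs:12.1f} Hz",
            f"Stimulation period     {self.delta:12.6f} samples"
            f"  ({tl.fs / self.delta:.3f} Hz)",
            f"Harmonics (order)      {self.order:12d}",
            f"Runs / losses          {len(tl.runs):6d} / {len(tl.losses):d}",
            f"Resolved               {sum(l.resolved is not None for l in tl.losses):12d}",
            f"Ambiguous              {self.n_ambiguous:12d}",
        ]
        if self.residual_sd is not None:
            lines.append(f"Consolidation resid sd {self.residual_sd:12.3f} uV")
        lines.append("-" * 51)
        table = self.loss_table
        if len(table):
            lines.append(table.to_string(index=False, max_rows=40))
        else:
            lines.append("(no losses)")
        return "\n".join(lines)

    def to_report(self, path=None) -> dict:
        """Machine-readable report (per-loss profiles, δ̂, order, residual sd)."""
        obj = {
            "schema_version": SCHEMA_VERSION,
            "fs": self.timeline.fs,
            "delta": self.delta,
            "order": self.order,
            "residual_sd": self.residual_sd,
            "resolved": self.timeline.resolved,
            "losses": [
                {
                    "after_run": l.after_run,
                    "initial_estimate": l.initial_estimate,
                    "uncertainty": l.uncertainty,
                    "resolved": l.resolved,
                    "ambiguous": l.ambiguous,
                    "score_profile": {str(k): v for k, v in l.score_profile.items()},
                }
                for l in self.timeline.losses
            ],
        }
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=1)
        return obj

    def plot_consolidation(self, ax=None):
        """Phase-folded samples overlaid on the fitted artifact waveform."""
        import matplotlib.pyplot as plt

        if self.consolidation is None:
            raise ValueError("no consolidation report (timeline unresolved)")
        if ax is None:
            _, ax = plt.subplots()
        rep = self.consolidation
        ax.plot(rep.phases, rep.values, ".", ms=2, color="0.6", label="samples")
        grid = np.linspace(0, self.delta, 400, endpoint=False)
        ax.plot(grid, harmonics.evaluate(rep.model, grid), lw=2, label="artifact model")
        ax.set_xlabel("time mod period (samples)")
        ax.set_ylabel("amplitude (uV)")
        ax.legend(frameon=False)
        return ax
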