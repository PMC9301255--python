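"""Periodic stimulation-artifact model: a truncated Fourier series.

Regular electrical stimulation imprints a deterministic, δ-periodic artifact
on the recording (δ = sampling rate / stimulation frequency, in samples,
generally non-integer).  The artifact is modelled as

    f_beta(t) = b1 + sum_{j=1..M} b_{2j} sin(2 pi j t / δ)
                   + sum_{j=1..M} b_{2j+1} cos(2 pi j t / δ)

fitted by linear least squares under homoscedastic Gaussian noise.  The
number of harmonics M is chosen by AIC on the longest run of contiguous
samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HarmonicModel",
    "design_matrix",
    "fit_harmonic",
    "evaluate",
    "select_order_aic",
    "phase_fold",
]


@dataclass
class HarmonicModel:
    """Fitted δ-periodic artifact waveform.

    ``beta`` has length ``2 * order + 1``: intercept, then (sin, cos) pairs
    for harmonics 1..order.  ``delta`` is in samples; ``fs`` (Hz) is carried
    only to convert to physical time when needed.
    """

    delta: float
    order: int
    beta: np.ndarray
    fs: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not self.delta > 1:
            raise ValueError("delta must exceed 1 sample")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.beta.size != 2 * self.order + 1:
            raise ValueError(
                f"beta has length {self.beta.size}, expected {2 * self.order + 1}"
            )

    def __call__(self, times) -> np.ndarray:
        return evaluate(self, times)

    @property
    def rms(self) -> float:
        """Root-mean-square amplitude of the waveform over one period."""
        t = np.linspace(0.0, self.delta, 4096, endpoint=False)
        return float(np.sqrt(np.mean(evaluate(self, t) ** 2)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "delta": self.delta,
                "order": self.order,
                "beta": self.beta.tolist(),
                "fs": self.fs,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HarmonicModel":
        obj = json.loads(text)
        return cls(
            delta=obj["delta"],
            order=obj["order"],
            beta=np.asarray(obj["beta"], dtype=float),
            fs=obj.get("fs"),
        )


def design_matrix(times, delta: float, order: int) -> np.ndarray:
    """Harmonic regression design: [1, sin(2πjt/δ), cos(2πjt/δ)] for j=1..order."""
    if not delta > 1:
        raise ValueError("delta must exceed 1 sample")
    if order < 1:
        raise ValueError("order must be >= 1")
    # On an integer sample grid, harmonic j appears at the aliased frequency
    # ±j/δ (mod 1) cycles/sample.  Columns go near-singular when two aliased
    # harmonics coincide, or one lands on 0 or 1/2 (sin column vanishes);
    # merely exceeding the Nyquist rate is harmless for non-integer δ.
    f = np.arange(1, order + 1) / delta
    folded = np.abs(((f + 0.5) % 1.0) - 0.5)  # distance to nearest integer
    clash = np.abs(folded[:, None] - folded[None, :])
    np.fill_diagonal(clash, 1.0)
    if (
        np.any(folded < 1e-6)
        or np.any(np.abs(folded - 0.5) < 1e-6)
        or np.any(clash < 1e-6)
    ):
        warnings.warn(
            f"aliased harmonic frequencies nearly coincide for order {order} "
            f"at delta={delta:g}; design columns may be near-singular",
            stacklevel=2,
        )
    t = np.asarray(times, dtype=float)
    X = np.empty((t.size, 2 * order + 1))
    X[:, 0] = 1.0
    base = 2.0 * np.pi / delta * t
    for j in range(1, order + 1):
        X[:, 2 * j - 1] = np.sin(j * base)
        X[:, 2 * j] = np.cos(j * base)
    return X


def fit_harmonic(times, values, delta: float, order: int):
    """Least-squares harmonic fit; returns ``(model, rss, residual_sd)``.

    Solved via SVD (:func:`numpy.linalg.lstsq`), which tolerates the
    near-collinear columns that arise at high order; a genuinely
    rank-deficient design (e.g. all times congruent mod δ) raises.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    p = 2 * order + 1
    if t.size < p + 1:
        raise ValueError(f"need at least {p + 1} samples to fit order {order}")
    X = design_matrix(t, delta, order)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient harmonic design (rank {rank} < {p}); "
            "times may all be congruent modulo delta"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = max(t.size - p, 1)
    residual_sd = float(np.sqrt(rss / dof))
    return HarmonicModel(delta=delta, order=order, beta=beta), rss, residual_sd


def evaluate(model: HarmonicModel, times) -> np.ndarray:
    """Evaluate f_beta at the given times (samples); exactly δ-periodic."""
    return design_matrix(times, model.delta, model.order) @ model.beta


def select_order_aic(times, values, delta: float, max_order: int = 10) -> int:
    """Pick the harmonic count M in 1..max_order minimising AIC.

    Gaussian likelihood: AIC(M) = n ln(rss/n) + 2 (2M + 2); the parameter
    count is the intercept, 2M trig coefficients and the noise variance.
    Ties and near-zero rss favour the smaller model.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = t.size
    # Floor rss at the numerical noise of the fit itself, so that for a
    # noiseless signal every adequate order ties and the penalty decides.
    rss_floor = n * (1e-10 * max(float(np.sqrt(np.mean(y**2))), 1e-30)) ** 2
    best_m, best_aic = None, np.inf
    for M in range(1, max_order + 1):
        try:
            _, rss, _ = fit_harmonic(t, y, delta, M)
        except (ValueError, np.linalg.LinAlgError):
            continue
        aic = n * np.log(max(rss, rss_floor) / n) + 2 * (2 * M + 2)
        if aic < best_aic:
            best_m, best_aic = M, aic
    if best_m is None:
        raise np.linalg.LinAlgError("every candidate order was rank-deficient")
    return best_m


def phase_fold(times, delta: float) -> np.ndarray:
    """Map times onto a single stimulation cycle: elementwise ``times mod delta``."""
    if not delta > 0:
        raise ValueError("delta must be positive")
    return np.mod(np.asarray(times, dtype=float), delta)
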