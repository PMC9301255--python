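# Methods

## Problem

Bidirectional implanted neurostimulators (e.g. the Medtronic Summit RC+S)
stream local field potentials wirelessly in packets of consecutive samples.
Packets are lost in transit, and the per-packet timing metadata — a sequence
counter modulo 256, a 0.1 ms fine clock tick modulo 65536 (6.5536 s), a 1 s
coarse timestamp and a ±50 ms receiver wall clock — is not accurate enough to
reconstruct the gap sizes down to the sample. Without sample-exact gaps, the
time axis of the reconstructed recording is wrong, which corrupts
trial-locked analyses and filtering.

When therapeutic stimulation is on, the recording carries a highly periodic
stimulation artifact. That artifact is a free, always-on timing reference:
the correct gap size is the one that keeps the artifact phase-continuous
across the loss. `pelp` implements this idea end to end.

## Model

The artifact is a δ-periodic truncated Fourier series on the sample grid,

    f_β(t) = β₁ + Σ_{j=1..M} β_{2j} sin(2πjt/δ) + β_{2j+1} cos(2πjt/δ),

with δ the stimulation period in samples (fs / stimulation frequency,
generally non-integer, ≈ 6.6401 at 1 kHz / 150.6 Hz), M the harmonic count,
and homoscedastic Gaussian noise around it. Within one run of contiguous
samples β is estimated by linear least squares (SVD; the design can be
near-collinear at high order).

**Loss resolution.** For the loss between runs r and r+1, each candidate
integer gap Δ places run r+1 at times n_r + Δ + t (0-based local times).
One *shared* β is fitted jointly to both runs, and

    Δ̂ = argmin_{Δ ∈ Ω} RMSE(joint fit at Δ).

Sharing β across the pair is what makes Δ identifiable; fitting each run its
own β would fit any shift equally well. Ω is the integer window
max(1, E−U) … E+U around the metadata estimate E, with U the stated
uncertainty (half-width; U = 0 means "trust the metadata"). Candidates that
differ by kδ with kδ near an integer are inherently indistinguishable
(aliasing); the smallest such distance for δ ≈ 6.64 is 7 (|δ−7| = 0.36), and
it tightens at 20 ≈ 3δ (off by 0.08). Near-ties within a relative tolerance
(default 1e-3, with an absolute floor of 1e-6 × the data rms so a noiseless
zero minimum still recognises its aliases) are reported as `ambiguous` and
broken toward the candidate nearest E (the metadata is unbiased within its
jitter), then toward the smaller gap.

Each loss uses only its two flanking runs, so resolution is pairwise-local
and order-independent. `max_flank` optionally truncates long flanking runs
to the samples nearest the loss, bounding the influence of slow drift within
a run; the default uses the full runs.

**Scoring fast path.** Shifting run r+1 by Δ only rotates each (sin, cos)
column pair of its design matrix through 2πjΔ/δ. The per-candidate normal
equations are therefore assembled from two fixed Gram matrices and a block
rotation, making the cost per candidate independent of run length.
`joint_fit_score` keeps a plain SVD least-squares implementation; tests pin
the fast profile to it and to a from-scratch oracle at 1e-8 relative. The
normal-equation route loses accuracy only when the residual is at machine
noise (cancellation ~√ε × data scale), which cannot affect the argmin.

**Period estimation.** δ is nominally known but device clocks err by enough
to matter, so it is re-estimated from data: the objective is the pooled
per-run least-squares residual (each run gets its own β — phase cannot be
assumed continuous across unresolved losses — but all share δ), using at
most the first 10⁴ samples of each run and excluding runs shorter than 10
periods (ill-conditioned phase). The search is two successive 101-point
grids — the first spanning nominal × (1 ± 1e-3) — followed by bounded scalar
minimisation to 1e-7 relative. A coarse-grid objective with two comparable
(within 5%) well-separated local minima raises rather than guessing.
Candidate periods where every fit is rank-deficient (an exactly-integer
period whose top harmonic vanishes on the integer grid) score +inf and are
skipped.

**Order selection.** M is chosen on the single longest run by AIC with
Gaussian likelihood, AIC(M) = n·ln(rss/n) + 2(2M+2); the parameter count
includes the intercept, 2M trig coefficients and the noise variance (the +1
shifts all models equally, so selection is unaffected). The rss is floored
at the fit's own numerical noise so that for noiseless signals all adequate
orders tie and the penalty picks the smallest. Default search range 1–10.
Note AIC is not consistent: it keeps a spurious harmonic with asymptotic
probability P(χ²₂ > 4) ≈ 13.5%; a slightly over-fitted artifact model is
harmless for gap resolution.

**Metadata arithmetic.** The initial gap estimate from fine ticks S₁, S₂
(last sample of the packets flanking the loss), m tick rollovers and the
following packet's sample count n is

    N = round((((S₂ − S₁) mod 65536) + 65536·m) · 10⁻⁴ s · fs) − n.

The elapsed seconds are multiplied by fs before subtracting the sample
count — the quantity is a number of samples, so dimensional consistency
requires the fs factor — and rounded to nearest (ties to even); one tick
(0.1 ms) is finer than a sample at ≤ 1 kHz so the rounding error is below a
sample. Beyond ~6 s the tick difference is ambiguous modulo 6.5536 s; m is
then inferred from the coarse clocks (receiver wall clock preferred, device
timestamp otherwise) as the value minimising |tick-implied − coarse| elapsed
time, with an error if the two coarse clocks disagree by more than 2 s.
A boundary is declared a loss when the sequence counter skips (mod 256),
when the tick-implied elapsed time disagrees with the next packet's sample
count by ≥ 0.5 samples, or when timestamp and tick elapsed times disagree by
more than a configurable tolerance (default 1 s — one timestamp quantum —
which catches losses of exactly 256 packets, invisible to the counter).

## Synthetic data

The generator emulates the conditions under which the method was
characterised; its defaults are those conditions, not tuning knobs:

- 66 s at fs = 1000 Hz; stimulation at 150.6 Hz (δ ≈ 6.6401 samples).
- Background: Gaussian 1/f noise (spectrally shaped white noise, DC
  removed), rms 4.55 μV — the stimulation-off noise level the artifact is
  judged against. Real EEG/LFP additionally has line noise, transients and
  nonstationarity; passing tests show robustness to broadband background,
  not to every recording pathology.
- Artifact: zero-mean 4-harmonic template with alternating-sign decaying
  coefficients (a sharp biphasic-pulse-like waveform), scaled so its rms is
  R × background rms. Per-cycle amplitude factors ~ Normal(1, V/100)
  (clipped at 0 with a warning), applied to whole cycles. Drift d (percent
  of a period per 1000 cycles) generates at period δ(1 + d·10⁻⁵) while
  resolution uses the undrifted δ — i.e. drift models period-estimation
  error.
- Dropout: 50-sample packets, 20% removed. "exact-fraction" removes
  round(0.2 × n_packets) uniformly without replacement (the sweep setting);
  "iid" removes each packet independently (gap lengths then geometric, mean
  packet_len/(1−p) = 62.5 samples at p = 0.2). Consecutive removed packets
  merge into one loss. Leading/trailing gaps have no flanking pair and are
  excluded from recovery scoring (but counted in gap statistics).
- Sweeps perturb each true gap by a uniform integer in [−U, U] to form the
  metadata estimate and search estimate ± U, so the truth is always in the
  window; U both displaces and widens Ω, which is what produces accuracy
  transitions near 2U crossing the aliasing distances (≈7, 13, 20 for
  δ ≈ 6.64).

Monte-Carlo problem sizes: the packaged sweeps default to 20 trials per
cell over reduced axis grids (5–15 cells per sweep), which gives 2–6 × 10⁴
scored losses per sweep — binomial standard errors well under a percentage
point at the ≈100% operating points.

## Numerical choices and degenerate inputs

- All least-squares solves that define results use SVD (`lstsq`); rank
  deficiency raises in `fit_harmonic`, scores +inf in candidate scoring.
- Collinearity warning: on an integer grid harmonic j appears at the
  aliased frequency ±j/δ mod 1; a warning fires when two aliased harmonics
  coincide or one lands on 0 or 1/2 cycles/sample (where a sin column
  vanishes), not merely when j/δ exceeds 1/2 — order 4 at δ ≈ 6.64 is well
  conditioned and is the intended operating point.
- Tick arithmetic is exact integer arithmetic up to the single final
  rounding; `estimate_loss_size` is invariant to adding 65536k to both
  ticks.
- Empty packet files parse to an empty list with a logged warning; replayed
  packets (duplicate seq with identical tick) and non-monotone timestamps
  are errors.
- `resolve_all` continues past per-loss failures, leaving those losses
  unresolved and the timeline flagged unresolved.

## Limitations

- Requires stimulation on and visible in-band; not applicable to
  stimulation-off segments or heavily low-pass-filtered artifacts.
- Assumes one constant period per recording; closed-loop (time-varying)
  stimulation is out of scope.
- Integer or near-integer periods (in samples) leave gaps identifiable only
  modulo the period; the package reports the ambiguity rather than
  resolving it.
- Drift within a single long run is not modelled; `max_flank` mitigates but
  does not remove it.
- The packet dialect is a simplified CSV/JSON schema, not the native
  session format of any particular device.
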