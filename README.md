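# pelp — periodic estimation of lost packets

Wireless bidirectional neurostimulators stream local field potentials to an
external receiver in packets, and packets get lost. The per-packet timing
metadata (a sequence counter mod 256, a 0.1 ms clock tick mod 6.5536 s, a
1 s timestamp, a ±50 ms wall clock) bounds each gap but cannot pin it down
to the sample, so the reconstructed time axis is wrong by a few samples at
every dropout — enough to corrupt trial-locked analyses and filtering.

When therapeutic stimulation is on, its artifact is a free timing reference.
`pelp` models the artifact as a δ-periodic harmonic series

    f_β(t) = β₁ + Σⱼ β₂ⱼ sin(2πjt/δ) + β₂ⱼ₊₁ cos(2πjt/δ),

estimates δ from the data (stagewise grid search on the pooled per-run
least-squares residual), picks the harmonic count by AIC, and then resolves
each loss by choosing the integer gap size Δ — inside a window around the
metadata estimate — that minimises the RMSE of a *single* harmonic fit
shared across the two flanking runs:

    Δ̂ = argmin_{Δ ∈ Ω} min_β [ Σₖ (y_{k,r} − f_β(t_{k,r}))²
                              + Σₖ (y_{k,r+1} − f_β(n_r + Δ + t_{k,r+1}))² ].

Candidates differing by a near-integer multiple of δ are inherently
indistinguishable; such ties are flagged as ambiguous rather than silently
resolved. The package is aimed at anyone cleaning streamed recordings from
implanted sensing devices (or similar telemetry) after the fact.

It ships the full workflow: packet-stream parsing and loss detection from
metadata, the harmonic model, period estimation, loss resolution and
consolidation diagnostics — plus a simulator that generates
stimulation-plus-noise recordings with packet dropout and reproduces the
Monte-Carlo accuracy characterisation of the method.

## Worked example

```python
import numpy as np, pelp
from pelp import simulate as sim

rng = np.random.default_rng(42)
spec = sim.StimulationSpec(ratio=2.0)            # artifact rms = 2 x background
n = 20000                                        # 20 s at 1 kHz
sig = sim.synth_background(n, seed=rng) + sim.synth_artifact(spec, n, seed=rng)
mask, _ = sim.drop_packets(n, sim.DropoutSpec(), seed=rng)   # 20% of 50-sample packets
pkts = sim.packets_from_signal(sig, mask, 1000.0, seed=rng)

res = pelp.PELP.from_packets(pkts, fs=1000.0, stim_freq=150.6, uncertainty=5).fit()
print(res.summary())
```

```
Periodic Estimation of Lost Packets
===================================================
Sampling rate                1000.0 Hz
Stimulation period         6.640068 samples  (150.601 Hz)
Harmonics (order)                 4
Runs / losses              68 / 67
Resolved                         67
Ambiguous                         0
Consolidation resid sd        4.511 uV
---------------------------------------------------
 loss  after_run  initial_estimate  uncertainty  resolved     rmse  ambiguous
    0          0                50            5        50 2.873670      False
    1          1               100            5       100 3.164169      False
    2          2                50            5        50 3.153717      False
    ...
```

The fitted period (6.640068 samples ≈ 150.601 Hz) recovers the generator's
clock to a few 1e-5 samples; all 67 dropouts are resolved, each `resolved`
column entry equalling the true number of missing samples; and the
consolidation residual sd (4.51 μV — every sample folded modulo δ and
compared against one artifact fit) matches the 4.55 μV background noise
injected by the simulator, the signature of a sample-exact reconstruction.
`res.plot_consolidation()` shows the folded overlay;
`res.to_report("report.json")` and `pelp.write_timeline(...)` export the
per-loss profiles and the reconstructed series.

The same workflow is available from a shell:

```sh
pelp simulate --duration 20 --seed 42 --out stream.csv --truth truth.json
pelp resolve --packets stream.csv --fs 1000 --stim-freq 150.6 \
     --uncertainty 5 --out timeline.csv --report report.json
pelp sweep --axis ratio --trials 20 --seed 7 --out sweep.json
```

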