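import numpy as np
import pytest

from pelp import HarmonicModel, Packet, Run, design_matrix

FS = 1000.0
STIM_FREQ = 150.6
DELTA = FS / STIM_FREQ  # ~6.6401 samples


def artifact_values(times, delta=DELTA, beta=None, order=4):
    """Reference artifact trace: truncated Fourier series at period delta."""
    if beta is None:
        beta = np.array([0.0, 10.0, 4.5, -7.0, -3.0, 4.5, 2.0, -2.5, -1.0])
    return design_matrix(np.asarray(times, float), delta, order) @ np.asarray(beta)


def split_with_gap(signal, n_left, gap, n_right, start=0):
    """Cut two flanking runs out of a continuous signal around a known gap."""
    a = start
    b = a + n_left
    c = b + gap
    d = c + n_right
    run_l = Run(values=signal[a:b], times=np.arange(n_left, dtype=float), global_start=a)
    run_r = Run(values=signal[c:d], times=np.arange(n_right, dtype=float), global_start=c)
    return run_l, run_r


def make_packets(signal, fs=FS, packet_len=50, drop=(), t0=0.0, gen_time=True):
    """Packetise a signal, omitting the packet indices in ``drop``."""
    packets = []
    n = len(signal)
    for k in range(0, n, packet_len):
        idx = k // packet_len
        if idx in drop:
            continue
        hi = min(k + packet_len, n)
        t_last = t0 + (hi - 1) / fs
        packets.append(
            Packet(
                seq=idx % 256,
                tick=int(round(t_last / 1e-4)) % 65536,
                tstamp=int(np.floor(t_last)),
                samples=np.asarray(signal[k:hi], float),
                channel="ch0",
                gen_time=t_last if gen_time else None,
            )
        )
    return packets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
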