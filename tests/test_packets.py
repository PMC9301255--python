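"""Packet parsing, loss detection and timing-metadata arithmetic."""

import numpy as np
import pytest

import pelp
from pelp.packets import (
    TICK_ROLLOVER_S,
    Packet,
    PacketError,
    detect_losses,
    estimate_loss_size,
    infer_rollovers,
    read_packets,
    write_packets,
    write_timeline,
)

from conftest import FS, make_packets


def three_packets():
    return [
        Packet(seq=5, tick=490, tstamp=0, samples=[1.0, -2.5, 3.25], gen_time=0.049),
        Packet(seq=6, tick=520, tstamp=0, samples=[0.5, 0.125, -9.0]),
        Packet(seq=7, tick=550, tstamp=0, samples=[4.0, 5.0, 6.0], channel="ch0"),
    ]


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_packet_io_round_trip(tmp_path, fmt):
    path = tmp_path / f"stream.{fmt}"
    original = three_packets()
    write_packets(original, path)
    back = read_packets(path)
    assert len(back) == 3
    for a, b in zip(original, back):
        assert (a.seq, a.tick, a.tstamp, a.channel) == (b.seq, b.tick, b.tstamp, b.channel)
        np.testing.assert_allclose(b.samples, a.samples, rtol=1e-9)
        if a.gen_time is None:
            assert b.gen_time is None
        else:
            assert b.gen_time == pytest.approx(a.gen_time, rel=1e-12)


def test_read_empty_file_warns(tmp_path, caplog):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with caplog.at_level("WARNING"):
        assert read_packets(path) == []
    assert "empty" in caplog.text


def test_out_of_range_tick_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("seq,tick,tstamp,gen_time,channel,samples\n1,70000,0,,ch0,1.0\n")
    with pytest.raises(PacketError):
        read_packets(path)


def test_malformed_row_names_location(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("seq,tick,tstamp,gen_time,channel,samples\n1,xx,0,,ch0,1.0\n")
    with pytest.raises(PacketError, match="line 2"):
        read_packets(path)


def test_packet_invariants():
    with pytest.raises(PacketError):
        Packet(seq=300, tick=0, tstamp=0, samples=[1.0])
    with pytest.raises(PacketError):
        Packet(seq=0, tick=0, tstamp=0, samples=[])


# ---------------------------------------------------------------------------
# loss detection
# ---------------------------------------------------------------------------


def test_seq_skip_is_a_loss():
    sig = np.arange(200.0)
    packets = make_packets(sig, packet_len=50, drop={2})  # seq 0,1,3
    tl = detect_losses(packets, FS)
    assert len(tl.runs) == 2
    assert len(tl.losses) == 1
    assert tl.losses[0].after_run == 0
    assert tl.losses[0].initial_estimate == 50


def test_contiguous_packets_make_one_run():
    sig = np.arange(500.0)
    tl = detect_losses(make_packets(sig, packet_len=50), FS)
    assert len(tl.runs) == 1 and not tl.losses
    np.testing.assert_array_equal(tl.runs[0].values, sig)


def test_seq_rollover_is_not_a_loss():
    # brute-force every mod-256 boundary: consecutive packets with consistent
    # ticks must merge into one run whatever the counter value
    for start_seq in range(256):
        packets = []
        for i in range(3):
            t_last = (start_seq + i) * 50 / FS + 49 / FS
            packets.append(
                Packet(
                    seq=(start_seq + i) % 256,
                    tick=int(round(t_last * 1e4)) % 65536,
                    tstamp=int(t_last),
                    samples=np.zeros(50),
                )
            )
        tl = detect_losses(packets, FS)
        assert len(tl.runs) == 1, f"spurious loss at seq {start_seq}"


def test_whole_seq_rollover_loss_caught_by_timestamp():
    # exactly 256 packets lost: seq is consistent, only coarse time betrays it
    sig = np.arange((256 + 4) * 50, dtype=float)
    drop = set(range(2, 258))
    packets = make_packets(sig, packet_len=50, drop=drop)
    assert packets[2].seq == packets[1].seq + 1  # the skip is invisible to seq
    tl = detect_losses(packets, FS)
    assert len(tl.losses) == 1
    assert tl.losses[0].initial_estimate == 256 * 50


def test_detected_boundaries_match_simulator_mask(rng):
    from pelp import DropoutSpec, drop_packets, runs_from_mask

    n = 20000
    sig = rng.standard_normal(n)
    mask, _ = drop_packets(n, DropoutSpec(), seed=rng)
    drop = {k for k in range(n // 50) if not mask[k * 50]}
    tl = detect_losses(make_packets(sig, packet_len=50, drop=drop), FS)
    runs, gaps = runs_from_mask(sig, mask)
    assert len(tl.runs) == len(runs)
    assert [l.initial_estimate for l in tl.losses] == gaps
    for a, b in zip(tl.runs, runs):
        np.testing.assert_array_equal(a.values, b.values)


def test_replayed_packet_rejected():
    p = three_packets()
    with pytest.raises(PacketError, match="replayed"):
        detect_losses([p[0], p[1], p[1]], FS)


def test_non_monotone_timestamp_rejected():
    a = Packet(seq=0, tick=0, tstamp=5, samples=[1.0])
    b = Packet(seq=1, tick=500, tstamp=4, samples=[1.0])
    with pytest.raises(PacketError, match="tstamp"):
        detect_losses([a, b], FS)


# ---------------------------------------------------------------------------
# tick arithmetic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "s1,s2,m,n_after,fs,expected",
    [
        (1000, 3000, 0, 50, 1000.0, 150),  # 2000 ticks = 0.2 s
        (65036, 500, 0, 50, 1000.0, 50),  # tick rollover: 1000 ticks = 0.1 s
        (0, 0, 1, 250, 250.0, 1388),  # 6.5536 s * 250 Hz = 1638.4 -> 1638
    ],
)
def test_estimate_loss_size_examples(s1, s2, m, n_after, fs, expected):
    # independent elapsed-time oracle for the same inputs
    elapsed = (((s2 - s1) % 65536) + 65536 * m) * 1e-4
    assert expected == round(elapsed * fs) - n_after
    assert estimate_loss_size(s1, s2, m, n_after, fs) == expected


def test_estimate_loss_size_tick_shift_invariance(rng):
    for _ in range(200):
        s1 = int(rng.integers(0, 65536))
        s2 = int(rng.integers(0, 65536))
        m = int(rng.integers(0, 3))
        base = estimate_loss_size(s1, s2, m, 10, 1000.0)
        k = int(rng.integers(1, 5))
        shifted = estimate_loss_size(s1 + 65536 * k, s2 + 65536 * k, m, 10, 1000.0)
        assert shifted == base


def test_estimate_loss_size_negative_is_error():
    with pytest.raises(PacketError):
        estimate_loss_size(1000, 1100, 0, 50, 1000.0)


def test_infer_rollovers_examples():
    assert infer_rollovers(0, 2) == 0
    # brute-force oracle: m minimising |tick-implied - coarse| elapsed time
    for coarse, tick_el in [(7.0, 0.45), (13.2, 0.1), (2.0, 2.0), (26.0, 0.2)]:
        want = min(range(10), key=lambda m: abs(tick_el + TICK_ROLLOVER_S * m - coarse))
        got = infer_rollovers(0, int(coarse), 100.0, 100.0 + coarse, tick_elapsed=tick_el)
        assert got == want
    assert infer_rollovers(0, 7, tick_elapsed=0.45) == 1
    assert infer_rollovers(0, 13, 50.0, 63.2) == 2


def test_infer_rollovers_inconsistent_clocks():
    with pytest.raises(PacketError, match="disagree"):
        infer_rollovers(0, 20, 100.0, 107.0)


def test_long_loss_rollover_recovered_via_coarse_clock():
    # a ~13.1 s dropout at 250 Hz spans two tick rollovers; exact metadata
    # must still produce the exact initial estimate
    fs = 250.0
    n = 30 * 250
    sig = np.arange(n, dtype=float)
    packet_len = 50
    gap_packets = range(3, 3 + 66)  # 66 * 50 / 250 Hz = 13.2 s
    packets = make_packets(sig, fs=fs, packet_len=packet_len, drop=set(gap_packets))
    tl = detect_losses(packets, fs)
    assert len(tl.losses) == 1
    assert tl.losses[0].rollovers == 2
    assert tl.losses[0].initial_estimate == 66 * 50


def test_initial_estimates_exact_for_sub_6s_losses(rng):
    sig = rng.standard_normal(40000)
    drop = {4, 5, 6, 40, 100, 101, 500, 700, 701, 702, 703}
    tl = detect_losses(make_packets(sig, packet_len=50, drop=drop), FS)
    assert [l.initial_estimate for l in tl.losses] == [150, 50, 100, 50, 200]


# ---------------------------------------------------------------------------
# timeline export
# ---------------------------------------------------------------------------


def resolved_two_run_timeline(gap=5):
    runs = [
        pelp.Run(values=np.arange(10.0), times=np.arange(10.0), global_start=0),
        pelp.Run(values=np.arange(10.0), times=np.arange(10.0), global_start=10 + gap),
    ]
    loss = pelp.LossRecord(after_run=0, initial_estimate=gap, resolved=gap)
    return pelp.RecordingTimeline(fs=FS, runs=runs, losses=[loss], resolved=True)


def test_write_timeline_nan_policy(tmp_path):
    path = tmp_path / "tl.csv"
    write_timeline(resolved_two_run_timeline(), path, gap_policy="nan")
    frame = pelp.read_timeline(path)
    assert len(frame) == 25
    assert frame["value"].isna().sum() == 5
    assert frame["value"][10:15].isna().all()


def test_write_timeline_omit_policy(tmp_path):
    path = tmp_path / "tl.csv"
    write_timeline(resolved_two_run_timeline(), path, gap_policy="omit-with-index")
    frame = pelp.read_timeline(path)
    assert len(frame) == 20
    assert frame["index"].tolist() == list(range(10)) + list(range(15, 25))


def test_write_timeline_zero_loss_identity(tmp_path):
    sig = np.sin(np.arange(100.0))
    tl = detect_losses(make_packets(sig, packet_len=50), FS)
    tl.resolved = True
    path = tmp_path / "tl.csv"
    write_timeline(tl, path, gap_policy="nan")
    frame = pelp.read_timeline(path)
    np.testing.assert_allclose(frame["value"].to_numpy(), sig, rtol=1e-9)


def test_write_timeline_requires_resolution(tmp_path):
    tl = resolved_two_run_timeline()
    tl.resolved = False
    with pytest.raises(ValueError, match="unresolved"):
        write_timeline(tl, tmp_path / "x.csv")
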