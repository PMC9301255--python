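"""Packet streams, loss detection, and the run/loss decomposition.

Wireless bidirectional neurostimulators (the Medtronic Summit RC+S is the
motivating device) transmit samples in packets carrying three integer timing
variables: a sequence counter (``seq``, modulo 256), a fine device clock tick
(``tick``, 0.1 ms resolution, modulo 65536 i.e. every 6.5536 s) stamped on the
last sample of the packet, and a coarse 1 s ``tstamp`` with no rollover.  An
optional receiver-side wall-clock estimate (``gen_time``, accurate to roughly
±50 ms) helps disambiguate tick rollovers across long dropouts.

This module parses packet files, detects dropouts from the metadata, and
decomposes the recording into runs of contiguous samples separated by losses
of initially-uncertain size.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TICK_RESOLUTION_S = 1e-4
TICK_MODULUS = 65536
TICK_ROLLOVER_S = TICK_MODULUS * TICK_RESOLUTION_S  # 6.5536 s
SEQ_MODULUS = 256

__all__ = [
    "Packet",
    "Run",
    "LossRecord",
    "RecordingTimeline",
    "PacketError",
    "read_packets",
    "write_packets",
    "detect_losses",
    "estimate_loss_size",
    "infer_rollovers",
    "write_timeline",
    "read_timeline",
]


class PacketError(ValueError):
    """Malformed or inconsistent packet data."""


@dataclass
class Packet:
    """One transmitted unit: consecutive samples plus timing metadata.

    Parameters
    ----------
    seq : int
        Packet sequence counter, 0-255, rolls over every 256 packets.
    tick : int
        Fine clock of the *last* sample in the packet, units of 0.1 ms,
        0-65535 (rolls over every 6.5536 s).
    tstamp : int
        Coarse device timestamp in whole seconds; no rollover.
    samples : numpy.ndarray
        Recorded amplitudes in microvolts, in acquisition order.
    channel : str
        Channel identifier.
    gen_time : float or None
        Receiver-side wall-clock estimate of packet generation, seconds
        (coarse: about ±50 ms).
    """

    seq: int
    tick: int
    tstamp: int
    samples: np.ndarray
    channel: str = "ch0"
    gen_time: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise PacketError("packet has no samples")
        if not 0 <= int(self.seq) < SEQ_MODULUS:
            raise PacketError(f"seq {self.seq} outside 0-255")
        if not 0 <= int(self.tick) < TICK_MODULUS:
            raise PacketError(f"tick {self.tick} outside 0-65535")
        if self.tstamp < 0:
            raise PacketError(f"tstamp {self.tstamp} negative")
        self.seq = int(self.seq)
        self.tick = int(self.tick)
        self.tstamp = int(self.tstamp)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class Run:
    """A maximal stretch of contiguous received samples between two losses."""

    values: np.ndarray
    times: np.ndarray  # sample times relative to run start (0, 1, ..., n-1)
    global_start: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("run times must be strictly increasing")
        if self.global_start < 0:
            raise ValueError("global_start must be >= 0")

    @property
    def length(self) -> int:
        return int(self.values.size)

    @property
    def global_times(self) -> np.ndarray:
        return self.global_start + self.times


@dataclass
class LossRecord:
    """One dropout between run ``after_run`` and the following run."""

    after_run: int
    initial_estimate: int
    rollovers: int = 0
    uncertainty: int = 0
    resolved: int | None = None
    ambiguous: bool = False
    score_profile: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_estimate < 1:
            raise ValueError("initial_estimate must be >= 1")
        if self.rollovers < 0 or self.uncertainty < 0:
            raise ValueError("rollovers and uncertainty must be >= 0")

    @property
    def size(self) -> int:
        """Best available loss size: resolved if present, else the estimate."""
        return self.resolved if self.resolved is not None else self.initial_estimate


@dataclass
class RecordingTimeline:
    """Runs and the losses between them, on one reconstructed sample grid."""

    fs: float
    runs: list[Run]
    losses: list[LossRecord]
    resolved: bool = False

    def __post_init__(self) -> None:
        if len(self.losses) != max(len(self.runs) - 1, 0):
            raise ValueError("need exactly one loss between each adjacent run pair")

    @property
    def n_received(self) -> int:
        return sum(r.length for r in self.runs)

    def update_global_starts(self) -> None:
        """Recompute run origins cumulatively from the current loss sizes."""
        pos = self.runs[0].global_start if self.runs else 0
        for r, run in enumerate(self.runs):
            run.global_start = pos
            pos += run.length
            if r < len(self.losses):
                pos += self.losses[r].size


def estimate_loss_size(s1: int, s2: int, m: int, n_after: int, fs: float) -> int:
    """Number of samples lost between two packets, from fine-clock ticks.

    ``s1``/``s2`` are the ticks of the packets flanking the loss (each stamps
    the *last* sample of its packet), ``m`` is the number of 6.5536 s tick
    rollovers spanned, and ``n_after`` the sample count of the packet after
    the loss.  The tick difference measures last-sample to last-sample, so the
    following packet's own samples are subtracted:

        N = round((((s2 - s1) mod 65536) + 65536 m) * 1e-4 * fs) - n_after

    Rounding is to nearest (ties to even); at sampling rates of 1 kHz or
    below one tick (0.1 ms) is finer than one sample, so the rounding error
    is under a sample.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not (0 <= s1 < TICK_MODULUS and 0 <= s2 < TICK_MODULUS):
        # tolerate un-wrapped ticks: only their difference matters
        pass
    if m < 0:
        raise ValueError("rollover count m must be >= 0")
    elapsed_s = (((s2 - s1) % TICK_MODULUS) + TICK_MODULUS * m) * TICK_RESOLUTION_S
    n = round(elapsed_s * fs) - int(n_after)
    if n < 0:
        raise PacketError(
            f"tick arithmetic gives {n} lost samples (< 0); metadata inconsistent"
        )
    return int(n)


def infer_rollovers(
    tstamp1: int,
    tstamp2: int,
    gen_time1: float | None = None,
    gen_time2: float | None = None,
    tick_elapsed: float = 0.0,
    tolerance_s: float = 2.0,
) -> int:
    """Count of 6.5536 s tick rollovers consistent with the coarse clocks.

    Prefers the receiver wall clock (``gen_time``, ±50 ms) when both flanking
    packets carry it, else the 1 s device timestamp.  ``tick_elapsed`` is the
    sub-rollover elapsed time implied by the tick difference (seconds); the
    returned ``m`` minimises ``|tick_elapsed + 6.5536 m - coarse elapsed|``.
    """
    ts_elapsed = float(tstamp2 - tstamp1)
    if gen_time1 is not None and gen_time2 is not None:
        gen_elapsed = float(gen_time2 - gen_time1)
        if abs(gen_elapsed - ts_elapsed) > tolerance_s:
            raise PacketError(
                "coarse clocks disagree: gen_time elapsed "
                f"{gen_elapsed:.3f} s vs timestamp elapsed {ts_elapsed:.3f} s"
            )
        coarse = gen_elapsed
    else:
        coarse = ts_elapsed
    m = round((coarse - tick_elapsed) / TICK_ROLLOVER_S)
    return max(0, int(m))


def _contiguous(p1: Packet, p2: Packet, fs: float, tstamp_tol_s: float) -> bool:
    """True when p2 follows p1 with no samples missing in between."""
    seq_ok = p2.seq == (p1.seq + 1) % SEQ_MODULUS
    if not seq_ok:
        return False
    tick_elapsed = ((p2.tick - p1.tick) % TICK_MODULUS) * TICK_RESOLUTION_S
    # contiguity requires the tick-implied elapsed time to match p2's length
    tick_ok = abs(tick_elapsed * fs - p2.n_samples) < 0.5
    # guard against exactly-256-packet losses: seq matches but coarse time jumps
    ts_ok = abs((p2.tstamp - p1.tstamp) - tick_elapsed) <= tstamp_tol_s
    return tick_ok and ts_ok


def detect_losses(
    packets: list[Packet],
    fs: float,
    tstamp_tolerance_s: float = 1.0,
    rollover_threshold_s: float = 6.0,
) -> RecordingTimeline:
    """Group packets into runs and record a loss at every dropout boundary.

    A loss is declared when the sequence counter skips (mod 256) or when the
    tick-implied elapsed time disagrees with the sample count of the next
    packet.  Each loss gets an initial size estimate from tick arithmetic
    (:func:`estimate_loss_size`); when the coarse elapsed time exceeds
    ``rollover_threshold_s`` the rollover count is inferred from the coarse
    clocks first (:func:`infer_rollovers`), since a single tick difference is
    ambiguous beyond 6.5536 s.

    The returned timeline is *unresolved*: initial estimates position the
    runs provisionally until the loss sizes are pinned down against the
    stimulation artifact.
    """
    if not packets:
        raise PacketError("no packets given")
    channels = {p.channel for p in packets}
    if len(channels) > 1:
        raise PacketError(f"multiple channels in one stream: {sorted(channels)}")
    for a, b in zip(packets, packets[1:]):
        if b.tstamp < a.tstamp:
            raise PacketError(
                f"non-monotone tstamp: {a.tstamp} then {b.tstamp}"
            )
        if b.seq == a.seq and b.tick == a.tick:
            raise PacketError(f"replayed packet (seq={b.seq}, tick={b.tick})")

    runs: list[Run] = []
    losses: list[LossRecord] = []
    chunk: list[np.ndarray] = [packets[0].samples]

    def close_run() -> None:
        values = np.concatenate(chunk)
        runs.append(Run(values=values, times=np.arange(values.size, dtype=float)))

    for p1, p2 in zip(packets, packets[1:]):
        if _contiguous(p1, p2, fs, tstamp_tolerance_s):
            chunk.append(p2.samples)
            continue
        close_run()
        chunk = [p2.samples]
        coarse_elapsed = float(p2.tstamp - p1.tstamp)
        m = 0
        if coarse_elapsed > rollover_threshold_s:
            tick_elapsed = ((p2.tick - p1.tick) % TICK_MODULUS) * TICK_RESOLUTION_S
            m = infer_rollovers(
                p1.tstamp, p2.tstamp, p1.gen_time, p2.gen_time, tick_elapsed
            )
        n = estimate_loss_size(p1.tick, p2.tick, m, p2.n_samples, fs)
        losses.append(
            LossRecord(after_run=len(runs) - 1, initial_estimate=max(n, 1), rollovers=m)
        )
    close_run()

    timeline = RecordingTimeline(fs=float(fs), runs=runs, losses=losses)
    timeline.update_global_starts()
    return timeline


# ---------------------------------------------------------------------------
# I/O: packet CSV/JSON dialect and timeline export
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["seq", "tick", "tstamp", "gen_time", "channel", "samples"]


def _packet_from_record(rec: dict, where: str) -> Packet:
    try:
        samples = rec["samples"]
        if isinstance(samples, str):
            samples = [float(v) for v in samples.split(";") if v != ""]
        gen = rec.get("gen_time")
        if gen in (None, ""):
            gen = None
        else:
            gen = float(gen)
        return Packet(
            seq=int(rec["seq"]),
            tick=int(rec["tick"]),
            tstamp=int(rec["tstamp"]),
            samples=np.asarray(samples, dtype=float),
            channel=str(rec.get("channel") or "ch0"),
            gen_time=gen,
        )
    except PacketError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise PacketError(f"malformed packet at {where}: {exc}") from exc


def read_packets(path, format_name: str | None = None) -> list[Packet]:
    """Read a packet stream from the CSV or JSON dialect.

    CSV: header ``seq,tick,tstamp,gen_time,channel,samples`` with ``samples``
    a ``;``-separated list of decimal microvolt values.  JSON: an array of
    objects with the same keys.  ``format_name`` may be ``"csv"`` or
    ``"json"``; by default it is inferred from the file extension.
    """
    path = str(path)
    if format_name is None:
        format_name = "json" if path.lower().endswith(".json") else "csv"
    packets: list[Packet] = []
    if format_name == "json":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        if not text.strip():
            logger.warning("empty packet file: %s", path)
            return []
        records = json.loads(text)
        for i, rec in enumerate(records):
            packets.append(_packet_from_record(rec, f"{path} item {i}"))
    elif format_name == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                logger.warning("empty packet file: %s", path)
                return []
            missing = set(_CSV_FIELDS) - set(reader.fieldnames)
            if missing:
                raise PacketError(f"{path}: missing columns {sorted(missing)}")
            for row in reader:
                packets.append(_packet_from_record(row, f"{path} line {reader.line_num}"))
    else:
        raise ValueError(f"unknown format {format_name!r} (use 'csv' or 'json')")
    if not packets:
        logger.warning("packet file %s contained no packets", path)
    return packets


def write_packets(packets: list[Packet], path, format_name: str | None = None) -> None:
    """Write packets in the CSV or JSON dialect (inverse of :func:`read_packets`)."""
    path = str(path)
    if format_name is None:
        format_name = "json" if path.lower().endswith(".json") else "csv"
    if format_name == "json":
        records = [
            {
                "seq": p.seq,
                "tick": p.tick,
                "tstamp": p.tstamp,
                "gen_time": p.gen_time,
                "channel": p.channel,
                "samples": [float(v) for v in p.samples],
            }
            for p in packets
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh)
    elif format_name == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(_CSV_FIELDS)
            for p in packets:
                writer.writerow(
                    [
                        p.seq,
                        p.tick,
                        p.tstamp,
                        "" if p.gen_time is None else repr(float(p.gen_time)),
                        p.channel,
                        ";".join(repr(float(v)) for v in p.samples),
                    ]
                )
    else:
        raise ValueError(f"unknown format {format_name!r} (use 'csv' or 'json')")


def write_timeline(timeline: RecordingTimeline, path, gap_policy: str = "nan") -> None:
    """Export a resolved timeline as a single continuous series.

    CSV columns ``index,time_s,value`` where ``index`` is the global sample
    index.  ``gap_policy="nan"`` emits one row per grid sample with an empty
    value inside gaps; ``"omit-with-index"`` emits only received samples (the
    gap is visible as a jump in ``index``).
    """
    import pandas as pd

    if not timeline.resolved:
        raise ValueError("timeline is unresolved; resolve losses before export")
    if gap_policy not in ("nan", "omit-with-index"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    idx = np.concatenate(
        [r.global_start + np.arange(r.length) for r in timeline.runs]
    ).astype(int)
    val = np.concatenate([r.values for r in timeline.runs])
    if gap_policy == "nan":
        n_total = int(idx[-1]) + 1
        full = np.full(n_total, np.nan)
        full[idx] = val
        idx = np.arange(n_total)
        val = full
    frame = pd.DataFrame(
        {"index": idx, "time_s": idx / timeline.fs, "value": val}
    )
    frame.to_csv(path, index=False, na_rep="", lineterminator="\n")


def read_timeline(path):
    """Read a timeline CSV written by :func:`write_timeline` (gaps become NaN)."""
    import pandas as pd

    return pd.read_csv(path)
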