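"""Deterministic pulse-time models of the stimulation schedules.

Theta-burst stimulation delivers 50-Hz triplet bursts every 200 ms (5 Hz):
continuously for 40 s (cTBS, 200 bursts) or in intermittent 2-s-on/8-s-off
trains (iTBS, 20 trains of 10 bursts), 600 pulses at 80% resting motor
threshold either way. The 20-Hz protocol (and its 10%-RMT sham) delivers
2-s trains at 20 Hz with 28 s off over 20 minutes. This module only models
the schedules — pulse times and session metadata — not hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CTBS = "cTBS"
ITBS = "iTBS"
RTMS20 = "rTMS20"
SHAM = "sham"

PROTOCOLS = (CTBS, ITBS, RTMS20, SHAM)


@dataclass(frozen=True)
class PulseSchedule:
    """A protocol's full pulse-onset sequence plus its defining parameters."""

    protocol: str
    pulse_times_s: tuple[float, ...]
    burst_size: int
    intra_burst_hz: float
    burst_rate_hz: float
    train_on_s: float  # 0 for one continuous train
    train_off_s: float
    intensity_pct_rmt: float
    n_trains: int = field(default=1)

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times_s)
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    @property
    def pulse_count(self) -> int:
        return len(self.pulse_times_s)

    @property
    def n_bursts(self) -> int:
        return self.pulse_count // self.burst_size if self.burst_size else 0


def _burst(onset: float, size: int, hz: float) -> list[float]:
    return [onset + j / hz for j in range(size)]


def build_schedule(protocol: str) -> PulseSchedule:
    """Construct the pulse schedule for a named protocol.

    cTBS: 200 consecutive bursts 0.2 s apart, 3 pulses per burst at 50 Hz
    (600 pulses, 40 s, 80% RMT). iTBS: 20 trains every 10 s, 10 bursts per
    2-s train (600 pulses, 80% RMT). rTMS20/sham: 40 pulses per 2-s 20-Hz
    train, 28 s off, 20-minute protocol; sham at 10% RMT.
    """
    if protocol in (CTBS,):
        times = [t for b in range(200) for t in _burst(0.2 * b, 3, 50.0)]
        return PulseSchedule(
            protocol=CTBS,
            pulse_times_s=tuple(times),
            burst_size=3,
            intra_burst_hz=50.0,
            burst_rate_hz=5.0,
            train_on_s=0.0,
            train_off_s=0.0,
            intensity_pct_rmt=80.0,
            n_trains=1,
        )
    if protocol == ITBS:
        times = [
            t
            for tr in range(20)
            for b in range(10)
            for t in _burst(10.0 * tr + 0.2 * b, 3, 50.0)
        ]
        return PulseSchedule(
            protocol=ITBS,
            pulse_times_s=tuple(times),
            burst_size=3,
            intra_burst_hz=50.0,
            burst_rate_hz=5.0,
            train_on_s=2.0,
            train_off_s=8.0,
            intensity_pct_rmt=80.0,
            n_trains=20,
        )
    if protocol in (RTMS20, SHAM):
        times = [
            30.0 * tr + j / 20.0 for tr in range(40) for j in range(40)
        ]  # 40 trains in 20 min
        return PulseSchedule(
            protocol=protocol,
            pulse_times_s=tuple(times),
            burst_size=1,
            intra_burst_hz=20.0,
            burst_rate_hz=20.0,
            train_on_s=2.0,
            train_off_s=28.0,
            intensity_pct_rmt=10.0 if protocol == SHAM else 80.0,
            n_trains=40,
        )
    raise ValueError(f"unknown protocol {protocol!r}")


def schedule_summary(s: PulseSchedule) -> dict:
    """Headline numbers of a schedule.

    ``nominal_duration_s`` is the continuous-train length (bursts / burst
    rate) for continuous protocols, and last-train onset + train length for
    intermittent ones. ``last_train_onset_s`` follows the train-spacing
    convention (n_trains - 1 periods), the figure usually printed for iTBS
    (19 x 10 s = 190 s).
    """
    if s.pulse_count == 0:
        return {
            "pulse_count": 0,
            "n_bursts": 0,
            "n_trains": 0,
            "nominal_duration_s": 0.0,
            "last_train_onset_s": 0.0,
        }
    if s.train_on_s == 0:  # continuous
        nominal = s.n_bursts / s.burst_rate_hz
        last_onset = 0.0
    else:
        period = s.train_on_s + s.train_off_s
        last_onset = (s.n_trains - 1) * period
        nominal = last_onset + s.train_on_s
    return {
        "pulse_count": s.pulse_count,
        "n_bursts": s.n_bursts,
        "n_trains": s.n_trains,
        "nominal_duration_s": float(nominal),
        "last_train_onset_s": float(last_onset),
    }


def schedule_to_tsv(s: PulseSchedule) -> str:
    """Two-column TSV export: pulse index, onset time in seconds."""
    lines = ["pulse\ttime_s"]
    lines += [f"{i}\t{t:.6f}" for i, t in enumerate(s.pulse_times_s)]
    return "\n".join(lines) + "\n"
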