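"""Surface-EMG processing for the mirror-biofeedback protocol.

Signal chain: zero-phase band-pass (Butterworth, default 20-450 Hz, order
4) -> full-wave rectification -> moving RMS (default 100 ms window, 50 ms
step).  The gesture protocol is fixed: kiss, smile, eyebrow raise, each
held 5 s with 10 s of rest in between; per-gesture, per-muscle activation
is summarized as the maximum of the RMS envelope within the gesture cycle,
reported in mV and additionally on a x1000 integer scale (the microvolt
dialect used in clinical maxima tables).

A synthetic generator produces protocol-shaped recordings with programmed
activation amplitudes and a synkinesis coupling matrix (involuntary
co-activation of muscles not intended for the gesture), for testing the
chain end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError

__all__ = [
    "MUSCLES", "GESTURES", "PROTOCOL_HOLD_S", "PROTOCOL_REST_S",
    "EmgRecording", "GestureCycle", "EmgSummary", "ChainOptions",
    "bandpass", "rectify", "moving_rms", "segment_protocol", "summarize",
    "EmgSpec", "generate_emg", "load_emg_csv", "save_emg_csv",
]

MUSCLES = ("orbicularis", "buccinator", "frontalis")
GESTURES = ("kiss", "smile", "eyebrows")
PROTOCOL_HOLD_S = 5.0
PROTOCOL_REST_S = 10.0


@dataclass
class EmgRecording:
    """Multi-channel EMG time series in millivolts at a fixed sample rate."""

    samples: np.ndarray  # (channels, time)
    rate: float = 1000.0
    channel_names: tuple[str, ...] = MUSCLES
    resolution_bits: int = 16

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ParameterError("sample rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ParameterError("channel_names must match the sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


@dataclass(frozen=True)
class GestureCycle:
    """Half-open sample interval [start_sample, end_sample) of one gesture."""

    gesture: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ParameterError("cycle must have positive length")


@dataclass
class EnvelopeSeries:
    """Moving-RMS envelope: frame center times (s) and per-channel values."""

    times_s: np.ndarray
    values: np.ndarray  # (channels, frames)
    channel_names: tuple[str, ...]


@dataclass(frozen=True)
class ChainOptions:
    """Processing-chain parameters (conventional surface-EMG defaults)."""

    band_low_hz: float = 20.0
    band_high_hz: float = 450.0
    filter_order: int = 4
    rms_window_s: float = 0.100
    rms_step_s: float = 0.050
    raw_max: bool = False  # report raw rectified maxima instead of envelope maxima


@dataclass
class EmgSummary:
    """Per-gesture, per-muscle activation maxima for one condition."""

    condition: str  # "without" | "with" (biofeedback)
    values_mV: dict[tuple[str, str], float]  # (gesture, muscle) -> mV

    def scaled(self, gesture: str, muscle: str) -> int:
        """Value on the x1000 integer scale (round-half-up)."""
        return scale_x1000(self.values_mV[(gesture, muscle)])


def scale_x1000(value_mV: float) -> int:
    return int(Decimal(value_mV * 1000.0).quantize(0, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# chain stages
# ---------------------------------------------------------------------------

def bandpass(
    rec: EmgRecording, low_hz: float = 20.0, high_hz: float = 450.0, order: int = 4
) -> EmgRecording:
    """Zero-phase Butterworth band-pass (forward-backward), per channel."""
    nyq = rec.rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = butter(order, [low_hz, high_hz], btype="band", fs=rec.rate, output="sos")
    filtered = sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def rectify(rec: EmgRecording) -> EmgRecording:
    """Full-wave rectification (elementwise absolute value)."""
    return replace(rec, samples=np.abs(rec.samples))


def moving_rms(
    rec: EmgRecording, window_s: float = 0.100, step_s: float = 0.050
) -> EnvelopeSeries:
    """Sliding-window root mean square per channel.

    Windows are ``window_s`` long, advanced by ``step_s``; each output frame
    is stamped at its window center.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    if step_s <= 0 or step_s > window_s:
        raise ParameterError("need 0 < step_s <= window_s")
    win = int(round(window_s * rec.rate))
    step = max(1, int(round(step_s * rec.rate)))
    if win > rec.n_samples:
        raise ParameterError("window longer than the recording")
    sq = rec.samples**2
    starts = np.arange(0, rec.n_samples - win + 1, step)
    # cumulative sum for exact window means
    csum = np.concatenate(
        [np.zeros((sq.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1
    )
    means = (csum[:, starts + win] - csum[:, starts]) / win
    values = np.sqrt(np.maximum(means, 0.0))
    times = (starts + (win - 1) / 2.0) / rec.rate
    return EnvelopeSeries(times_s=times, values=values, channel_names=rec.channel_names)


def segment_protocol(rec: EmgRecording, t0_s: float = 0.0) -> list[GestureCycle]:
    """Gesture cycles of the fixed protocol, in samples at the recording rate.

    Gesture k (kiss, smile, eyebrows) occupies
    ``[t0 + 15 k, t0 + 15 k + 5)`` seconds: a 5 s hold followed by 10 s of
    rest.  Boundaries are exact integer sample indices; intervals are
    half-open and non-overlapping.
    """
    period = PROTOCOL_HOLD_S + PROTOCOL_REST_S
    needed = t0_s + period * (len(GESTURES) - 1) + PROTOCOL_HOLD_S
    if rec.duration_s < needed:
        raise ParameterError(
            f"recording of {rec.duration_s:g} s too short for the protocol "
            f"({needed:g} s needed)"
        )
    cycles = []
    for k, gesture in enumerate(GESTURES):
        start = t0_s + period * k
        cycles.append(
            GestureCycle(
                gesture=gesture,
                start_sample=int(round(start * rec.rate)),
                end_sample=int(round((start + PROTOCOL_HOLD_S) * rec.rate)),
            )
        )
    return cycles


def summarize(
    rec: EmgRecording,
    cycles: list[GestureCycle],
    options: ChainOptions = ChainOptions(),
    condition: str = "without",
) -> EmgSummary:
    """Run the full chain and take per-cycle, per-muscle maxima.

    The chain is band-pass -> rectify -> moving RMS; the reported maximum is
    the largest envelope frame whose window center falls inside the cycle
    (or the raw rectified maximum when ``options.raw_max``).
    """
    filtered = rectify(
        bandpass(rec, options.band_low_hz, options.band_high_hz, options.filter_order)
    )
    values: dict[tuple[str, str], float] = {}
    if options.raw_max:
        for cyc in cycles:
            seg = filtered.samples[:, cyc.start_sample:cyc.end_sample]
            if seg.shape[1] == 0:
                raise ParameterError(f"empty cycle {cyc}")
            for ci, name in enumerate(rec.channel_names):
                values[(cyc.gesture, name)] = float(seg[ci].max())
        return EmgSummary(condition=condition, values_mV=values)
    env = moving_rms(filtered, options.rms_window_s, options.rms_step_s)
    for cyc in cycles:
        t_lo = cyc.start_sample / rec.rate
        t_hi = cyc.end_sample / rec.rate
        mask = (env.times_s >= t_lo) & (env.times_s < t_hi)
        if not np.any(mask):
            raise ParameterError(f"cycle {cyc} contains no envelope frames")
        for ci, name in enumerate(rec.channel_names):
            values[(cyc.gesture, name)] = float(env.values[ci, mask].max())
    return EmgSummary(condition=condition, values_mV=values)


# ---------------------------------------------------------------------------
# synthetic recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmgSpec:
    """Programmed activations for a synthetic protocol recording.

    ``amplitudes[gesture][muscle]`` is the target activation in mV on the
    sine-amplitude scale: the RMS-envelope plateau reads amplitude/sqrt(2),
    as it would for a sinusoid of that amplitude.  ``coupling[s, t]`` mixes
    the carrier of source muscle s into target channel t (diagonal 1 =
    no synkinesis); off-diagonal entries emulate involuntary co-activation.
    """

    amplitudes: Mapping[str, Mapping[str, float]]
    coupling: np.ndarray | None = None  # (3, 3), source x target
    t0_s: float = 2.0
    tail_s: float = 3.0
    ramp_s: float = 0.5
    baseline_noise_mV: float = 0.0005  # RMS of the resting noise floor

    def coupling_matrix(self) -> np.ndarray:
        if self.coupling is None:
            return np.eye(len(MUSCLES))
        c = np.asarray(self.coupling, float)
        if c.shape != (len(MUSCLES), len(MUSCLES)):
            raise ParameterError("coupling must be 3x3 (source x target)")
        if np.any(c < 0) or np.any(c > 1):
            raise ParameterError("coupling entries must be in [0, 1]")
        return c

    def amplitude(self, gesture: str, muscle: str) -> float:
        a = float(self.amplitudes.get(gesture, {}).get(muscle, 0.0))
        if a < 0:
            raise ParameterError("amplitudes must be >= 0")
        return a


def _trapezoid(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((stop - t) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


_CARRIER_GRID_HZ = 10.0  # tone spacing; 1 / (100 ms RMS window)


def _multisine_carrier(
    rng: np.random.Generator, n: int, rate: float, channel_index: int
) -> np.ndarray:
    """Random-phase multisine with exactly unit 100 ms windowed RMS.

    Tones sit on a 10 Hz grid inside the 50-250 Hz band where surface-EMG
    power concentrates, so every 100 ms window holds whole periods of every
    tone and of every tone-difference — the windowed RMS is exactly 1
    regardless of window placement, and a programmed envelope is recovered
    by the analysis chain without the upward bias a max statistic takes on
    fluctuating local power.  Channels use disjoint tone subsets (grid
    index mod channel count), so cross-talk mixtures add in quadrature.
    """
    top = min(250.0, 0.45 * rate)
    grid = np.arange(5, int(top / _CARRIER_GRID_HZ) + 1)
    grid = grid[grid % len(MUSCLES) == channel_index % len(MUSCLES)]
    if len(grid) == 0:
        raise ParameterError("sample rate too low for the carrier tone grid")
    freqs = grid * _CARRIER_GRID_HZ
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    t = np.arange(n) / rate
    amp = np.sqrt(2.0 / len(freqs))
    return amp * np.sum(
        np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
    )


def generate_emg(
    spec: EmgSpec, rate: float = 1000.0, seed: int = 0
) -> tuple[EmgRecording, dict[tuple[str, str], float]]:
    """Synthesize a protocol recording; returns it with the expected
    per-(gesture, muscle) RMS-envelope peaks in mV as ground truth.

    Each muscle's source signal is a random-phase multisine carrier with
    exactly unit windowed RMS (see :func:`_multisine_carrier`) scaled by
    amplitude/sqrt(2) and a trapezoidal hold envelope on the protocol
    schedule; channels are mixed by the coupling matrix (disjoint tone
    grids add in quadrature) and a small Gaussian noise floor is added.
    Same spec, rate and seed give identical output.
    """
    period = PROTOCOL_HOLD_S + PROTOCOL_REST_S
    duration = spec.t0_s + period * (len(GESTURES) - 1) + PROTOCOL_HOLD_S + spec.tail_s
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    sources = np.zeros((len(MUSCLES), n))
    for si, muscle in enumerate(MUSCLES):
        carrier = _multisine_carrier(rng, n, rate, si)
        env = np.zeros(n)
        for k, gesture in enumerate(GESTURES):
            start = spec.t0_s + period * k
            amp = spec.amplitude(gesture, muscle)
            env += amp * _trapezoid(t, start, start + PROTOCOL_HOLD_S, spec.ramp_s)
        sources[si] = (env / np.sqrt(2.0)) * carrier

    coupling = spec.coupling_matrix()
    mixed = coupling.T @ sources
    mixed += spec.baseline_noise_mV * rng.standard_normal(mixed.shape)

    expected: dict[tuple[str, str], float] = {}
    for gesture in GESTURES:
        for ti, target in enumerate(MUSCLES):
            contributions = [
                coupling[si, ti] * spec.amplitude(gesture, src) / np.sqrt(2.0)
                for si, src in enumerate(MUSCLES)
            ]
            expected[(gesture, target)] = float(np.sqrt(np.sum(np.square(contributions))))

    rec = EmgRecording(samples=mixed, rate=rate, channel_names=MUSCLES)
    return rec, expected


# ---------------------------------------------------------------------------
# CSV I/O: header "time_s,orbicularis,buccinator,frontalis", values in mV
# ---------------------------------------------------------------------------

def save_emg_csv(rec: EmgRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.rate
    df = pd.DataFrame({"time_s": t})
    for name, ch in zip(rec.channel_names, rec.samples):
        df[name] = ch
    df.to_csv(path, index=False, float_format="%.6g")


def load_emg_csv(path: str | Path) -> EmgRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df) < 2:
        raise ParameterError("EMG CSV needs a time_s column and >= 2 rows")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("EMG CSV must be uniformly sampled")
    rate = 1.0 / dt[0]
    names = tuple(c for c in df.columns if c != "time_s")
    samples = df[list(names)].to_numpy(float).T
    return EmgRecording(samples=samples, rate=float(round(rate, 6)), channel_names=names)
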