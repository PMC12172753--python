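"""Stimulation-locked EMG processing: filtering, MEP detection, hotspot, RMT.

The classification chain mirrors standard navigated-TMS practice: the raw
trace is high-pass filtered at 30 Hz with a 2nd-order bidirectional
(zero-phase) Butterworth filter, the baseline standard deviation is taken
from the 200 ms preceding the stimulus, and the peak-to-peak amplitude in
the post-stimulus response window is accepted as a motor-evoked potential
(MEP) when it exceeds twenty times the baseline SD while staying below the
10 mV artifact ceiling.

The resting motor threshold (RMT) is the lowest stimulator intensity at
which the MEP amplitude exceeds 50 uV in at least five out of ten pulses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EMGTrace",
    "MEPResult",
    "RMTResult",
    "highpass_filter",
    "baseline_sd",
    "detect_mep",
    "find_hotspot",
    "estimate_rmt",
    "MEP_THRESHOLD_FACTOR",
    "ARTIFACT_CEILING_UV",
    "RMT_AMPLITUDE_UV",
]

MEP_THRESHOLD_FACTOR = 20.0  # p2p must exceed 20 x baseline SD
ARTIFACT_CEILING_UV = 10_000.0  # 10 mV upper bound (artifact rejection)
RMT_AMPLITUDE_UV = 50.0
RMT_MIN_SUCCESSES = 5
RMT_TRIALS_PER_INTENSITY = 10


class EMGError(ValueError):
    pass


class NoThresholdError(EMGError):
    """No tested intensity satisfied the RMT rule."""


@dataclass
class EMGTrace:
    """A stimulation-locked EMG sweep.

    ``t0_s`` is the time of the first sample relative to the stimulus
    (negative = pre-stimulus). For MEP classification the trace must
    cover the 200 ms pre-stimulus baseline and the response window.
    """

    samples: np.ndarray
    rate_hz: float
    t0_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise EMGError("rate_hz must be positive")
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise EMGError("trace needs at least 2 samples")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.rate_hz

    def window(self, start_s: float, stop_s: float) -> np.ndarray:
        """Samples with time in [start_s, stop_s)."""
        t = self.times_s
        return self.samples[(t >= start_s) & (t < stop_s)]


@dataclass
class MEPResult:
    p2p_uv: float
    baseline_sd_uv: float
    is_mep: bool
    reason: str  # "ok" | "below_threshold" | "artifact_too_large"

    def __post_init__(self) -> None:
        if self.p2p_uv < 0 or self.baseline_sd_uv < 0:
            raise EMGError("amplitudes must be non-negative")
        if self.is_mep and self.reason != "ok":
            raise EMGError("an accepted MEP must have reason 'ok'")


@dataclass
class RMTResult:
    rmt_intensity: float
    per_intensity_counts: dict  # intensity -> (n_above_50uv, n_total)


def highpass_filter(trace: EMGTrace, cutoff_hz: float = 30.0, order: int = 2) -> EMGTrace:
    """Zero-phase (forward-backward) Butterworth high-pass filter.

    Same length and rate out; phase distortion cancels because the filter
    runs once forward and once backward. Traces shorter than the reflective
    padding requirement are rejected rather than zero-padded.
    """
    if trace.rate_hz <= 2 * cutoff_hz:
        raise EMGError("sampling rate must exceed twice the cutoff")
    b, a = signal.butter(order, cutoff_hz, btype="highpass", fs=trace.rate_hz)
    padlen = 3 * max(len(a), len(b))
    if len(trace.samples) <= padlen:
        raise EMGError(f"trace too short for zero-phase filtering (need > {padlen} samples)")
    filtered = signal.filtfilt(b, a, trace.samples, padlen=padlen)
    return EMGTrace(filtered, trace.rate_hz, trace.t0_s)


def baseline_sd(trace: EMGTrace, window_ms: float = 200.0) -> float:
    """Population SD of the pre-stimulus baseline window [-window_ms, 0)."""
    start = -window_ms / 1000.0
    if trace.t0_s > start + 1e-12:
        raise EMGError("trace does not cover the pre-stimulus baseline window")
    seg = trace.window(start, 0.0)
    if len(seg) == 0:
        raise EMGError("no samples in baseline window")
    return float(np.std(seg))


def detect_mep(
    trace: EMGTrace,
    response_window_ms: tuple[float, float] = (15.0, 50.0),
    baseline_window_ms: float = 200.0,
    threshold_factor: float = MEP_THRESHOLD_FACTOR,
    artifact_ceiling_uv: float = ARTIFACT_CEILING_UV,
) -> MEPResult:
    """Classify one (already filtered) trace as MEP / non-MEP.

    ``p2p`` is max minus min inside the response window. The pulse is an
    MEP iff ``p2p > threshold_factor * baseline_sd`` and
    ``p2p < artifact_ceiling_uv`` (strict on both sides). When the
    amplitude violates both rules the artifact ceiling takes precedence
    in ``reason``.
    """
    lo, hi = (w / 1000.0 for w in response_window_ms)
    t = trace.times_s
    if trace.t0_s > lo or t[-1] < hi - 1.0 / trace.rate_hz:
        raise EMGError("response window outside trace")
    seg = trace.window(lo, hi)
    if len(seg) == 0:
        raise EMGError("no samples in response window")
    p2p = float(seg.max() - seg.min())
    sd = baseline_sd(trace, baseline_window_ms)
    if p2p >= artifact_ceiling_uv:
        return MEPResult(p2p, sd, False, "artifact_too_large")
    if p2p <= threshold_factor * sd:
        return MEPResult(p2p, sd, False, "below_threshold")
    return MEPResult(p2p, sd, True, "ok")


def find_hotspot(events_with_results: Sequence[tuple]) -> object:
    """Event with the largest peak-to-peak amplitude; ties -> lowest index."""
    if len(events_with_results) == 0:
        raise EMGError("cannot find a hotspot among zero events")
    amplitudes = np.array([res.p2p_uv for _, res in events_with_results])
    best = int(np.argmax(amplitudes))
    return events_with_results[best][0]


def estimate_rmt(trials: Mapping[float, Sequence[float]]) -> RMTResult:
    """RMT: lowest intensity with >= 5 of 10 amplitudes above 50 uV.

    ``trials`` maps stimulator intensity to exactly ten MEP amplitudes (uV).
    """
    if not trials:
        raise EMGError("no intensities tested")
    counts: dict = {}
    for intensity in sorted(trials):
        amps = np.asarray(trials[intensity], dtype=float)
        if len(amps) != RMT_TRIALS_PER_INTENSITY:
            raise EMGError(
                f"intensity {intensity}: expected {RMT_TRIALS_PER_INTENSITY} trials, got {len(amps)}"
            )
        counts[intensity] = (int(np.sum(amps > RMT_AMPLITUDE_UV)), len(amps))
    for intensity in sorted(counts):
        n_above, _ = counts[intensity]
        if n_above >= RMT_MIN_SUCCESSES:
            return RMTResult(intensity, counts)
    raise NoThresholdError("no intensity reached 50 uV in five of ten stimulations")
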