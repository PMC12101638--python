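"""Automatic pulse-cycle segmentation of bruit recordings.

A cycle is one cardiac pulse of the bruit. The bruit is loud during
ejection and quiet between beats, so the smoothed amplitude envelope is
periodic at the pulse rate: cycle onsets are envelope troughs between
successive envelope peaks (trough-to-trough, onset-aligned, so that the
cycle start precedes the ejection peak — the convention TMP depends on).
Detection is amplitude-scale invariant: all thresholds are relative to
the envelope's own level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .audio import AudioRecording

logger = logging.getLogger(__name__)

#: Onset = last point before a peak still within this fraction of the
#: trough-to-peak swing above the trough minimum (foot of the rising
#: edge; small enough to sit at the very start of the rise, large
#: enough to stay clear of the noise ripple on the quiet plateau).
ONSET_THRESHOLD_FRAC = 0.03


class NoCyclesDetectedError(RuntimeError):
    """Raised when no periodic pulse structure is found in the envelope."""


def _onset(env: np.ndarray, left_peak: int, right_peak: int) -> int:
    """Cycle onset between two envelope peaks.

    The quiet phase between beats is a near-flat plateau whose exact
    minimum is noise-driven, so a bare argmin jitters (and shifts under
    resampling). Instead, anchor the onset to the end of the plateau:
    the last point before the next peak at which the envelope is still
    within ONSET_THRESHOLD_FRAC of the trough-to-peak swing above the
    minimum. That is the foot of the rising edge — the acoustic start
    of the cycle.
    """
    span = env[left_peak:right_peak + 1]
    m = span.min()
    threshold = m + ONSET_THRESHOLD_FRAC * (env[right_peak] - m)
    below = np.nonzero(span <= threshold)[0]
    return int(left_peak + below[-1])


@dataclass(frozen=True)
class SegmentationConfig:
    """Envelope smoothing and physiologic constraints.

    Rate bounds are in beats/minute and bracket plausible hemodialysis
    patient heart rates; cycle durations must fall in
    [60/max_rate, 60/min_rate] seconds.
    """

    envelope_smoothing: float = 0.02  # seconds of moving-RMS window
    min_rate: float = 40.0
    max_rate: float = 140.0
    n_cycles_to_select: int = 3
    # peaks must rise by at least this fraction of the envelope maximum
    peak_prominence_frac: float = 0.25
    # envelope must dip below this fraction of its maximum somewhere:
    # a pulsatile bruit is near-silent between beats, stationary noise
    # never is
    max_depth_frac: float = 0.5

    def __post_init__(self) -> None:
        if not self.min_rate < self.max_rate:
            raise ValueError("min_rate must be below max_rate")
        if self.n_cycles_to_select < 1:
            raise ValueError("n_cycles_to_select must be >= 1")
        if self.envelope_smoothing <= 0:
            raise ValueError("envelope_smoothing must be positive")


@dataclass(frozen=True)
class CycleSegment:
    """One pulse cycle as a half-open sample interval [start, end)."""

    start_sample: int
    end_sample: int
    sample_rate: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("require 0 <= start_sample < end_sample")

    @property
    def duration(self) -> float:
        return (self.end_sample - self.start_sample) / self.sample_rate

    def extract(self, recording: AudioRecording) -> np.ndarray:
        return recording.samples[self.start_sample:self.end_sample]


def compute_envelope(recording: AudioRecording,
                     config: SegmentationConfig | None = None) -> np.ndarray:
    """Smoothed amplitude envelope (moving RMS) at the recording's time base."""
    if config is None:
        config = SegmentationConfig()
    if len(recording.samples) == 0:
        raise ValueError("empty recording")
    window = max(1, int(round(config.envelope_smoothing * recording.sample_rate)))
    return np.sqrt(uniform_filter1d(recording.samples**2, size=window, mode="nearest"))


def detect_cycles(envelope: np.ndarray, sample_rate: int,
                  config: SegmentationConfig | None = None) -> list[CycleSegment]:
    """Segment the envelope into trough-to-trough pulse cycles.

    Peaks are constrained to the configured rate band; onsets are the
    envelope minima between successive peaks (plus the minima before the
    first and after the last peak, so a recording of k clean cycles
    yields about k segments). Segments whose duration falls outside the
    physiologic band are discarded.

    Raises
    ------
    NoCyclesDetectedError
        If fewer than two sufficiently prominent peaks exist (e.g.
        unmodulated noise).
    """
    if config is None:
        config = SegmentationConfig()
    env = np.asarray(envelope, dtype=np.float64)
    peak_level = env.max() if env.size else 0.0
    if peak_level <= 0:
        raise NoCyclesDetectedError("silent envelope")
    if env.min() > config.max_depth_frac * peak_level:
        raise NoCyclesDetectedError(
            "no cycles detected: envelope never drops below "
            f"{config.max_depth_frac:.0%} of its peak (no pulsatile modulation)"
        )
    min_distance = max(1, int(sample_rate * 60.0 / config.max_rate))
    peaks, _ = find_peaks(env, distance=min_distance,
                          prominence=config.peak_prominence_frac * peak_level)
    if len(peaks) < 2:
        raise NoCyclesDetectedError(
            f"no cycles detected: {len(peaks)} prominent envelope peak(s); "
            "expected a periodic pulse envelope"
        )
    onsets = [_onset(env, 0, peaks[0])]
    for a, b in zip(peaks[:-1], peaks[1:]):
        onsets.append(_onset(env, a, b))
    # only complete cycles (onset to next onset) are emitted; the tail
    # after the last peak has no following onset to close it

    lo, hi = 60.0 / config.max_rate, 60.0 / config.min_rate
    segments = []
    for s, e in zip(onsets[:-1], onsets[1:]):
        if s < e and lo <= (e - s) / sample_rate <= hi:
            segments.append(CycleSegment(s, e, sample_rate))
    return segments


def select_cycles(segments: list[CycleSegment], recording: AudioRecording,
                  k: int | None = None,
                  config: SegmentationConfig | None = None) -> list[CycleSegment]:
    """Pick the k cleanest cycles, mirroring the practice of analysing a
    few representative cycles per recording (default 3).

    Quality is the envelope peak-to-trough ratio within the segment — a
    well-formed cycle swings from near silence to a clear ejection peak.
    Segments containing clipped samples are demoted regardless of ratio.
    Ties break to the earliest start; the selection is returned in time
    order. If fewer than k segments exist, all are returned (warned).
    """
    if config is None:
        config = SegmentationConfig()
    if k is None:
        k = config.n_cycles_to_select
    if not segments:
        raise ValueError("no segments to select from")
    env = compute_envelope(recording, config)
    eps = 1e-12
    scored = []
    for seg in segments:
        window = env[seg.start_sample:seg.end_sample]
        ratio = float(window.max() / (window.min() + eps))
        clipped = np.any(np.abs(seg.extract(recording)) >= 0.999)
        scored.append((0 if clipped else 1, ratio, -seg.start_sample, seg))
    if len(segments) < k:
        logger.warning("only %d segments available, requested %d", len(segments), k)
        return sorted(segments, key=lambda s: s.start_sample)
    scored.sort(reverse=True)
    chosen = [seg for *_, seg in scored[:k]]
    return sorted(chosen, key=lambda s: s.start_sample)
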