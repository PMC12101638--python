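"""WAV input/output and recording validation.

Recordings are mono float arrays in [-1, 1]. On disk everything is PCM
16-bit WAV; integer samples are scaled by 1/32767 so that a write/read
round trip is exact up to one quantisation step (2**-15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

_INT16_SCALE = 32767.0

#: Analysis band ceiling in Hz; recordings must be sampled fast enough to
#: resolve it (Nyquist >= this value).
BAND_CEILING_HZ = 4000.0


@dataclass(frozen=True)
class AudioRecording:
    """A mono audio recording of an AVF bruit."""

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecording samples must be one-dimensional (mono)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate


def read_wav(path, subject_id: str = "") -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer formats are rescaled to [-1, 1]; multi-channel input is
    down-mixed to mono by averaging the channels (logged, since bruit
    recordings are expected to be mono).
    """
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        # symmetric scale (max magnitude of the positive range) so that
        # write_wav . read_wav is the identity up to quantisation
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        logger.info("down-mixing %d-channel WAV %s to mono by channel mean",
                    samples.shape[1], path)
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioRecording(samples=samples, sample_rate=int(rate), subject_id=subject_id)


def write_wav(recording: AudioRecording, path) -> None:
    """Write a recording as PCM 16-bit mono WAV.

    Raises
    ------
    ValueError
        If the sample array is empty or contains values outside [-1, 1]
        (no silent clipping).
    """
    samples = recording.samples
    if len(samples) == 0:
        raise ValueError("cannot write an empty recording")
    peak = float(np.max(np.abs(samples)))
    if peak > 1.0:
        raise ValueError(f"samples exceed [-1, 1] (max abs {peak:.4g}); rescale before writing")
    data = np.round(samples * _INT16_SCALE).astype(np.int16)
    wavfile.write(path, recording.sample_rate, data)


def validate_recording(
    recording: AudioRecording,
    min_duration: float = 5.0,
    min_rate: float = 8000.0,
    clip_fraction: float = 1e-3,
    silence_rms: float = 1e-4,
) -> list[str]:
    """Check a recording is usable for band analysis; return findings.

    Findings (empty list = clean): too short for a handful of pulse
    cycles, sample rate whose Nyquist falls below the 4 kHz band
    ceiling, clipped samples, near-silence.
    """
    findings: list[str] = []
    if recording.duration < min_duration:
        findings.append(
            f"too short: {recording.duration:.2f} s < {min_duration:g} s minimum"
        )
    if recording.sample_rate < min_rate:
        findings.append(
            f"sample rate {recording.sample_rate} Hz below minimum {min_rate:g} Hz"
        )
    if recording.sample_rate / 2.0 < BAND_CEILING_HZ:
        findings.append(
            f"Nyquist {recording.sample_rate / 2:.0f} Hz below {BAND_CEILING_HZ:.0f} Hz band ceiling"
        )
    n = len(recording.samples)
    if n:
        clipped = np.count_nonzero(np.abs(recording.samples) >= 0.999)
        if clipped > clip_fraction * n:
            findings.append(f"clipping: {clipped} samples at full scale")
        rms = float(np.sqrt(np.mean(recording.samples**2)))
        if rms < silence_rms:
            findings.append(f"near-silence: RMS {rms:.2e}")
    else:
        findings.append("empty recording")
    return findings
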