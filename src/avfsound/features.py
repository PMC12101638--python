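"""Per-cycle spectral statistics: band power, TMP, MF and PSD200.

The analysis grid is 40 contiguous 100-Hz bands with centers
100, 200, ..., 4000 Hz; band f covers [f-50, f+50). Three statistics are
computed per pulse cycle:

* TMP (time at maximum power): within a cycle whose duration is
  normalized to 100 time bins, the bin (as percent of the cycle) at
  which a band's short-time power peaks.
* MF: the band center at which the whole-cycle PSD is maximal.
* PSD200: the prominence of the 200-Hz band over its neighbours,
  2*P(200) - P(100) - P(300), in linear per-Hz power-density units. Low
  values accompany AVF dysfunction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BAND_CENTERS",
    "BandPowerMatrix",
    "CycleFeatures",
    "SubjectFeatures",
    "band_spectrogram",
    "normalize_time",
    "compute_tmp",
    "compute_band_psd",
    "compute_mf",
    "compute_psd200",
    "cycle_features",
    "aggregate_subject",
]

BAND_CENTERS = np.arange(100, 4001, 100)
BAND_HALF_WIDTH = 50.0
N_TIME_BINS = 100

# STFT: 50 ms Hann at 75% overlap -> 20 Hz frequency resolution (finer
# than the 100-Hz bands) and ~80 native frames for a 1-s cycle.
STFT_WINDOW_S = 0.05
STFT_OVERLAP = 0.75


@dataclass(frozen=True)
class BandPowerMatrix:
    """time_bins x 40-band matrix of non-negative power densities."""

    values: np.ndarray  # (n_time_bins, 40)
    band_centers: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != len(BAND_CENTERS):
            raise ValueError(f"expected (time, {len(BAND_CENTERS)}) matrix, got {values.shape}")
        if np.any(values < 0):
            raise ValueError("power densities must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_centers", BAND_CENTERS.copy())

    @property
    def n_time_bins(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CycleFeatures:
    """Statistics of a single pulse cycle."""

    tmp_by_band: np.ndarray  # percent of cycle, NaN where the band is silent
    band_psd: np.ndarray  # per-Hz power density per band
    mf: int  # Hz, a band center
    psd200: float


@dataclass(frozen=True)
class SubjectFeatures:
    """Cycle-averaged statistics for one subject."""

    subject_id: str
    tmp_by_band: np.ndarray
    band_psd: np.ndarray
    mf: int
    psd200: float
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.n_cycles_used < 1:
            raise ValueError("n_cycles_used must be >= 1")


def _band_aggregate(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Integrate a per-Hz spectrum into the 40 bands and express each as
    a density over the nominal 100-Hz bandwidth.

    psd may be 1-D (freq,) or 2-D (freq, time).
    """
    df = freqs[1] - freqs[0]
    out_shape = (len(BAND_CENTERS),) + psd.shape[1:]
    out = np.zeros(out_shape)
    for i, c in enumerate(BAND_CENTERS):
        mask = (freqs >= c - BAND_HALF_WIDTH) & (freqs < c + BAND_HALF_WIDTH)
        if np.any(mask):
            out[i] = psd[mask].sum(axis=0) * df / (2 * BAND_HALF_WIDTH)
    return out


def _nperseg(sample_rate: int) -> int:
    return int(round(STFT_WINDOW_S * sample_rate))


def band_spectrogram(cycle: np.ndarray, sample_rate: int) -> BandPowerMatrix:
    """Short-time band power of one cycle (time bins x 40 bands).

    Raises
    ------
    ValueError
        If the cycle is shorter than one STFT window.
    """
    cycle = np.asarray(cycle, dtype=np.float64)
    nperseg = _nperseg(sample_rate)
    if len(cycle) < nperseg:
        raise ValueError(
            f"cycle of {len(cycle)} samples is shorter than the "
            f"{nperseg}-sample ({STFT_WINDOW_S * 1000:.0f} ms) analysis window"
        )
    freqs, _, sxx = signal.spectrogram(
        cycle, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * STFT_OVERLAP), scaling="density",
        mode="psd", detrend=False,
    )
    return BandPowerMatrix(values=_band_aggregate(freqs, sxx).T)


def normalize_time(matrix: BandPowerMatrix, n_bins: int = N_TIME_BINS) -> BandPowerMatrix:
    """Resample the time axis to exactly n_bins.

    Each output bin takes the level of the source frame containing its
    center (zero-order hold), then each band is rescaled so its mean
    level — and hence its integrated power over the normalized cycle —
    is conserved exactly. Sampling rather than mean-pooling keeps the
    location of a band's power maximum intact: averaging across frame
    boundaries dilutes narrow peaks and can hand the argmax to a
    near-tied competitor elsewhere in the cycle. An input already on
    the target grid passes through unchanged.
    """
    values = matrix.values
    t = values.shape[0]
    if t < 1:
        raise ValueError("matrix has no time bins")
    if t == n_bins:
        return matrix
    centers = (np.arange(n_bins) + 0.5) * (t / n_bins)
    src = np.minimum(centers.astype(np.intp), t - 1)
    sampled = values[src, :]
    src_mean = values.mean(axis=0)
    new_mean = sampled.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(new_mean > 0, src_mean / np.where(new_mean > 0, new_mean, 1.0), 1.0)
    return BandPowerMatrix(values=sampled * scale)


def compute_tmp(matrix: BandPowerMatrix) -> np.ndarray:
    """Per-band time-at-maximum-power in percent of the cycle.

    TMP = argmax bin + 0.5 (the bin center on the 100-unit axis); ties
    resolve to the earliest bin. A band with no power has no maximum and
    is reported as NaN.
    """
    if matrix.n_time_bins != N_TIME_BINS:
        raise ValueError(f"matrix must be time-normalized to {N_TIME_BINS} bins first")
    values = matrix.values
    tmp = np.argmax(values, axis=0) + 0.5
    silent = values.max(axis=0) <= 0
    return np.where(silent, np.nan, tmp.astype(np.float64))


def compute_band_psd(cycle: np.ndarray, sample_rate: int) -> np.ndarray:
    """Whole-cycle averaged-periodogram PSD aggregated to the 40 bands
    (per-Hz density over each nominal 100-Hz bandwidth)."""
    cycle = np.asarray(cycle, dtype=np.float64)
    nperseg = _nperseg(sample_rate)
    if len(cycle) < nperseg:
        raise ValueError(
            f"cycle of {len(cycle)} samples is shorter than the "
            f"{nperseg}-sample analysis window"
        )
    freqs, psd = signal.welch(cycle, fs=sample_rate, window="hann",
                              nperseg=nperseg, scaling="density", detrend=False)
    return _band_aggregate(freqs, psd)


def compute_mf(band_psd: np.ndarray) -> int:
    """Band center (Hz) of the maximum whole-cycle PSD; ties take the
    lowest frequency."""
    band_psd = np.asarray(band_psd)
    if band_psd.shape != BAND_CENTERS.shape or not np.all(np.isfinite(band_psd)):
        raise ValueError("band_psd must be a complete, finite 40-band vector")
    return int(BAND_CENTERS[int(np.argmax(band_psd))])


def compute_psd200(band_psd: np.ndarray) -> float:
    """Spectral prominence index 2*P(200) - P(100) - P(300)."""
    band_psd = np.asarray(band_psd)
    if band_psd.shape != BAND_CENTERS.shape:
        raise ValueError("band_psd must cover all 40 bands")
    p100, p200, p300 = band_psd[0], band_psd[1], band_psd[2]
    if not np.all(np.isfinite([p100, p200, p300])):
        raise ValueError("bands 100, 200 and 300 Hz must be present and finite")
    return float(2.0 * p200 - p100 - p300)


def cycle_features(cycle: np.ndarray, sample_rate: int) -> CycleFeatures:
    """All per-cycle statistics for one extracted pulse cycle."""
    matrix = normalize_time(band_spectrogram(cycle, sample_rate))
    band_psd = compute_band_psd(cycle, sample_rate)
    return CycleFeatures(
        tmp_by_band=compute_tmp(matrix),
        band_psd=band_psd,
        mf=compute_mf(band_psd),
        psd200=compute_psd200(band_psd),
    )


def aggregate_subject(features: list[CycleFeatures], subject_id: str) -> SubjectFeatures:
    """Average per-cycle features into one subject record.

    TMP, band PSD and PSD200 are arithmetic means across cycles (TMP
    ignores cycles where a band was silent); MF is the modal band, ties
    to the lowest frequency.
    """
    if not features:
        raise ValueError("need at least one cycle to aggregate")
    tmp = np.nanmean(np.vstack([f.tmp_by_band for f in features]), axis=0)
    band_psd = np.mean(np.vstack([f.band_psd for f in features]), axis=0)
    counts = Counter(f.mf for f in features)
    top = max(counts.values())
    mf = min(hz for hz, c in counts.items() if c == top)
    return SubjectFeatures(
        subject_id=subject_id,
        tmp_by_band=tmp,
        band_psd=band_psd,
        mf=mf,
        psd200=float(np.mean([f.psd200 for f in features])),
        n_cycles_used=len(features),
    )
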