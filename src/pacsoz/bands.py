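"""Frequency-band grid, zero-phase FIR filtering, Hilbert phase/amplitude, segmentation.

The analysis grid pairs 16 narrow low-frequency bands (0.5--24 Hz, used for
instantaneous phase) with 16 high-frequency bands (80--560 Hz in 30 Hz steps,
used for instantaneous amplitude).  The low-frequency tiling uses bandwidths of
0.5 Hz (0.5--1), 1 Hz (1--8) and 2 Hz (8--24) so that the delta band is
resolved finely while keeping the grid square.

Filtering is FIR with a Kaiser window, odd tap count (avoiding a zero at
Nyquist), applied zero-phase.  Phase and amplitude come from the analytic
signal (Hilbert transform).  Records are decomposed as whole channels and only
then cut into non-overlapping 20-s segments, so a 1-h record yields 180
segments per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyBand",
    "BandGrid",
    "SegmentedSeries",
    "build_band_grid",
    "kaiser_taps",
    "fir_bandpass",
    "hilbert_phase_amplitude",
    "segment",
    "channel_analytic",
]

# Kaiser design targets: >= 60 dB stopband attenuation, transition width equal
# to half the band's width, tap count forced odd and clamped to [101, 20001].
STOPBAND_DB = 60.0
MIN_TAPS = 101
MAX_TAPS = 20001


class FrequencyBand(NamedTuple):
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got {self}")
        if self.high >= fs / 2.0:
            raise ValueError(f"band {self} reaches Nyquist for fs={fs}")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high


@dataclass(frozen=True)
class BandGrid:
    """16 phase bands tiling 0.5--24 Hz and 16 amplitude bands tiling 80--560 Hz."""

    phase_bands: tuple[FrequencyBand, ...]
    amp_bands: tuple[FrequencyBand, ...]

    def __post_init__(self) -> None:
        for bands, lo, hi in (
            (self.phase_bands, 0.5, 24.0),
            (self.amp_bands, 80.0, 560.0),
        ):
            if len(bands) != 16:
                raise ValueError("each band axis must have exactly 16 bands")
            if bands[0].low != lo or bands[-1].high != hi:
                raise ValueError(f"bands must tile [{lo}, {hi}] Hz")
            for a, b in zip(bands, bands[1:]):
                if a.high != b.low:
                    raise ValueError(f"gap/overlap between {a} and {b}")

    def phase_index(self, freq: float) -> int:
        """Index of the phase band containing ``freq`` (half-open intervals)."""
        for i, band in enumerate(self.phase_bands):
            if band.contains(freq):
                return i
        raise ValueError(f"{freq} Hz outside the phase-band range")

    def amp_index(self, freq: float) -> int:
        for i, band in enumerate(self.amp_bands):
            if band.contains(freq):
                return i
        raise ValueError(f"{freq} Hz outside the amplitude-band range")


def build_band_grid() -> BandGrid:
    """The 16 x 16 analysis grid.

    Phase bands: (0.5, 1), then 1-Hz steps to 8 Hz, then 2-Hz steps to 24 Hz.
    Amplitude bands: 30-Hz steps from 80 to 560 Hz.
    """
    edges = [0.5, 1.0]
    edges += [float(f) for f in range(2, 9)]        # 1-8 Hz in 1-Hz steps
    edges += [float(f) for f in range(10, 25, 2)]   # 8-24 Hz in 2-Hz steps
    phase = tuple(FrequencyBand(a, b) for a, b in zip(edges, edges[1:]))
    amp = tuple(
        FrequencyBand(float(f), float(f + 30)) for f in range(80, 560, 30)
    )
    return BandGrid(phase_bands=phase, amp_bands=amp)


def kaiser_taps(band: FrequencyBand, fs: float) -> np.ndarray:
    """Kaiser-window band-pass taps for ``band``; tap count is always odd."""
    band = FrequencyBand(*band)
    band.validate(fs)
    transition = band.width / 2.0
    beta = signal.kaiser_beta(STOPBAND_DB)
    # Kaiser tap-count estimate: N ~ (A - 7.95) / (2.285 * delta_omega)
    n = int(np.ceil((STOPBAND_DB - 7.95) / (2.285 * 2.0 * np.pi * transition / fs)))
    n = min(max(n, MIN_TAPS), MAX_TAPS)
    if n % 2 == 0:
        n += 1
    return signal.firwin(
        n, [band.low, band.high], window=("kaiser", beta), pass_zero=False, fs=fs
    )


def fir_bandpass(x: np.ndarray, band: FrequencyBand, fs: float) -> np.ndarray:
    """Zero-phase band-pass of ``x``; output has the input's length.

    The taps are linear-phase (symmetric, odd count), so a centered linear
    convolution is exactly zero-phase.  Raises if the band reaches Nyquist or
    if ``x`` is shorter than the filter.
    """
    x = np.asarray(x, dtype=float)
    taps = kaiser_taps(band, fs)
    if x.shape[-1] < taps.size:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than filter ({taps.size} taps)"
        )
    return signal.fftconvolve(x, taps, mode="same")


def hilbert_phase_amplitude(x_filtered: np.ndarray, role: str) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) or amplitude of a band-limited series.

    ``role`` is ``"phase"`` (angle of the analytic signal) or ``"amplitude"``
    (its magnitude).  A constant input has amplitude 0 and undefined phase;
    phase 0 is returned with a warning.
    """
    if role not in ("phase", "amplitude"):
        raise ValueError(f"role must be 'phase' or 'amplitude', got {role!r}")
    x = np.asarray(x_filtered, dtype=float)
    if np.ptp(x) == 0.0:
        warnings.warn("constant input: amplitude is 0 and phase undefined (returning 0)")
        return np.zeros_like(x)
    analytic = signal.hilbert(x)
    return np.angle(analytic) if role == "phase" else np.abs(analytic)


@dataclass
class SegmentedSeries:
    """Chronologically ordered fixed-length windows of one series."""

    segments: np.ndarray          # (n_segments, samples_per_segment)
    segment_length: float         # seconds
    fs: float

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def segment(x: np.ndarray, fs: float, seg_seconds: float = 20.0) -> SegmentedSeries:
    """Cut ``x`` into non-overlapping ``seg_seconds`` windows; remainder discarded."""
    n_per = seg_seconds * fs
    if abs(n_per - round(n_per)) > 1e-9 or n_per <= 0:
        raise ValueError(f"fs*seg_seconds={n_per} must be a positive integer")
    n_per = round(n_per)
    x = np.asarray(x)
    n_seg = x.shape[-1] // n_per
    if n_seg == 0:
        warnings.warn(
            f"series of {x.shape[-1]} samples shorter than one "
            f"{seg_seconds}-s segment; returning no segments"
        )
    segs = x[..., : n_seg * n_per].reshape(*x.shape[:-1], n_seg, n_per)
    return SegmentedSeries(segments=segs, segment_length=seg_seconds, fs=fs)


def channel_analytic(
    x: np.ndarray, grid: BandGrid, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band instantaneous phase and amplitude for one channel.

    Returns ``(phases, amps)`` with shapes ``(16, n)``: row ``p`` of ``phases``
    is the phase series of phase band ``p``, row ``a`` of ``amps`` the
    amplitude series of amplitude band ``a``.

    The decomposition is done in the frequency domain: one FFT of the channel,
    then for each band a multiplication with the (real, zero-phase) frequency
    response of the same Kaiser taps used by :func:`fir_bandpass`, combined
    with the analytic-signal mask, and one inverse FFT.  This equals
    ``hilbert(fir_bandpass(x))`` up to periodic-versus-linear convolution edge
    effects confined to half a filter length at the record boundaries.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    spec = np.fft.fft(x)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    # analytic mask: double positive frequencies, keep DC/Nyquist, drop negative
    mask = np.zeros(n)
    mask[0] = 1.0
    if n % 2 == 0:
        mask[1 : n // 2] = 2.0
        mask[n // 2] = 1.0
    else:
        mask[1 : (n + 1) // 2] = 2.0

    def _band_analytic(band: FrequencyBand) -> np.ndarray:
        taps = kaiser_taps(band, fs)
        if n < taps.size:
            raise ValueError(
                f"signal length {n} shorter than filter ({taps.size} taps)"
            )
        half = taps.size // 2
        # zero-phase (centered) circular response; real-valued by symmetry
        resp = np.exp(2j * np.pi * freqs * half / fs)
        h = np.fft.fft(taps, n) * resp
        return np.fft.ifft(spec * h.real * mask)

    phases = np.empty((len(grid.phase_bands), n))
    amps = np.empty((len(grid.amp_bands), n))
    for i, band in enumerate(grid.phase_bands):
        phases[i] = np.angle(_band_analytic(band))
    for i, band in enumerate(grid.amp_bands):
        amps[i] = np.abs(_band_analytic(band))
    return phases, amps
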