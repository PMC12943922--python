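"""Hilbert spectral analysis of intrinsic mode functions.

Each IMF is mapped to its analytic signal z(t) = imf(t) + i H[imf](t); the
modulus gives the instantaneous amplitude (IA, µV) and the derivative of the
unwrapped phase gives the instantaneous frequency (IF, Hz).  Two scalars
summarize an IMF over an epoch:

* CF — center frequency, the IA²-weighted mean of the IF, i.e. the first
  moment of the marginal Hilbert spectrum;
* TP — total power, the per-sample mean of IA² in µV², reported in dB via
  10·log10(P) so it is invariant to epoch length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateInputError, DimensionError, NumericError

__all__ = [
    "AnalyticIMF",
    "MarginalSpectrum",
    "IMFFeatures",
    "analytic_signal",
    "instantaneous_amplitude",
    "instantaneous_frequency",
    "analyze_imf",
    "marginal_spectrum",
    "center_frequency",
    "total_power",
    "total_power_db",
    "imf_features",
]

#: samples with IA below this fraction of the epoch maximum get no IF estimate
AMPLITUDE_FLOOR_REL = 1e-6
MIN_SAMPLES = 8


@dataclasses.dataclass
class AnalyticIMF:
    """One IMF with its instantaneous amplitude/frequency series.

    ``if_hz`` holds NaN where the amplitude floor leaves the phase
    undefined.  Out-of-range IF samples (negative or above Nyquist) are kept
    as estimated here and discarded only by the spectral summaries.
    """

    imf: np.ndarray
    ia: np.ndarray
    if_hz: np.ndarray
    fs: float

    def valid_mask(self) -> np.ndarray:
        """Samples with a defined, physically admissible IF (0..Nyquist)."""
        return np.isfinite(self.if_hz) & (self.if_hz >= 0) & (self.if_hz <= self.fs / 2)


@dataclasses.dataclass(frozen=True)
class MarginalSpectrum:
    """Time-integrated Hilbert spectrum: IA² power accumulated per IF bin."""

    freq_bins: np.ndarray  # bin centers, Hz
    power: np.ndarray      # µV² per bin
    bin_hz: float


@dataclasses.dataclass(frozen=True)
class IMFFeatures:
    """Scalar per-epoch summary of one IMF."""

    cf: float      # Hz; NaN for a silent IMF
    tp_db: float   # dB re 1 µV²; NaN when power is zero
    tp_uv2: float  # raw mean IA² (µV²)


def analytic_signal(imf: np.ndarray) -> np.ndarray:
    """Analytic signal via the FFT-based discrete Hilbert transform.

    The real part equals the input exactly; the imaginary part is the 90°
    phase-shifted companion.
    """
    imf = np.asarray(imf, dtype=float)
    if imf.size < MIN_SAMPLES:
        raise DimensionError(f"need at least {MIN_SAMPLES} samples, got {imf.size}")
    if not np.all(np.isfinite(imf)):
        raise NumericError("IMF contains non-finite values")
    z = hilbert(imf)
    # keep the real part bit-exact (the FFT round trip perturbs it by ~1 ulp)
    return imf + 1j * z.imag


def instantaneous_amplitude(z: np.ndarray) -> np.ndarray:
    """Elementwise modulus |z(t)| = sqrt(imf² + H[imf]²)."""
    return np.abs(np.asarray(z))


def instantaneous_frequency(
    z: np.ndarray, fs: float, amplitude_floor_rel: float = AMPLITUDE_FLOOR_REL
) -> np.ndarray:
    """Phase-derivative IF in Hz: central differences of the unwrapped angle.

    One-sided differences at the ends.  Samples whose amplitude falls below
    ``amplitude_floor_rel`` times the epoch maximum have no meaningful phase
    and are returned as NaN; an all-zero signal is degenerate.
    """
    z = np.asarray(z)
    ia = np.abs(z)
    peak = ia.max() if ia.size else 0.0
    if peak == 0:
        raise DegenerateInputError("all-zero signal has no instantaneous frequency")
    phase = np.unwrap(np.angle(z))
    if_hz = np.gradient(phase) * fs / (2.0 * np.pi)
    if_hz[ia < amplitude_floor_rel * peak] = np.nan
    return if_hz


def analyze_imf(imf: np.ndarray, fs: float, trim_seconds: float = 0.0) -> AnalyticIMF:
    """Build the full analytic description of one IMF.

    ``trim_seconds`` drops that many seconds from each end *after* the
    transform, which suppresses Hilbert edge effects on short epochs.
    """
    z = analytic_signal(imf)
    ia = instantaneous_amplitude(z)
    if np.all(ia == 0):
        if_hz = np.full(ia.size, np.nan)
    else:
        if_hz = instantaneous_frequency(z, fs)
    imf = np.asarray(imf, dtype=float)
    if trim_seconds > 0:
        k = int(round(trim_seconds * fs))
        if 2 * k >= imf.size:
            raise DimensionError("trim_seconds removes the whole epoch")
        sl = slice(k, imf.size - k)
        imf, ia, if_hz = imf[sl], ia[sl], if_hz[sl]
    return AnalyticIMF(imf=imf, ia=ia, if_hz=if_hz, fs=fs)


def marginal_spectrum(aimf: AnalyticIMF, bin_hz: float = 0.5) -> MarginalSpectrum:
    """Accumulate IA² into uniform IF bins from 0 to Nyquist.

    Total binned power equals the summed IA² of the contributing samples
    (power conservation); samples without an admissible IF are excluded.
    """
    mask = aimf.valid_mask()
    if not mask.any():
        raise DegenerateInputError("no samples with a defined instantaneous frequency")
    nyq = aimf.fs / 2.0
    n_bins = max(1, int(np.ceil(nyq / bin_hz)))
    edges = np.linspace(0.0, n_bins * bin_hz, n_bins + 1)
    power, _ = np.histogram(aimf.if_hz[mask], bins=edges, weights=aimf.ia[mask] ** 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MarginalSpectrum(freq_bins=centers, power=power, bin_hz=bin_hz)


def center_frequency(aimf: AnalyticIMF, power_weighted: bool = True) -> float:
    """CF in Hz: the IA²-weighted (default) or plain mean of the admissible IF.

    Returns NaN (missing) rather than raising when the IMF carries no
    power — silent IMFs are routine in quiet epochs.
    """
    mask = aimf.valid_mask()
    if not mask.any():
        return float("nan")
    f = aimf.if_hz[mask]
    if not power_weighted:
        return float(np.mean(f))
    w = aimf.ia[mask] ** 2
    total = w.sum()
    if total == 0:
        return float("nan")
    return float(np.sum(w * f) / total)


def total_power(aimf: AnalyticIMF) -> float:
    """Mean IA² per sample over the epoch, in µV²."""
    return float(np.mean(aimf.ia**2))


def total_power_db(aimf: AnalyticIMF) -> float:
    """TP in dB = 10·log10(mean IA²); NaN when the power is exactly zero."""
    p = total_power(aimf)
    if p <= 0:
        return float("nan")
    return float(10.0 * np.log10(p))


def imf_features(aimf: AnalyticIMF, power_weighted: bool = True) -> IMFFeatures:
    """Scalar (CF, TP) summary of one analytic IMF."""
    p = total_power(aimf)
    return IMFFeatures(
        cf=center_frequency(aimf, power_weighted=power_weighted),
        tp_db=total_power_db(aimf),
        tp_uv2=p,
    )
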