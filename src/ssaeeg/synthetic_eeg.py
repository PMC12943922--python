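"""Anesthesia-like synthetic frontal EEG with a known depth-of-anesthesia index.

Each recording emulates the 10 minutes before emergence from volatile-agent
general anesthesia, split into three equal phases:

* maintenance — large slow (delta) oscillation plus prominent 10-12 Hz
  alpha spindle bursts, the signature of steady sevoflurane anesthesia;
* transition — attenuated delta/alpha with rising 15-47 Hz fast activity;
* emergence — low-amplitude, beta-dominated activity.

Phase parameters are cross-faded over a 10-s window, and the background is
1/f ("pink") noise so the residual spectrum decays with frequency as real
EEG does.  A BIS-like index (0-100) is programmed as a clipped affine
function of the smoothed log band powers of the three construction
components, rising monotonically from the maintenance level toward
emergence; it is the ground truth the regression stage is asked to recover.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .errors import SSAEEGError
from .io_eeg import EEGRecording

__all__ = [
    "PhaseParams",
    "BISModel",
    "SyntheticConfig",
    "SyntheticRecording",
    "generate_recording",
    "generate_cohort",
]


@dataclasses.dataclass(frozen=True)
class PhaseParams:
    """Component amplitudes/frequencies for one anesthetic phase.

    Amplitudes are µV (peak for the deterministic components, RMS for the
    stochastic ones); ``spindle_rate`` is bursts per minute.
    """

    delta_amp: float
    delta_freq: float
    alpha_amp: float
    alpha_freq: float
    spindle_rate: float
    spindle_dur: float
    beta_amp: float
    beta_band: tuple[float, float]
    noise_sd: float

    def validate(self, fs: float) -> None:
        lo, hi = self.beta_band
        if not 0 < lo < hi:
            raise SSAEEGError(f"invalid beta band {self.beta_band}")
        if fs <= 2 * hi:
            raise SSAEEGError(f"fs={fs} too low for beta band up to {hi} Hz")
        for name in ("delta_amp", "alpha_amp", "beta_amp", "noise_sd", "spindle_rate"):
            if getattr(self, name) < 0:
                raise SSAEEGError(f"{name} must be non-negative")


@dataclasses.dataclass(frozen=True)
class BISModel:
    """BIS-like index = clip(intercept + Σ weight·log10(band power + eps)
    + w_beta_freq·(beta center frequency − maintenance center)) + noise.

    Weights are negative on the slow/alpha powers (more slow activity =
    deeper anesthesia = lower index) and positive on the fast-band power
    and on the fast-band center frequency, so the index carries band-power
    and band-frequency information that the IMF features must recover.
    """

    intercept: float = 64.0
    w_delta: float = -10.0
    w_alpha: float = -4.0
    w_beta: float = 12.0
    w_beta_freq: float = 1.5   # BIS units per Hz of fast-band center shift
    noise_sd: float = 1.5
    smooth_seconds: float = 15.0
    eps: float = 0.1


#: maintenance / transition / emergence defaults: strong delta + 11 Hz
#: spindles, then fading slow activity with broad 15-47 Hz fast power,
#: then low-amplitude beta.
DEFAULT_PHASES: tuple[PhaseParams, PhaseParams, PhaseParams] = (
    PhaseParams(delta_amp=20.0, delta_freq=1.2, alpha_amp=15.0, alpha_freq=11.0,
                spindle_rate=22.0, spindle_dur=2.0, beta_amp=1.2,
                beta_band=(14.0, 26.0), noise_sd=2.5),
    PhaseParams(delta_amp=12.0, delta_freq=1.0, alpha_amp=6.0, alpha_freq=10.0,
                spindle_rate=12.0, spindle_dur=1.5, beta_amp=2.0,
                beta_band=(16.0, 40.0), noise_sd=3.5),
    PhaseParams(delta_amp=6.0, delta_freq=0.8, alpha_amp=2.0, alpha_freq=10.0,
                spindle_rate=3.0, spindle_dur=1.0, beta_amp=1.8,
                beta_band=(20.0, 36.0), noise_sd=5.0),
)


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    duration_s: float = 600.0
    fs: float = 128.0
    n_recordings: int = 10
    phase_schedule: tuple[PhaseParams, PhaseParams, PhaseParams] = DEFAULT_PHASES
    bis_model: BISModel = BISModel()
    fade_s: float = 10.0
    jitter: float = 0.10       # per-recording relative spread of amps/freqs
    amp_wander: float = 0.15   # sd of slow log10 amplitude modulation, per band
    freq_wander: float = 2.5   # sd (Hz) of the slow fast-band center-frequency walk
    wander_smooth_s: float = 30.0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise SSAEEGError("duration_s and fs must be positive")
        for ph in self.phase_schedule:
            ph.validate(self.fs)


@dataclasses.dataclass
class SyntheticRecording:
    """A generated recording plus the programmed ground truth."""

    recording: EEGRecording
    true_bis: pd.Series          # dense, one value per second
    ground_truth: pd.DataFrame   # per-second band powers (delta/alpha/beta)


def _phase_weights(t: np.ndarray, duration: float, fade: float) -> np.ndarray:
    """(3, n) matrix of cross-fade weights; columns sum to 1."""

    def ramp(edge):
        # raised-cosine 0 -> 1 over [edge - fade/2, edge + fade/2]
        x = np.clip((t - (edge - fade / 2)) / max(fade, 1e-9), 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * x)

    s1 = ramp(duration / 3.0)
    s2 = ramp(2.0 * duration / 3.0)
    return np.vstack([1.0 - s1, s1 - s2, s2])


def _blend(weights: np.ndarray, values: list[float]) -> np.ndarray:
    return weights.T @ np.asarray(values, dtype=float)


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance background noise with a 1/f² power spectrum (flat below 0.5 Hz).

    The steep rolloff matches the broadband background of frontal EEG, so
    the high-rank SSA residual is not artificially rich in fast activity.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.maximum(f, 0.5)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _slow_wander(rng: np.random.Generator, n: int, fs: float, smooth_s: float) -> np.ndarray:
    """Unit-variance slow random modulation (smoothed at the 1-s level)."""
    n_sec = max(2, int(np.ceil(n / fs)) + 1)
    coarse = _moving_average(rng.standard_normal(n_sec), int(smooth_s) | 1)
    sd = coarse.std()
    if sd > 0:
        coarse = coarse / sd
    t_coarse = np.arange(n_sec, dtype=float)
    return np.interp(np.arange(n) / fs, t_coarse, coarse)


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, f_center: np.ndarray, bw: float
) -> np.ndarray:
    """Unit-RMS narrowband Gaussian noise around a time-varying center frequency.

    Built from two quadrature lowpass envelopes (bandwidth ``bw``) riding a
    frequency-modulated carrier, the standard model of band-limited EEG
    fast activity.
    """
    sos = butter(4, bw / 2.0, btype="lowpass", fs=fs, output="sos")
    a = sosfiltfilt(sos, rng.standard_normal(n))
    b = sosfiltfilt(sos, rng.standard_normal(n))
    phi = 2.0 * np.pi * np.cumsum(f_center) / fs
    x = a * np.cos(phi) + b * np.sin(phi)
    return x / x.std()


def _spindle_train(
    rng: np.random.Generator,
    t: np.ndarray,
    fs: float,
    weights: np.ndarray,
    phases: tuple[PhaseParams, ...],
) -> np.ndarray:
    """Hann-windowed alpha bursts from a thinned Poisson event process."""
    n = t.size
    duration = t[-1] + 1.0 / fs
    rate_env = _blend(weights, [p.spindle_rate for p in phases]) / 60.0  # events/s
    amp_env = _blend(weights, [p.alpha_amp for p in phases])
    freq_env = _blend(weights, [p.alpha_freq for p in phases])
    dur_env = _blend(weights, [p.spindle_dur for p in phases])
    max_rate = rate_env.max()
    out = np.zeros(n)
    if max_rate <= 0:
        return out
    n_cand = rng.poisson(max_rate * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept = rng.uniform(0.0, 1.0, n_cand)
    for t0, u in zip(cand, accept):
        i0 = int(t0 * fs)
        if i0 >= n or u > rate_env[i0] / max_rate:
            continue
        dur = max(dur_env[i0], 2.0 / fs)
        m = int(dur * fs)
        if m < 4:
            continue
        stop = min(i0 + m, n)
        win = hann(m)[: stop - i0]
        amp = amp_env[i0] * (1.0 + 0.2 * rng.standard_normal())
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        tt = t[i0:stop] - t0
        out[i0:stop] += max(amp, 0.0) * win * np.sin(2.0 * np.pi * freq_env[i0] * tt + phase0)
    return out


def _window_power(x: np.ndarray, fs: float, n_windows: int) -> np.ndarray:
    """Mean squared value per 1-s window."""
    m = int(fs)
    return (x[: n_windows * m] ** 2).reshape(n_windows, m).mean(axis=1)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width | 1)  # odd
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def generate_recording(
    cfg: SyntheticConfig | None = None,
    seed: int | None = None,
    recording_id: str = "synthetic",
) -> SyntheticRecording:
    """Generate one recording with its programmed BIS-like index.

    Reproducible: the same config and seed give an identical series.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    phases = cfg.phase_schedule
    w = _phase_weights(t, cfg.duration_s, cfg.fade_s)

    # slow, semi-independent band dynamics: each band's amplitude wanders on
    # a ~30-s timescale around its phase envelope, so band powers are not
    # perfectly collinear with the phase ramp
    wander = {
        band: 10.0 ** (cfg.amp_wander * _slow_wander(rng, n, fs, cfg.wander_smooth_s))
        for band in ("delta", "alpha", "beta")
    }

    # slow (delta) oscillation with a phase-dependent amplitude/frequency envelope
    delta_amp = _blend(w, [p.delta_amp for p in phases]) * wander["delta"]
    delta_freq = _blend(w, [p.delta_freq for p in phases])
    delta = delta_amp * np.sin(
        2.0 * np.pi * np.cumsum(delta_freq) / fs + rng.uniform(0.0, 2.0 * np.pi)
    )

    alpha = _spindle_train(rng, t, fs, w, phases) * wander["alpha"]

    # fast ("beta") narrowband activity: center frequency blends the phase
    # band midpoints plus a slow random walk that the BIS model reads out
    centers = _blend(w, [(p.beta_band[0] + p.beta_band[1]) / 2.0 for p in phases])
    f_center = centers + cfg.freq_wander * _slow_wander(rng, n, fs, cfg.wander_smooth_s)
    f_center = np.clip(f_center, 4.0, fs / 2.0 - 4.0)
    beta_bw = float(np.mean([p.beta_band[1] - p.beta_band[0] for p in phases])) / 2.0
    beta_amp = _blend(w, [p.beta_amp for p in phases]) * wander["beta"]
    beta = beta_amp * _narrowband(rng, n, fs, f_center, max(beta_bw, 4.0))

    noise_sd = _blend(w, [p.noise_sd for p in phases])
    noise = noise_sd * _pink_noise(rng, n, fs)

    eeg = delta + alpha + beta + noise

    # ground truth: per-second powers and fast-band center frequency of the
    # construction components
    n_sec = int(cfg.duration_s)
    sec = np.arange(n_sec, dtype=float)
    powers = pd.DataFrame(
        {
            "delta_power": _window_power(delta, fs, n_sec),
            "alpha_power": _window_power(alpha, fs, n_sec),
            "beta_power": _window_power(beta, fs, n_sec),
            "beta_freq": f_center[: n_sec * int(fs)].reshape(n_sec, int(fs)).mean(axis=1),
        },
        index=pd.Index(sec, name="t"),
    )

    bm = cfg.bis_model
    width = int(bm.smooth_seconds)
    f_ref = (phases[0].beta_band[0] + phases[0].beta_band[1]) / 2.0
    bis = bm.intercept + sum(
        getattr(bm, f"w_{band}")
        * _moving_average(np.log10(powers[f"{band}_power"].to_numpy() + bm.eps), width)
        for band in ("delta", "alpha", "beta")
    )
    bis = bis + bm.w_beta_freq * _moving_average(
        powers["beta_freq"].to_numpy() - f_ref, width
    )
    bis = bis + bm.noise_sd * rng.standard_normal(n_sec)
    true_bis = pd.Series(np.clip(bis, 0.0, 100.0), index=powers.index, name="BIS")

    rec = EEGRecording(
        samples=eeg, fs=fs, bis=true_bis.copy(), recording_id=recording_id
    )
    return SyntheticRecording(recording=rec, true_bis=true_bis, ground_truth=powers)


def _jittered(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticConfig:
    """Per-recording ±jitter on amplitudes and frequencies; BIS model shared."""

    def factor():
        return 1.0 + rng.uniform(-cfg.jitter, cfg.jitter)

    new_phases = tuple(
        dataclasses.replace(
            p,
            delta_amp=p.delta_amp * factor(),
            delta_freq=p.delta_freq * factor(),
            alpha_amp=p.alpha_amp * factor(),
            alpha_freq=p.alpha_freq * factor(),
            beta_amp=p.beta_amp * factor(),
            noise_sd=p.noise_sd * factor(),
        )
        for p in cfg.phase_schedule
    )
    return dataclasses.replace(cfg, phase_schedule=new_phases)


def generate_cohort(
    cfg: SyntheticConfig | None = None, base_seed: int | None = None
) -> list[SyntheticRecording]:
    """Generate ``cfg.n_recordings`` mutually distinct recordings.

    All randomness flows from one seed tree: base_seed spawns one
    SeedSequence child per recording, which drives both the parameter
    jitter and the signal generation.
    """
    cfg = cfg or SyntheticConfig()
    if cfg.n_recordings < 1:
        raise SSAEEGError("n_recordings must be at least 1")
    children = np.random.SeedSequence(base_seed).spawn(cfg.n_recordings)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(2**31))
        out.append(
            generate_recording(
                _jittered(cfg, rng), seed=sub_seed, recording_id=f"synthetic-{i:02d}"
            )
        )
    return out
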