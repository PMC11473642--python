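"""Acoustic stimulus features and marker-latency correction.

Three representations of the soundscape drive the neural encoding models:

* ``envelope_raw`` — broadband amplitude envelope of the raw audio,
* ``envelope_denoised`` — envelope after Wiener noise reduction (the
  stationary ventilation/machine floor is estimated from the first second
  and subtracted in the STFT domain),
* ``onsets`` — a sparse binary vector marking detected acoustic event
  starts (a privacy-preserving representation: no waveform is retained).

The module also corrects two marker latencies of the presentation setup:
a constant hardware delay between marker and sound (default 30 ms), and
the per-letter delay until a token embedded in the running soundscape
becomes energetically salient (first energetic peak within a short search
window after the nominal onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

FEATURE_KINDS = ("envelope_raw", "envelope_denoised", "onsets")


@dataclass
class StimulusFeature:
    """A single stimulus feature time series aligned to the block timeline.

    Parameters
    ----------
    values : ndarray
        Feature samples at ``rate`` Hz. Non-negative for envelope kinds,
        strictly {0, 1} for onsets.
    rate : float
        Sampling rate of the feature in Hz.
    kind : str
        One of ``envelope_raw``, ``envelope_denoised``, ``onsets``.
    block : int
        Block index the feature belongs to.
    """

    values: np.ndarray
    rate: float
    kind: str
    block: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "onsets":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("onset feature must be binary")
        elif (self.values < 0).any():
            raise ValueError("envelope feature must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def _as_mono(audio: np.ndarray) -> np.ndarray:
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError(
            "multichannel audio: mix to mono before feature extraction"
        )
    return audio


def extract_envelope(
    audio: np.ndarray,
    fs: float,
    target_rate: float,
    compression: float = 1.0 / 3.0,
    kind: str = "envelope_raw",
    block: int = 0,
) -> StimulusFeature:
    """Amplitude envelope: |analytic signal|^2, window-averaged, compressed.

    The squared magnitude of the Hilbert analytic signal is averaged over
    consecutive windows of ``fs / target_rate`` samples and compressed by
    ``x ** compression`` (cube root by default; ``compression=1`` disables
    the compression). A constant-amplitude tone of amplitude ``A`` thus
    maps to ``A**2`` per window before compression.
    """
    audio = _as_mono(audio)
    if fs <= 2 * target_rate:
        raise ValueError("audio rate must exceed twice the target rate")
    win = int(round(fs / target_rate))
    n_out = audio.size // win
    env = np.abs(signal.hilbert(audio)) ** 2
    env = env[: n_out * win].reshape(n_out, win).mean(axis=1)
    if compression != 1.0:
        env = env**compression
    return StimulusFeature(env, target_rate, kind, block)


def wiener_denoise(
    audio: np.ndarray,
    fs: float,
    noise_seconds: float = 1.0,
    frame_s: float = 0.032,
    hop_s: float = 0.008,
    psd_smooth_frames: int = 9,
    psd_smooth_bins: int = 9,
) -> np.ndarray:
    """Wiener noise reduction against a stationary floor.

    The input is high-pass filtered at 1 Hz, the noise power spectral
    density is estimated as the mean STFT power over the first
    ``noise_seconds``, and each STFT frame is scaled by the spectral gain
    ``max(0, 1 - PSD_noise / PSD_frame)`` before overlap-add resynthesis.
    The frame PSD is smoothed over ``psd_smooth_frames`` neighbouring
    frames and ``psd_smooth_bins`` frequency bins so the gain tracks the
    local signal power rather than single-periodogram fluctuations. Output has the same length as the
    input.
    """
    audio = _as_mono(audio)
    if noise_seconds * fs >= audio.size:
        raise ValueError("noise_seconds must be shorter than the signal")
    if not audio.any():
        return np.zeros_like(audio)
    sos = signal.butter(2, 1.0, btype="highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, audio)

    nperseg = int(round(frame_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    f, t, Z = signal.stft(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - hop
    )
    power = np.abs(Z) ** 2
    noise_frames = t <= noise_seconds
    if not noise_frames.any():
        noise_frames[0] = True
    psd_noise = power[:, noise_frames].mean(axis=1, keepdims=True)
    if psd_smooth_frames > 1 or psd_smooth_bins > 1:
        from scipy.ndimage import uniform_filter1d
        if psd_smooth_frames > 1:
            power = uniform_filter1d(power, size=psd_smooth_frames, axis=1)
        if psd_smooth_bins > 1:
            power = uniform_filter1d(power, size=psd_smooth_bins, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.clip(1.0 - psd_noise / power, 0.0, None)
    gain[~np.isfinite(gain)] = 0.0
    _, y = signal.istft(
        Z * gain, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - hop
    )
    if y.size < audio.size:
        y = np.pad(y, (0, audio.size - y.size))
    return y[: audio.size]


def spectral_flux(
    audio: np.ndarray, fs: float, frame_s: float = 0.016, hop_s: float = 0.004
) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectified spectral-flux novelty curve.

    Returns ``(times, novelty)`` where novelty[t] sums positive magnitude
    increases across frequency between consecutive STFT frames.
    """
    audio = _as_mono(audio)
    nperseg = int(round(frame_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    _, t, Z = signal.stft(
        audio, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - hop
    )
    mag = np.log1p(100.0 * np.abs(Z))
    flux = np.diff(mag, axis=1)
    novelty = np.clip(flux, 0.0, None).sum(axis=0)
    return t[1:], novelty


def detect_onsets(
    audio: np.ndarray,
    fs: float,
    target_rate: float,
    min_ioi_s: float = 0.05,
    median_window_s: float = 0.5,
    delta: float = 5.0,
    block: int = 0,
) -> StimulusFeature:
    """Binary onset vector from a spectral-flux novelty curve.

    The novelty curve is compared against an adaptive threshold (running
    median over ``median_window_s`` plus ``delta`` times the global novelty
    scale); supra-threshold local maxima separated by at least
    ``min_ioi_s`` become ones at ``target_rate``. Silence yields all zeros.
    """
    audio = _as_mono(audio)
    n_out = int(round(audio.size / fs * target_rate))
    values = np.zeros(n_out)
    if not np.any(audio):
        return StimulusFeature(values, target_rate, "onsets", block)

    t, nov = spectral_flux(audio, fs)
    if nov.size < 3:
        return StimulusFeature(values, target_rate, "onsets", block)
    hop = t[1] - t[0]
    k = max(3, int(round(median_window_s / hop)) | 1)
    med = signal.medfilt(nov, kernel_size=k)
    detrended = nov - med
    # robust scale: median absolute deviation of the detrended novelty,
    # so loud events do not inflate the threshold
    mad = np.median(np.abs(detrended)) * 1.4826
    if mad <= 0:
        mad = max(detrended.std(), 1e-12)
    min_dist = max(1, int(round(min_ioi_s / hop)))
    peaks, _ = signal.find_peaks(detrended, height=delta * mad,
                                 distance=min_dist)
    idx = np.round(t[peaks] * target_rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n_out)]
    values[idx] = 1.0
    return StimulusFeature(values, target_rate, "onsets", block)


def correct_marker_delay(
    markers: pd.DataFrame,
    fs: float,
    delay_ms: float = 30.0,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Shift every marker by a constant hardware delay.

    ``onset_sample`` is shifted by ``round(delay_ms / 1000 * fs)`` samples
    (``onset_s`` follows if present). Markers shifted past the end of the
    recording (when ``n_samples`` is given) are clamped and flagged in a
    ``clamped`` column with a warning. Ordering is preserved.
    """
    if not np.isfinite(delay_ms):
        raise ValueError("delay must be finite")
    shift = int(round(delay_ms / 1000.0 * fs))
    out = markers.copy()
    out["onset_sample"] = out["onset_sample"].astype(int) + shift
    if "onset_s" in out.columns:
        out["onset_s"] = out["onset_sample"] / fs
    out["clamped"] = False
    if n_samples is not None:
        over = out["onset_sample"] >= n_samples
        if over.any():
            warnings.warn(
                f"{int(over.sum())} marker(s) shifted past the recording "
                "end; clamped"
            )
            out.loc[over, "onset_sample"] = n_samples - 1
            out.loc[over, "clamped"] = True
    return out


def refine_letter_onsets(
    audio: np.ndarray,
    fs: float,
    letter_markers: pd.DataFrame,
    search_ms: float = 20.0,
    rel_threshold: float = 0.1,
    smooth_ms: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Move each letter marker forward to the first energetic peak.

    Within ``[marker, marker + search_ms]`` the short-time energy (squared
    waveform smoothed over ``smooth_ms``) is scanned; the marker moves to
    the first local energy maximum exceeding ``rel_threshold`` times the
    window maximum. Shifts are non-negative and bounded by ``search_ms``.
    Events with no supra-threshold energy keep their marker and are
    flagged.

    Returns the corrected marker table and a per-letter shift report with
    columns ``shift_ms`` and ``flagged``.
    """
    audio = _as_mono(audio)
    win = int(round(search_ms / 1000.0 * fs))
    smooth = max(1, int(round(smooth_ms / 1000.0 * fs)))
    kernel = np.ones(smooth) / smooth

    out = letter_markers.copy()
    shifts, flagged = [], []
    for i, row in letter_markers.iterrows():
        start = int(row["onset_sample"])
        if start + win > audio.size:
            raise ValueError(
                f"marker at sample {start} has less than {search_ms} ms of "
                "audio after it"
            )
        seg = audio[start : start + win + smooth]
        energy = np.convolve(seg**2, kernel, mode="valid")[: win + 1]
        peak = None
        if energy.max() > 0:
            thr = rel_threshold * energy.max()
            look = max(1, smooth // 2)
            # first supra-threshold sample after which the smoothed energy
            # no longer rises within the look-ahead: the first energy peak
            tol = 1e-6 * energy.max()
            for i in np.flatnonzero(energy >= thr):
                ahead = energy[i + 1 : i + 1 + look]
                if ahead.size == 0 or energy[i] >= ahead.max() - tol:
                    peak = int(i)
                    break
        if peak is None:
            shifts.append(0.0)
            flagged.append(True)
        else:
            out.loc[i, "onset_sample"] = start + peak
            shifts.append(peak / fs * 1000.0)
            flagged.append(False)
    if "onset_s" in out.columns:
        out["onset_s"] = out["onset_sample"] / fs
    report = pd.DataFrame(
        {"shift_ms": shifts, "flagged": flagged}, index=letter_markers.index
    )
    return out, report
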