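"""Synthetic study generator: soundscape, letter streams, EEG, behavior.

Emulates a session in which participants perform a simulated surgery task
under low/high memory load while a continuous operating-room-like
soundscape (stationary ventilation noise plus transient events such as
monitor beeps and instrument clatter) and a stream of spoken-letter-like
tokens are played back. Everything downstream of this module — feature
extraction, EEG cleaning, ERP/TRF estimation, spatial filtering,
behavioral models — is exercised against the ground truth planted here.

The EEG forward model is

    EEG = sum_f (kernel_f * feature_f) x pattern_f
          + ERP template at letter onsets x pattern_erp
          + spatially smooth 1/f noise (+ optional line noise, blinks,
            muscle bursts, broken channels)

with multiplicative condition and time-on-task scaling of the kernels,
so the encoding models and the mixed-effects layer have known targets.
All randomness derives from ``SynthConfig.seed`` via ``SeedSequence``;
identical configs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.io import wavfile

from .audio import StimulusFeature
from .preproc import DEFAULT_CHANNELS, Recording, channel_positions

DEFAULT_LETTER_SET = tuple("BCDFHKLMPQST")

# stream ids for SeedSequence derivation
_S_SOUND, _S_LETTER, _S_EEG, _S_BEHAV, _S_FEAT = 1, 2, 3, 4, 5


@dataclass
class SynthConfig:
    """Study-level configuration of the synthetic session."""

    n_participants: int = 1
    n_blocks: int = 28
    blocks_per_condition: int = 14
    block_duration_s: float = 60.0
    audio_fs: float = 48000.0
    eeg_fs: float = 500.0
    channels: tuple = tuple(DEFAULT_CHANNELS)
    letter_iti_s: float = 3.0
    letter_set: tuple = DEFAULT_LETTER_SET
    snr_db: float = 0.0
    seed: int = 0
    # feature / timing
    feature_rate: float = 125.0
    marker_delay_ms: float = 30.0
    letter_duration_s: float = 0.3
    letter_stream_start_s: float = 1.0
    fade_in_s: float = 0.5
    # soundscape
    transient_rate_hz: float = 0.5
    soundscape_noise_rms: float = 0.05
    # EEG noise & artifacts
    noise_exponent: float = 1.0
    sensor_noise_frac: float = 0.1
    line_noise_amp: float = 0.0
    blink_rate_hz: float = 0.0
    blink_amp: float = 80.0
    muscle_amp: float = 0.0
    bad_channels: dict = field(default_factory=dict)  # label -> flat|noisy

    def __post_init__(self):
        if self.blocks_per_condition * 2 != self.n_blocks:
            raise ValueError("blocks_per_condition * 2 must equal n_blocks")
        if self.block_duration_s <= 0:
            raise ValueError("block duration must be positive")
        if self.letter_iti_s <= self.letter_duration_s:
            raise ValueError("letter ITI must exceed token duration")
        if self.n_channels != len(set(self.channels)):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % 2**31, *stream])
        )


def _gauss_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _component_kernel(
    rate: float, span_s: float, peaks: list[tuple[float, float, float]]
) -> np.ndarray:
    """Sum-of-Gaussians lag kernel: peaks are (latency_s, width_s, amp)."""
    t = np.arange(int(round(span_s * rate))) / rate
    k = np.zeros_like(t)
    for lat, width, amp in peaks:
        k += amp * _gauss_bump(t, lat, width)
    return k


def fronto_central_pattern(
    labels: list[str], center: str = "Cz", spread: float = 0.07,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-norm smooth topography peaking around the given electrode."""
    pos = channel_positions(list(labels))
    c = pos[list(labels).index(center)]
    pat = np.exp(-0.5 * (np.linalg.norm(pos - c, axis=1) / spread) ** 2)
    if rng is not None:
        pat = pat + 0.05 * rng.standard_normal(pat.size)
    return pat / np.linalg.norm(pat)


@dataclass
class GroundTruth:
    """Planted responses and behavioral effects of the synthetic session."""

    erp_template: np.ndarray
    erp_rate: float
    trf_kernel_env: np.ndarray
    trf_kernel_ons: np.ndarray
    kernel_rate: float
    spatial_patterns: dict
    condition_scale: float = 1.0
    time_slope: float = 0.005
    behavior_params: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, pat in self.spatial_patterns.items():
            n = np.linalg.norm(pat)
            if n == 0:
                raise ValueError(f"zero spatial pattern {name!r}")
            self.spatial_patterns[name] = np.asarray(pat, float) / n

    def kernel_for(self, kind: str) -> np.ndarray:
        return self.trf_kernel_ons if kind == "onsets" else self.trf_kernel_env

    def pattern_for(self, kind: str) -> np.ndarray:
        key = "trf_ons" if kind == "onsets" else "trf_env"
        return self.spatial_patterns[key]

    def amp_scale(self, condition: int, block: int, n_blocks: int) -> float:
        cond = self.condition_scale if condition == 1 else 1.0
        drift = 1.0 + self.time_slope * (block - (n_blocks + 1) / 2.0)
        return cond * max(drift, 0.0)


def default_behavior_params() -> dict:
    """Fixed effects, random-intercept SDs and residual SDs per outcome.

    Scales echo a 0-20 visual-analog workload scale, a surgery duration
    of one to a few minutes with an early learning curve, rare mistakes
    (0-3 per block), low tissue-damage counts, and load-dependent
    serial-recall errors.
    """
    return {
        "effort": dict(intercept=8.0, beta_cond=3.7, beta_time=0.0,
                       ri_sd=2.0, sd=3.0),
        "frustration": dict(intercept=6.0, beta_cond=2.7, beta_time=0.0,
                            ri_sd=2.0, sd=3.0),
        "distraction": dict(intercept=5.0, beta_cond=1.3, beta_time=0.0,
                            ri_sd=2.0, sd=3.0),
        "duration": dict(asymptote=110.0, learn_amp=40.0, learn_tau=8.0,
                         beta_cond=-1.8, ri_sd=8.0, sd=10.0),
        "mistakes": dict(p0=0.25, p_slope=-0.004),
        "tissue_damage": dict(b0=np.log(3.0), beta_cond=0.0,
                              beta_time=-0.02, ri_sd=0.3),
        "memory": dict(p_err_low=0.08, p_err_high=0.30, p_omit=0.08),
    }


def default_ground_truth(cfg: SynthConfig) -> GroundTruth:
    """Canonical planted responses: N1/P2/N2 morphology, fronto-central
    topographies, envelope kernel peaking earlier than the onset kernel."""
    erp = _component_kernel(cfg.eeg_fs, 0.6, [
        (0.100, 0.015, -2.0), (0.200, 0.025, 1.5), (0.250, 0.025, -1.0),
    ])
    k_env = _component_kernel(cfg.feature_rate, 0.45, [
        (0.080, 0.015, -1.0), (0.170, 0.025, 0.7), (0.270, 0.025, -0.5),
    ])
    k_ons = _component_kernel(cfg.feature_rate, 0.45, [
        (0.100, 0.015, -1.0), (0.200, 0.025, 0.7), (0.250, 0.025, -0.5),
    ])
    labels = list(cfg.channels)
    patterns = {
        "erp": fronto_central_pattern(labels, "Cz"),
        "trf_env": fronto_central_pattern(labels, "Fz"),
        "trf_ons": fronto_central_pattern(labels, "Cz"),
    }
    return GroundTruth(
        erp_template=erp, erp_rate=cfg.eeg_fs,
        trf_kernel_env=k_env, trf_kernel_ons=k_ons,
        kernel_rate=cfg.feature_rate, spatial_patterns=patterns,
        behavior_params=default_behavior_params(),
    )


def colored_noise(
    rng: np.random.Generator, n: int, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent (power) noise via spectral shaping, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_soundscape(
    cfg: SynthConfig, block: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """One block of OR-like audio: stationary colored noise, Poisson
    transients (tone pips and noise bursts) with logged onsets, and a
    linear fade-in over the first ``fade_in_s`` seconds."""
    if block >= cfg.n_blocks:
        raise ValueError(f"block {block} out of range")
    rng = cfg.rng(_S_SOUND, block)
    fs = cfg.audio_fs
    n = int(round(cfg.block_duration_s * fs))
    audio = cfg.soundscape_noise_rms * colored_noise(rng, n, 1.0)

    rows = []
    n_events = rng.poisson(cfg.transient_rate_hz * cfg.block_duration_s)
    onsets = np.sort(rng.uniform(0.0, cfg.block_duration_s, n_events))
    for onset in onsets:
        kind = rng.choice(["pip", "burst"])
        dur = rng.uniform(0.05, 0.15)
        amp = rng.uniform(0.2, 0.5)
        start = int(round(onset * fs))
        m = min(int(round(dur * fs)), n - start)
        if m <= 8:
            continue
        t = np.arange(m) / fs
        if kind == "pip":
            freq = np.exp(rng.uniform(np.log(500.0), np.log(4000.0)))
            tone = np.sin(2 * np.pi * freq * t)
        else:
            freq = np.nan
            tone = rng.standard_normal(m)
            sos = sp_signal.butter(2, [500, min(6000, fs / 2 * 0.9)],
                                   btype="bandpass", fs=fs, output="sos")
            tone = sp_signal.sosfilt(sos, tone)
            tone /= max(np.abs(tone).max(), 1e-12)
        # fast attack, exponential decay: beeps and clatter start sharply
        attack = max(2, int(round(0.005 * fs)))
        env = np.exp(-t / (dur / 3.0))
        env[:attack] *= np.linspace(0.0, 1.0, attack)
        audio[start:start + m] += amp * tone * env
        rows.append(dict(onset_s=onset, onset_sample=start, kind=kind,
                         freq=freq, duration_s=dur, amplitude=amp))

    fade = int(round(cfg.fade_in_s * fs))
    if fade > 0:
        audio[:fade] *= np.linspace(0.0, 1.0, fade)
    events = pd.DataFrame(
        rows, columns=["onset_s", "onset_sample", "kind", "freq",
                       "duration_s", "amplitude"],
    )
    return audio, events


def make_letter_stream(
    cfg: SynthConfig, forbidden: set | tuple = (), block: int = 0
) -> pd.DataFrame:
    """Letter events every ``letter_iti_s``: four admissible letters drawn
    per block, presented as shuffled groups of four with no immediate
    repetitions and none of the forbidden (to-be-remembered) letters."""
    admissible = [l for l in cfg.letter_set if l not in set(forbidden)]
    if len(admissible) < 4:
        raise ValueError("fewer than 4 admissible letters")
    rng = cfg.rng(_S_LETTER, block)
    four = list(rng.choice(admissible, size=4, replace=False))

    t0 = cfg.letter_stream_start_s
    n_events = 0
    while (t0 + n_events * cfg.letter_iti_s + cfg.letter_duration_s
           <= cfg.block_duration_s):
        n_events += 1
    letters: list[str] = []
    while len(letters) < n_events:
        group = list(rng.permutation(four))
        if letters and group[0] == letters[-1]:
            j = int(rng.integers(1, 4))
            group[0], group[j] = group[j], group[0]
        letters.extend(group)
    letters = letters[:n_events]
    onsets = t0 + np.arange(n_events) * cfg.letter_iti_s
    return pd.DataFrame({
        "onset_s": onsets, "letter": letters, "block": block,
    })


def synth_letter_token(
    rng: np.random.Generator, fs: float, duration_s: float = 0.3
) -> np.ndarray:
    """Brief formant-like token (two damped sinusoids, 10 ms ramps).

    Only onset timing and energy matter downstream; this is not speech.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f1 = rng.uniform(300, 800)
    f2 = rng.uniform(1200, 2600)
    tok = (np.sin(2 * np.pi * f1 * t) + 0.6 * np.sin(2 * np.pi * f2 * t))
    tok *= np.exp(-t / (duration_s / 2.0))
    ramp = max(1, int(round(0.010 * fs)))
    tok[:ramp] *= np.linspace(0, 1, ramp)
    tok[-ramp:] *= np.linspace(1, 0, ramp)
    return 0.5 * tok


def render_letters(
    cfg: SynthConfig, letters: pd.DataFrame, block: int = 0
) -> np.ndarray:
    """Letter-only audio track aligned to the block timeline."""
    rng = cfg.rng(_S_LETTER, block, 1)
    n = int(round(cfg.block_duration_s * cfg.audio_fs))
    out = np.zeros(n)
    for onset in letters["onset_s"]:
        tok = synth_letter_token(rng, cfg.audio_fs, cfg.letter_duration_s)
        start = int(round(onset * cfg.audio_fs))
        m = min(tok.size, n - start)
        out[start:start + m] += tok[:m]
    return out


def envelope_like_feature(
    rng: np.random.Generator, n: int, rate: float
) -> np.ndarray:
    """Envelope-like stimulus drive: non-negative low-pass modulations
    plus sparse transient bumps (the forward model standardizes)."""
    x = rng.standard_normal(n)
    sos = sp_signal.butter(2, min(8.0, rate / 2 * 0.8), fs=rate, output="sos")
    env = np.abs(sp_signal.sosfilt(sos, x))
    n_bump = max(1, int(n / rate * 0.5))
    onsets = rng.integers(0, max(1, n - int(0.2 * rate)), n_bump)
    bump = np.exp(-np.arange(int(0.15 * rate)) / (0.05 * rate))
    for o in onsets:
        m = min(bump.size, n - o)
        env[o:o + m] += rng.uniform(1.0, 3.0) * bump[:m]
    return env


def _spatial_noise(
    rng: np.random.Generator, labels: list[str], n: int,
    exponent: float, sensor_frac: float,
) -> np.ndarray:
    """Spatially smooth 1/f background: latent sources project through
    random smooth scalp topographies (volume-conduction-like) on top of a
    broad common-mode component (shared reference/far-field activity),
    plus a small independent sensor-noise floor."""
    pos = channel_positions(list(labels))
    n_ch = len(labels)
    n_src = n_ch
    centers = pos[rng.integers(0, n_ch, n_src)]
    centers = centers + 0.02 * rng.standard_normal(centers.shape)
    mix = np.exp(
        -0.5 * (np.linalg.norm(pos[:, None] - centers[None], axis=-1) / 0.07) ** 2
    )
    src = np.stack([colored_noise(rng, n, exponent) for _ in range(n_src)])
    noise = mix @ src
    noise /= noise.std()
    common = colored_noise(rng, n, exponent)
    broad = 0.8 + 0.2 * rng.uniform(size=n_ch)
    noise += 1.5 * np.outer(broad, common)
    noise /= noise.std()
    noise += sensor_frac * rng.standard_normal((n_ch, n))
    return noise / noise.std()


def simulate_eeg(
    cfg: SynthConfig,
    truth: GroundTruth,
    features: dict[str, StimulusFeature] | None,
    letters: pd.DataFrame | None,
    block: int = 0,
    participant: int = 0,
    condition: int = 0,
) -> Recording:
    """One block of EEG from the forward generative model.

    ``features`` maps feature kinds to clean stimulus drives at
    ``cfg.feature_rate``; each is convolved with its planted kernel,
    resampled to ``cfg.eeg_fs`` and projected through its spatial
    pattern. ERP templates are inserted at letter onsets. Markers carry
    the configured hardware delay (letter markers precede the true sound
    onset by ``marker_delay_ms``) so the correction stage is testable.
    """
    rng = cfg.rng(_S_EEG, participant, block)
    fs = cfg.eeg_fs
    n = int(round(cfg.block_duration_s * fs))
    labels = list(cfg.channels)
    scale = truth.amp_scale(condition, block + 1, cfg.n_blocks)

    sig = np.zeros((len(labels), n))
    for kind, feat in (features or {}).items():
        kernel = truth.kernel_for(kind)
        if kernel.size / truth.kernel_rate > cfg.block_duration_s:
            raise ValueError("kernel support exceeds block length")
        v = np.asarray(feat.values, float)
        sd = v.std()
        drive = (v - v.mean()) / sd if sd > 0 else v
        resp = np.convolve(drive, scale * kernel)[: v.size]
        if feat.rate != fs:
            up, down = (np.array([fs, feat.rate]) /
                        np.gcd(int(fs), int(feat.rate))).astype(int)
            resp = sp_signal.resample_poly(resp, up, down)
        if resp.size < n:
            resp = np.pad(resp, (0, n - resp.size))
        sig += np.outer(truth.pattern_for(kind), resp[:n])

    if letters is not None and len(letters):
        tmpl = scale * truth.erp_template
        pat = truth.spatial_patterns["erp"]
        for onset in letters["onset_s"]:
            start = int(round(onset * fs))
            m = min(tmpl.size, n - start)
            if m > 0:
                sig += np.outer(pat, np.r_[np.zeros(start), tmpl[:m],
                                           np.zeros(n - start - m)])

    noise = _spatial_noise(rng, labels, n, cfg.noise_exponent,
                           cfg.sensor_noise_frac)
    sig_rms = sig.std()
    if np.isinf(cfg.snr_db):
        data = sig
    elif sig_rms == 0:
        data = noise
    else:
        noise_rms = sig_rms / 10.0 ** (cfg.snr_db / 20.0)
        data = sig + noise_rms * noise

    if cfg.line_noise_amp > 0:
        t = np.arange(n) / fs
        data = data + cfg.line_noise_amp * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        ) * rng.uniform(0.5, 1.0, (len(labels), 1))
    if cfg.blink_rate_hz > 0:
        data = data + _blink_artifact(cfg, rng, labels, n)
    if cfg.muscle_amp > 0:
        data = data + _muscle_artifact(cfg, rng, labels, n)
    for lab, mode in cfg.bad_channels.items():
        i = labels.index(lab)
        if mode == "flat":
            data[i] = 0.0
        elif mode == "noisy":
            data[i] = 20.0 * data.std() * rng.standard_normal(n)
        else:
            raise ValueError(f"unknown bad-channel mode {mode!r}")

    delay = int(round(cfg.marker_delay_ms / 1000.0 * fs))
    rows = [dict(onset_sample=0, label="sound_start", block=block,
                 condition=condition),
            dict(onset_sample=n - 1, label="sound_stop", block=block,
                 condition=condition)]
    for _, ev in (letters if letters is not None else pd.DataFrame()).iterrows():
        rows.append(dict(
            onset_sample=int(round(ev["onset_s"] * fs)) - delay,
            label=f"letter/{ev['letter']}", block=block, condition=condition,
        ))
    markers = pd.DataFrame(rows)
    rec = Recording(data, fs, labels, markers)
    rec.meta.update(block=block, condition=condition, participant=participant)
    rec.log(f"simulate_eeg block={block} snr_db={cfg.snr_db}")
    return rec


def _blink_artifact(cfg, rng, labels, n):
    pat = np.zeros(len(labels))
    for lab, w in (("Fp1", 1.0), ("Fp2", 1.0), ("AFz", 0.8), ("F3", 0.4),
                   ("F4", 0.4), ("Fz", 0.4)):
        if lab in labels:
            pat[labels.index(lab)] = w
    series = np.zeros(n)
    width = int(round(0.3 * cfg.eeg_fs))
    n_blinks = rng.poisson(cfg.blink_rate_hz * cfg.block_duration_s)
    pulse = np.sin(np.pi * np.arange(width) / width) ** 2
    for start in rng.integers(0, max(1, n - width), n_blinks):
        series[start:start + width] += pulse
    return cfg.blink_amp * np.outer(pat, series)


def _muscle_artifact(cfg, rng, labels, n):
    pat = np.zeros(len(labels))
    for lab, w in (("M1", 1.0), ("T7", 0.7), ("P7", 0.4)):
        if lab in labels:
            pat[labels.index(lab)] = w
    series = np.zeros(n)
    width = int(round(0.5 * cfg.eeg_fs))
    hp = sp_signal.butter(4, 20.0, btype="highpass", fs=cfg.eeg_fs,
                          output="sos")
    for start in rng.integers(0, max(1, n - width), max(1, int(
            0.2 * cfg.block_duration_s))):
        burst = sp_signal.sosfilt(hp, rng.standard_normal(width))
        series[start:start + width] += burst * np.hanning(width)
    return cfg.muscle_amp * np.outer(pat, series)


def simulate_behavior(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Block table with planted condition effects and time-on-task trends.

    Ratings follow ``intercept + beta_cond * condition + participant
    intercept + noise`` clipped to the 0-20 scale; surgery duration an
    exponential learning curve; mistakes Binomial(3, p(block)); tissue
    damage Poisson with log-linear time trend; serial-recall responses
    are simulated item-wise with load-dependent error and omission ('X')
    probabilities and scored downstream by edit distance.
    """
    bp = truth.behavior_params or default_behavior_params()
    for name, pars in bp.items():
        for key, val in pars.items():
            if key.endswith("sd") and val < 0:
                raise ValueError(f"negative SD for {name}.{key}")
    rng = cfg.rng(_S_BEHAV)
    rows = []
    for p in range(cfg.n_participants):
        conds = condition_sequence(cfg, p)
        ri = {k: rng.normal(0.0, v.get("ri_sd", 0.0))
              for k, v in bp.items() if "ri_sd" in v}
        for b in range(cfg.n_blocks):
            cond = int(conds[b])
            block = b + 1
            row = dict(participant=p, block=block, condition=cond)
            for q in ("effort", "frustration", "distraction"):
                v = bp[q]
                val = (v["intercept"] + v["beta_cond"] * cond
                       + v["beta_time"] * block + ri[q]
                       + rng.normal(0.0, v["sd"]))
                row[q] = float(np.clip(val, 0.0, 20.0))
            d = bp["duration"]
            row["duration"] = float(
                d["asymptote"] + d["learn_amp"] * np.exp(-block / d["learn_tau"])
                + d["beta_cond"] * cond + ri["duration"]
                + rng.normal(0.0, d["sd"])
            )
            m = bp["mistakes"]
            pm = float(np.clip(m["p0"] + m["p_slope"] * block, 0.0, 1.0))
            row["mistakes"] = int(rng.binomial(3, pm))
            td = bp["tissue_damage"]
            lam = np.exp(td["b0"] + td["beta_cond"] * cond
                         + td["beta_time"] * block + ri["tissue_damage"])
            row["tissue_damage"] = int(rng.poisson(lam))
            mem = bp["memory"]
            load = 8 if cond == 1 else 2
            target = "".join(rng.choice(list(cfg.letter_set), size=load,
                                        replace=False))
            p_err = mem["p_err_high"] if cond == 1 else mem["p_err_low"]
            resp = []
            for ch in target:
                u = rng.uniform()
                if u < mem["p_omit"]:
                    resp.append("X")
                elif u < mem["p_omit"] + p_err:
                    resp.append(str(rng.choice(
                        [l for l in cfg.letter_set if l != ch])))
                else:
                    resp.append(ch)
            row["target"] = target
            row["response"] = "".join(resp)
            rows.append(row)
    return pd.DataFrame(rows)


def condition_sequence(cfg: SynthConfig, participant: int) -> np.ndarray:
    """Balanced low/high order: equal counts per condition, balanced over
    the two session halves when divisible, randomized per participant."""
    rng = cfg.rng(_S_BEHAV, participant, 7)
    if cfg.n_blocks % 4 == 0:
        half = cfg.n_blocks // 2
        quarters = half // 2
        seq = np.r_[rng.permutation([0] * quarters + [1] * (half - quarters)),
                    rng.permutation([0] * quarters + [1] * (half - quarters))]
    else:
        seq = rng.permutation(
            [0] * cfg.blocks_per_condition + [1] * cfg.blocks_per_condition
        )
    return seq


def save_wav(path, audio: np.ndarray, fs: float) -> None:
    """Write mono audio as 16-bit PCM WAV."""
    peak = np.abs(audio).max()
    if peak > 1.0:
        warnings.warn("audio clipped to [-1, 1] for 16-bit export")
        audio = np.clip(audio, -1.0, 1.0)
    wavfile.write(path, int(fs), (audio * 32767).astype(np.int16))


def ground_truth_to_json(truth: GroundTruth) -> dict:
    d = asdict(truth)
    for key in ("erp_template", "trf_kernel_env", "trf_kernel_ons"):
        d[key] = list(map(float, d[key]))
    d["spatial_patterns"] = {
        k: list(map(float, v)) for k, v in d["spatial_patterns"].items()
    }
    return d
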