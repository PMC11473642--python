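"""Shared demo-study configuration for the numbered analysis scripts.

A compact session — 6 participants, 8 blocks of 60 s, audio at 8 kHz,
EEG/features at 125 Hz, planted responses at 0 dB SNR — small enough to
run each script in seconds while exercising every pipeline stage.
"""

from pathlib import Path

from orsound import synth
from orsound.pipeline import simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def demo_config(**overrides) -> synth.SynthConfig:
    base = dict(
        n_participants=6, n_blocks=8, blocks_per_condition=4,
        block_duration_s=60.0, audio_fs=8000.0, eeg_fs=125.0,
        feature_rate=125.0, snr_db=0.0, seed=SEED, transient_rate_hz=0.5,
    )
    base.update(overrides)
    return synth.SynthConfig(**base)


def demo_study(**overrides):
    cfg = demo_config(**overrides)
    truth = synth.default_ground_truth(cfg)
    return simulate_study(cfg, truth)
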