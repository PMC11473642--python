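# Demo-scale study for `orsound run --config demo.yaml --seed 7`
n_participants: 4
n_blocks: 8
blocks_per_condition: 4
block_duration_s: 60.0
audio_fs: 8000.0
eeg_fs: 125.0
feature_rate: 125.0
snr_db: 0.0
transient_rate_hz: 0.5
cv_segments: 4
lambda_grid_exponents: [-6, -4, -2, 0, 2, 4, 6]
seed: 7
outdir: scratch/demo_run
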