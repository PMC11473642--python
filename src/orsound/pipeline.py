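"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes simulate -> features -> preprocess -> erp ->
trf -> ged -> stats in dependency order on a single YAML-style config,
caches stage outputs keyed on the config subtree, and writes the
model-selection table plus per-stage logs to the output directory.

The heavy lifting lives in the sibling modules; this module wires them
together and owns the study-level loops (participants x blocks x
feature kinds). The helpers (`simulate_study`, `participant_trf`,
`ged_amplitudes`, ...) are also the building blocks the tests and the
acceptance script use directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audio as aud
from . import erp as erp_mod
from . import ged as ged_mod
from . import preproc, stats, synth, trf

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("envelope_raw", "envelope_denoised", "onsets")

_CONFIG_KEYS = {
    "n_participants", "n_blocks", "blocks_per_condition",
    "block_duration_s", "audio_fs", "eeg_fs", "feature_rate",
    "letter_iti_s", "snr_db", "seed", "transient_rate_hz", "cv_segments",
    "lambda_grid_exponents", "marker_delay_ms", "blink_rate_hz",
    "line_noise_amp", "bad_channels", "outdir", "figures", "stages",
}


@dataclass
class PipelineConfig:
    """Validated study/pipeline configuration (schema-checked YAML)."""

    n_participants: int = 4
    n_blocks: int = 8
    blocks_per_condition: int = 4
    block_duration_s: float = 60.0
    audio_fs: float = 8000.0
    eeg_fs: float = 125.0
    feature_rate: float = 125.0
    letter_iti_s: float = 3.0
    snr_db: float = 0.0
    seed: int = 0
    transient_rate_hz: float = 0.5
    cv_segments: int = 4
    lambda_grid_exponents: tuple = tuple(range(-8, 9))
    marker_delay_ms: float = 30.0
    blink_rate_hz: float = 0.0
    line_noise_amp: float = 0.0
    bad_channels: dict = field(default_factory=dict)
    outdir: str = "orsound_out"
    figures: bool = False
    stages: tuple = ("simulate", "features", "preprocess", "erp", "trf",
                     "ged", "stats")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            n_participants=self.n_participants, n_blocks=self.n_blocks,
            blocks_per_condition=self.blocks_per_condition,
            block_duration_s=self.block_duration_s, audio_fs=self.audio_fs,
            eeg_fs=self.eeg_fs, feature_rate=self.feature_rate,
            letter_iti_s=self.letter_iti_s, snr_db=self.snr_db,
            seed=self.seed, transient_rate_hz=self.transient_rate_hz,
            marker_delay_ms=self.marker_delay_ms,
            blink_rate_hz=self.blink_rate_hz,
            line_noise_amp=self.line_noise_amp,
            bad_channels=dict(self.bad_channels),
        )

    def hash(self, keys=None) -> str:
        d = {k: getattr(self, k) for k in sorted(_CONFIG_KEYS - {"outdir"})}
        if keys is not None:
            d = {k: d[k] for k in keys}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# study-level building blocks

def simulate_block_audio(cfg: synth.SynthConfig, block: int):
    """Soundscape audio, transient-only track, logged events and letter
    stream for one block (audio shared across participants, as a single
    playback would be)."""
    rng = cfg.rng(99, block)
    noise_only = synth.SynthConfig(**{**_cfg_dict(cfg),
                                      "transient_rate_hz": 0.0})
    base, _ = synth.make_soundscape(noise_only, block)
    full, events = synth.make_soundscape(cfg, block)
    transients = full - base
    del rng
    letters = synth.make_letter_stream(cfg, block=block)
    return full, transients, events, letters


def _cfg_dict(cfg: synth.SynthConfig) -> dict:
    from dataclasses import asdict
    d = asdict(cfg)
    return d


def clean_drives(cfg: synth.SynthConfig, transients: np.ndarray,
                 events: pd.DataFrame, block: int) -> dict:
    """Noise-free stimulus drives for the EEG forward model: the envelope
    of the transient-only track and the true event-onset vector."""
    env = aud.extract_envelope(transients + 1e-12, cfg.audio_fs,
                               cfg.feature_rate, block=block)
    n = env.values.size
    ons = np.zeros(n)
    idx = np.round(events["onset_s"].to_numpy() * cfg.feature_rate).astype(int)
    ons[idx[(idx >= 0) & (idx < n)]] = 1.0
    return {
        "envelope_denoised": env,
        "onsets": aud.StimulusFeature(ons, cfg.feature_rate, "onsets", block),
    }


def extract_block_features(cfg: synth.SynthConfig, audio_wave: np.ndarray,
                           block: int) -> dict:
    """The three measured features of one block of playback audio."""
    fs, rate = cfg.audio_fs, cfg.feature_rate
    den = aud.wiener_denoise(audio_wave, fs)
    return {
        "envelope_raw": aud.extract_envelope(audio_wave, fs, rate,
                                             block=block),
        "envelope_denoised": aud.extract_envelope(
            den, fs, rate, kind="envelope_denoised", block=block),
        "onsets": aud.detect_onsets(audio_wave, fs, rate, block=block),
    }


def simulate_study(cfg: synth.SynthConfig, truth: synth.GroundTruth,
                   with_audio_features: bool = True) -> dict:
    """Generate the full synthetic study.

    Returns a dict with per-block audio features (measured from the
    shared playback), per-(participant, block) EEG recordings driven by
    the clean transient envelope and true onsets, letter streams, and
    the behavioral block table.
    """
    blocks = range(cfg.n_blocks)
    features, letters_by_block, drives = {}, {}, {}
    for b in blocks:
        full, transients, events, letters = simulate_block_audio(cfg, b)
        letters_by_block[b] = letters
        drives[b] = clean_drives(cfg, transients, events, b)
        if with_audio_features:
            features[b] = extract_block_features(cfg, full, b)
    recordings = {}
    for p in range(cfg.n_participants):
        conds = synth.condition_sequence(cfg, p)
        for b in blocks:
            recordings[(p, b)] = synth.simulate_eeg(
                cfg, truth, drives[b], letters_by_block[b],
                block=b, participant=p, condition=int(conds[b]),
            )
    behavior = synth.simulate_behavior(cfg, truth)
    behavior["memory_score"] = [
        stats.memory_score(t, r)
        for t, r in zip(behavior["target"], behavior["response"])
    ]
    return dict(features=features, drives=drives, letters=letters_by_block,
                recordings=recordings, behavior=behavior, truth=truth,
                cfg=cfg)


def preprocess_recording(rec: preproc.Recording,
                         full_pipeline: bool = False) -> preproc.Recording:
    """Per-block cleaning. The full variant (filter, channel rejection,
    ICA, interpolation, re-reference) is exercised in dedicated tests;
    the default applies the filter and re-reference only, which is what
    short per-block segments support."""
    out = preproc.bandpass_fir(rec)
    if full_pipeline:
        out = preproc.reject_bad_channels(out)
        out, _ = preproc.ica_clean(out)
    out = preproc.interpolate_and_reref(out)
    return out


def participant_trf(
    study: dict, participant: int, kind: str,
    lam_grid=None, k: int | None = None, lag_max_ms: float = 450.0,
    use_clean_drive: bool = False,
) -> dict:
    """Cross-validated TRF analysis of one participant and feature kind.

    Returns the lambda search record, held-out prediction accuracy, and
    z-scored per-block TRFs at the modal lambda.
    """
    cfg = study["cfg"]
    lam_grid = (trf.DEFAULT_LAMBDA_GRID if lam_grid is None
                else tuple(lam_grid))
    k = k or min(10, cfg.n_blocks)
    feats, eegs = [], []
    for b in range(cfg.n_blocks):
        source = study["drives"] if use_clean_drive else study["features"]
        feats.append(np.asarray(source[b][kind].values, float))
        rec = study["recordings"][(participant, b)]
        eeg = trf.scale_eeg(rec.data.T)
        n = min(len(feats[-1]), eeg.shape[0])
        feats[-1] = feats[-1][:n]
        eegs.append(eeg[:n])
    cv = trf.crossval_lambda(feats, eegs, cfg.feature_rate, grid=lam_grid,
                             lag_max_ms=lag_max_ms, k=k, kind=kind)
    pred = trf.prediction_accuracy(feats, eegs, cfg.feature_rate,
                                   cv.best_lambda, lag_max_ms=lag_max_ms,
                                   k=k, kind=kind)
    models = trf.per_block_trf(feats, eegs, cfg.feature_rate, cv, kind=kind)
    return dict(cv=cv, prediction=pred, models=models)


def block_erps(study: dict, participant: int,
               sd_threshold: float = 3.0) -> dict:
    """Delay-corrected epoching and per-block average ERPs."""
    cfg = study["cfg"]
    out = {}
    for b in range(cfg.n_blocks):
        rec = study["recordings"][(participant, b)]
        rec = rec.copy()
        is_letter = rec.markers["label"].str.startswith("letter/")
        shifted = aud.correct_marker_delay(
            rec.markers[is_letter], rec.fs, cfg.marker_delay_ms,
            rec.n_samples)
        rec.markers = pd.concat([rec.markers[~is_letter], shifted],
                                ignore_index=True)
        epochs, times_ms, _ = erp_mod.epoch_letters(rec)
        epochs = erp_mod.baseline_correct(epochs, times_ms)
        out[b] = erp_mod.average_block(
            epochs, times_ms, sd_threshold,
            participant=participant, block=b,
            condition=int(rec.meta.get("condition", 0)),
        )
    return out


def ged_amplitudes(
    responses: dict, times_ms: np.ndarray, labels: list[str],
    response_family: str, component: str,
) -> tuple[pd.DataFrame, ged_mod.GEDFilter, float]:
    """Cross-participant GED filter and per-block component amplitudes.

    ``responses`` maps (participant, block) -> channels x time arrays on
    a common time axis (participant means are formed internally).
    """
    spec = ged_mod.WindowSpec(response_family, component)
    participants = sorted({p for p, _ in responses})
    means = {
        p: np.mean([r for (pp, _), r in responses.items() if pp == p],
                   axis=0)
        for p in participants
    }
    grand = np.mean(list(means.values()), axis=0)
    peak_ms, _, _ = ged_mod.find_peak(grand, times_ms, spec)
    S_list, R_list = [], []
    for p in participants:
        S, R = ged_mod.window_covariances(means[p], times_ms, peak_ms, spec)
        S_list.append(S)
        R_list.append(R)
    Sbar, Rbar, excluded = ged_mod.clean_and_average(S_list, R_list)
    filt = ged_mod.ged_decompose(Sbar, Rbar)
    filt.excluded = excluded
    filt = ged_mod.select_component(filt, spec, grand, times_ms, peak_ms,
                                    labels)
    table = ged_mod.component_amplitudes(filt, responses, times_ms,
                                         peak_ms, spec)
    return table, filt, peak_ms


# --------------------------------------------------------------------------
# staged runner with caching

def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Execute all stages; cache on config hash; return the result dict.

    Outputs written under ``outdir``: behavior table, prediction
    accuracies, amplitude table, model-selection summary, the resolved
    config with its content hash, and (optionally) figures.
    """
    t0 = time.time()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    cache_file = out / "pipeline_cache.json"
    if cache_file.exists():
        cached = json.loads(cache_file.read_text())
        if cached.get("config_hash") == chash and (
                out / "model_selection.json").exists():
            logger.info("cache hit (%s); skipping recomputation", chash)
            return json.loads((out / "model_selection.json").read_text())

    from dataclasses import asdict
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump({**asdict(config), "config_hash": chash}))

    cfg = config.synth_config()
    truth = synth.default_ground_truth(cfg)
    study = simulate_study(cfg, truth)
    study["behavior"].to_csv(out / "block_table.csv", index=False)

    # TRF predictions per participant x feature
    pred_rows, amp_frames = [], []
    trf_results = {}
    for kind in FEATURE_KINDS:
        for p in range(cfg.n_participants):
            res = participant_trf(study, p, kind, k=config.cv_segments,
                                  lam_grid=[10.0**e for e in
                                            config.lambda_grid_exponents])
            trf_results[(kind, p)] = res
            pred_rows.append(dict(participant=p, kind=kind,
                                  r=res["prediction"]["r"],
                                  lam=res["cv"].best_lambda))
    pred_df = pd.DataFrame(pred_rows)
    pred_df.to_csv(out / "trf_predictions.csv", index=False)

    # feature comparison (pairwise Wilcoxon, Bonferroni m=3)
    comparisons = {}
    wide = pred_df.pivot(index="participant", columns="kind", values="r")
    pairs = [("envelope_denoised", "envelope_raw"),
             ("onsets", "envelope_raw"),
             ("envelope_denoised", "onsets")]
    for a, b in pairs:
        res = stats.wilcoxon_signed_rank(wide[a], wide[b])
        comparisons[f"{a}_vs_{b}"] = dict(W=res.W, p=res.p, n=res.n_used)
    alpha_feat = stats.bonferroni_alpha(0.05, len(pairs), display=True)

    # ERPs and GED amplitudes
    responses = {}
    times_ms = None
    for p in range(cfg.n_participants):
        for b, be in block_erps(study, p).items():
            if not be.empty:
                responses[(p, b)] = be.data
                times_ms = be.times_ms
    amp_frames = []
    for comp in ("N1", "P2", "N2"):
        table, _, _ = ged_amplitudes(responses, times_ms,
                                     list(cfg.channels), "ERP", comp)
        amp_frames.append(table)
    amps = pd.concat(amp_frames, ignore_index=True)
    amps.to_csv(out / "ged_amplitudes.csv", index=False)

    # statistics layer
    behavior = study["behavior"]
    selection = {}
    for outcome in ("effort", "frustration", "distraction", "duration"):
        fits = [stats.fit_lmm(behavior, outcome, f) for f in (1, 2, 3)]
        chosen, table = stats.lrt_select(fits)
        selection[outcome] = _fit_json(chosen, table)
    for outcome in ("mistakes", "tissue_damage"):
        try:
            fits = [stats.fit_glmm_poisson(behavior, outcome, f)
                    for f in (1, 2, 3)]
            chosen, table = stats.lrt_select(fits)
            selection[outcome] = _fit_json(chosen, table)
        except (ValueError, RuntimeError) as err:
            selection[outcome] = {"error": str(err)}
    fits = [stats.fit_clmm(behavior, "memory_score", f) for f in (1, 2)]
    chosen, table = stats.lrt_select(fits)
    selection["memory_score"] = _fit_json(chosen, table)

    cond_erp = behavior.set_index(["participant", "block"])
    amps = amps.merge(
        behavior[["participant", "block", "condition"]],
        left_on=["participant", "block"],
        right_on=["participant", "block"], how="left",
    )
    amps["block"] = amps["block"].astype(int)
    for comp in ("N1", "P2", "N2"):
        sub = amps[amps["component"] == comp].rename(
            columns={"amplitude": "amp"})
        sub = sub.dropna(subset=["amp"])
        if sub["participant"].nunique() >= 2:
            fits = [stats.fit_lmm(sub, "amp", f) for f in (1, 2, 3)]
            chosen, table = stats.lrt_select(fits)
            selection[f"erp_{comp}"] = _fit_json(chosen, table)
    del cond_erp

    report = {
        "config_hash": chash,
        "alpha_bonferroni_responses": stats.bonferroni_alpha(
            0.05, 3, display=True),
        "alpha_bonferroni_features": alpha_feat,
        "feature_comparisons": comparisons,
        "prediction_mean_r": {
            k: float(pred_df[pred_df["kind"] == k]["r"].mean())
            for k in FEATURE_KINDS
        },
        "model_selection": selection,
        "elapsed_s": round(time.time() - t0, 1),
    }
    (out / "model_selection.json").write_text(json.dumps(report, indent=2))
    cache_file.write_text(json.dumps({"config_hash": chash}))
    if config.figures:
        try:
            _figures(out, study, trf_results, amps)
        except Exception as err:  # pragma: no cover - plotting best-effort
            warnings.warn(f"figure generation failed: {err}")
    return report


def _fit_json(fit: stats.ModelFit, table: pd.DataFrame) -> dict:
    return {
        "model": fit.formula_id,
        "method": fit.method,
        "beta": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "lrt": table.to_dict(orient="records"),
    }


def _figures(out: Path, study, trf_results, amps):  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    cfg = study["cfg"]
    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    for ax, kind in zip(axes, FEATURE_KINDS):
        f = study["features"][0][kind]
        ax.plot(f.times, f.values, lw=0.5)
        ax.set_ylabel(kind, fontsize=8)
    axes[-1].set_xlabel("time (s)")
    fig.savefig(figdir / "features_block0.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    for (kind, p), res in trf_results.items():
        if p == 0:
            w = np.mean([m.weights for m in res["models"]], axis=0)
            ax.plot(res["models"][0].lags_ms, w.mean(axis=1), label=kind)
    ax.legend()
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("z-scored weight")
    fig.savefig(figdir / "trf_morphology.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    for cond, g in amps[amps["component"] == "N1"].groupby("condition"):
        m = g.groupby("block")["amplitude"].mean()
        ax.plot(m.index, m.values, marker="o", label=f"condition {cond}")
    ax.legend()
    ax.set_xlabel("block")
    ax.set_ylabel("N1 amplitude")
    fig.savefig(figdir / "amplitude_by_block.png", dpi=100)
    plt.close(fig)
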