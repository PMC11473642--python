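"""EEG cleaning: filtering, segment restriction, channel/epoch rejection,
ICA artifact removal, interpolation and mastoid re-referencing.

The pipeline order is fixed and recorded in the ``history`` of every
:class:`Recording`: band-pass filter -> restrict to sound presentation ->
iterative bad-channel detection -> ICA cleanup (fit on a 1 Hz high-passed
copy, applied to the unfiltered data) -> spherical-spline interpolation of
bad channels -> re-reference to linked mastoids (M1/M2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

import mne

mne.set_log_level("ERROR")

#: 24-channel mobile montage (10-20 positions, mastoids included).
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "AFz", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8", "CPz", "Pz", "M1", "M2",
    "P3", "P4", "P7", "P8", "POz", "O1", "O2",
]

_FRONTAL = ("Fp1", "Fp2", "AFz")
_EDGE = ("M1", "M2", "T7", "T8", "F7", "F8", "P7", "P8")


def standard_montage() -> mne.channels.DigMontage:
    for name in ("standard_1005",):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return mne.channels.make_standard_montage(name)
        except ValueError:  # pragma: no cover - future mne renames
            continue
    return mne.channels.make_standard_montage("colin27_1005")


def channel_positions(labels: list[str]) -> np.ndarray:
    """3-D electrode positions (meters) for the given 10-20 labels."""
    pos = standard_montage().get_positions()["ch_pos"]
    return np.array([pos[lab] for lab in labels])


@dataclass
class Recording:
    """Multichannel EEG with markers and processing history.

    ``data`` is channels x samples in microvolts; ``markers`` is an event
    table with at least ``onset_sample`` and ``label`` columns.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["onset_sample", "label", "block", "condition"]
        )
    )
    bads: list[str] = field(default_factory=list)
    history: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("data row count must equal number of labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            self.fs,
            list(self.labels),
            self.markers.copy(),
            list(self.bads),
            list(self.history),
            dict(self.meta),
        )

    def log(self, step: str) -> None:
        self.history.append(step)

    def positions(self) -> np.ndarray:
        return channel_positions(self.labels)

    def to_mne(self, picks: list[str] | None = None) -> mne.io.RawArray:
        labels = picks if picks is not None else self.labels
        idx = [self.labels.index(lab) for lab in labels]
        info = mne.create_info(labels, self.fs, ch_types="eeg")
        raw = mne.io.RawArray(self.data[idx] * 1e-6, info, verbose="ERROR")
        raw.set_montage(standard_montage(), on_missing="ignore")
        raw.info["bads"] = [b for b in self.bads if b in labels]
        return raw


def bandpass_fir(
    rec: Recording,
    hp_edge: float = 0.5,
    lp_edge: float = 30.0,
    hp_trans: float = 0.5,
    lp_trans: float = 7.5,
) -> Recording:
    """Zero-phase Hamming-window FIR band-pass (high-pass then low-pass).

    With the stated transition bands the automatic filter-length rule
    (3.3 / bandwidth * fs) yields orders 3300 (high-pass) and 220
    (low-pass) at 500 Hz, scaling proportionally for other rates. Edges
    at or above Nyquist raise.
    """
    nyq = rec.fs / 2.0
    for edge in (hp_edge, lp_edge):
        if edge is not None and edge >= nyq:
            raise ValueError(f"filter edge {edge} Hz >= Nyquist {nyq} Hz")
    out = rec.copy()
    if hp_edge is not None:
        out.data = mne.filter.filter_data(
            out.data, rec.fs, l_freq=hp_edge, h_freq=None,
            filter_length="auto", l_trans_bandwidth=hp_trans,
            fir_window="hamming",
            phase="zero", verbose="ERROR",
        )
    if lp_edge is not None:
        out.data = mne.filter.filter_data(
            out.data, rec.fs, l_freq=None, h_freq=lp_edge,
            filter_length="auto", h_trans_bandwidth=lp_trans,
            fir_window="hamming",
            phase="zero", verbose="ERROR",
        )
    out.log(f"bandpass_fir hp={hp_edge} lp={lp_edge}")
    return out


def restrict_to_sound(
    rec: Recording, trim_s: float = 5.0, min_duration_s: float = 10.0
) -> list[Recording]:
    """Cut one segment per block spanning (sound_start + trim, sound_stop - trim).

    Segments shorter than ``min_duration_s`` are dropped with a warning.
    Already-restricted segments pass through unchanged (idempotent).
    """
    if rec.meta.get("restricted"):
        return [rec]
    m = rec.markers
    starts = m[m["label"] == "sound_start"]
    stops = m[m["label"] == "sound_stop"]
    segments: list[Recording] = []
    blocks = sorted(set(starts["block"]) | set(stops["block"]))
    for block in blocks:
        s = starts[starts["block"] == block]
        e = stops[stops["block"] == block]
        if len(s) != 1 or len(e) != 1:
            raise ValueError(f"unpaired sound markers in block {block}")
        a = int(s["onset_sample"].iloc[0] + trim_s * rec.fs)
        b = int(e["onset_sample"].iloc[0] - trim_s * rec.fs)
        if (b - a) / rec.fs < min_duration_s:
            warnings.warn(
                f"block {block}: segment shorter than {min_duration_s} s; "
                "dropped"
            )
            continue
        seg_markers = m[
            (m["onset_sample"] >= a) & (m["onset_sample"] < b)
            & ~m["label"].isin(["sound_start", "sound_stop"])
        ].copy()
        seg_markers["onset_sample"] = seg_markers["onset_sample"] - a
        seg = Recording(
            rec.data[:, a:b].copy(), rec.fs, list(rec.labels), seg_markers,
            list(rec.bads), list(rec.history), dict(rec.meta),
        )
        cond = s["condition"].iloc[0] if "condition" in s.columns else None
        seg.meta.update(restricted=True, block=block, condition=cond)
        seg.log(f"restrict_to_sound block={block} trim={trim_s}s")
        segments.append(seg)
    return segments


def _neighbor_sets(pos: np.ndarray, n_neighbors: int = 8) -> np.ndarray:
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1)[:, :n_neighbors], d


def reject_bad_channels(
    rec: Recording,
    criterion: float = 0.8,
    max_broken: float = 0.5,
    iterations: int = 10,
    vote: float = 0.5,
    max_remove: int = 5,
    window_s: float = 5.0,
    n_neighbors: int = 8,
    n_sample: int = 4,
    seed: int = 0,
) -> Recording:
    """Iterative correlation-to-reconstruction bad-channel detection.

    In each of ``iterations`` seeded passes, every channel is reconstructed
    in 5 s windows from a random subset of its nearest neighbours
    (inverse-distance weighting); a channel is flagged in a pass when its
    correlation with the reconstruction falls below ``criterion`` in more
    than ``max_broken`` of windows. Channels flagged in at least ``vote``
    of passes enter ``bads``, worst-first, capped at ``max_remove``. Data
    are unchanged.
    """
    pos = rec.positions()
    if pos.shape[0] != rec.n_channels:
        raise ValueError("montage positions missing for some channels")
    neighbors, dist = _neighbor_sets(pos, n_neighbors)
    win = int(round(window_s * rec.fs))
    n_win = max(1, rec.n_samples // win)
    rng = np.random.default_rng(seed)

    votes = np.zeros(rec.n_channels)
    mean_corr = np.zeros(rec.n_channels)
    all_windows = np.arange(n_win)
    for _ in range(iterations):
        # consensus reconstruction: on a random subsample of windows,
        # rank each channel's neighbours by correlation and reconstruct
        # from the best n_sample of them — a good channel with broken
        # neighbours finds its good ones, a broken channel finds none
        sub = rng.choice(all_windows, size=max(1, int(0.6 * n_win)),
                         replace=False)
        sel = np.concatenate([np.arange(k * win, (k + 1) * win)
                              for k in sub])
        corr = np.zeros((rec.n_channels, n_win))
        for c in range(rec.n_channels):
            nb = neighbors[c]
            x = rec.data[c, sel]
            xs = x.std()
            nb_corr = np.zeros(nb.size)
            for j, other in enumerate(nb):
                o = rec.data[other, sel]
                if xs > 0 and o.std() > 0:
                    nb_corr[j] = np.corrcoef(x, o)[0, 1]
            pick = nb[np.argsort(nb_corr)[::-1][:n_sample]]
            w = 1.0 / dist[c, pick]
            recon = (w[:, None] * rec.data[pick]).sum(axis=0) / w.sum()
            for k in range(n_win):
                a = rec.data[c, k * win:(k + 1) * win]
                b = recon[k * win:(k + 1) * win]
                if a.std() == 0 or b.std() == 0:
                    corr[c, k] = 0.0
                else:
                    corr[c, k] = np.corrcoef(a, b)[0, 1]
        broken = (corr < criterion).mean(axis=1) > max_broken
        votes += broken
        mean_corr += corr.mean(axis=1)
    mean_corr /= iterations

    flagged = np.flatnonzero(votes >= vote * iterations)
    order = flagged[np.argsort(mean_corr[flagged])]  # worst first
    out = rec.copy()
    out.bads = [rec.labels[i] for i in order[:max_remove]]
    out.log(
        f"reject_bad_channels removed={out.bads} "
        f"(flagged {len(flagged)}, cap {max_remove})"
    )
    return out


def jointprob_reject(
    epochs: np.ndarray, sd_threshold: float
) -> np.ndarray:
    """Joint-probability epoch rejection; returns a kept-epoch mask.

    Per channel an empirical amplitude density is estimated by histogram
    (Scott's rule). Each epoch's improbability is its negative mean
    log-density, per channel (local measure) and summed over channels
    (global measure). Epochs exceeding mean + ``sd_threshold`` * SD on
    either measure are rejected.
    """
    epochs = np.asarray(epochs, dtype=float)
    n_ep, n_ch, _ = epochs.shape
    if n_ep < 10:
        raise ValueError("need at least 10 epochs for density estimation")
    jp = np.zeros((n_ep, n_ch))
    for c in range(n_ch):
        pooled = epochs[:, c, :].ravel()
        sd = pooled.std()
        if sd == 0:
            warnings.warn("zero-variance channel in jointprob; skipped")
            continue
        # Scott's rule bin width
        h = 3.49 * sd * pooled.size ** (-1.0 / 3.0)
        nbins = max(10, int(np.ceil(np.ptp(pooled) / h)))
        hist, edges = np.histogram(pooled, bins=nbins, density=True)
        hist = np.clip(hist, 1e-12, None)
        idx = np.clip(
            np.searchsorted(edges, epochs[:, c, :], side="right") - 1,
            0, nbins - 1,
        )
        jp[:, c] = -np.log(hist[idx]).mean(axis=1)

    def _z(x):
        s = np.asarray(x.std(axis=0), dtype=float)
        mu = x.mean(axis=0)
        # degenerate spread (identical epochs up to float noise) -> z = 0
        s = np.where(s <= 1e-9 * (np.abs(mu) + 1e-30), 0.0, s)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / s
        return np.where(np.isfinite(z), z, 0.0)

    local = _z(jp)
    glob = _z(jp.sum(axis=1))
    if np.all(local == 0) and np.all(glob == 0):
        warnings.warn("identical epochs: jointprob rejects nothing")
        return np.ones(n_ep, dtype=bool)
    reject = (local.max(axis=1) > sd_threshold) | (glob > sd_threshold)
    return ~reject


def _band_fraction(source: np.ndarray, fs: float, lo: float, hi: float) -> float:
    f, pxx = sp_signal.welch(source, fs=fs, nperseg=min(source.size, 1024))
    total = pxx.sum()
    if total == 0:
        return 0.0
    band = pxx[(f >= lo) & (f <= hi)].sum()
    return float(band / total)


def classify_components(
    patterns: np.ndarray,
    sources: np.ndarray,
    labels: list[str],
    fs: float,
    frontal_ratio: float = 1.8,
    edge_ratio: float = 1.8,
    low_frac: float = 0.5,
    high_frac: float = 0.6,
) -> list[str]:
    """Heuristic IC classification: blink / muscle / horizontal-eye / brain.

    A component is a blink candidate when its topography is dominated by
    the fronto-polar channels and its source power concentrates below
    3 Hz; a muscle candidate when mastoid/temporal-edge channels dominate
    and >20 Hz power exceeds ``high_frac`` of the total; a horizontal eye
    movement when the lateral-frontal pair carries a strong opposite-sign
    dipole.
    """
    out = []
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    front = [lab_idx[l] for l in _FRONTAL if l in lab_idx]
    edge = [lab_idx[l] for l in _EDGE if l in lab_idx]
    lf = [lab_idx[l] for l in ("F7", "Fp1") if l in lab_idx]
    rf = [lab_idx[l] for l in ("F8", "Fp2") if l in lab_idx]
    for j in range(patterns.shape[1]):
        p = patterns[:, j]
        mean_abs = np.abs(p).mean()
        if mean_abs == 0:
            out.append("brain")
            continue
        fr = np.abs(p[front]).mean() / mean_abs if front else 0.0
        er = np.abs(p[edge]).mean() / mean_abs if edge else 0.0
        lofrac = _band_fraction(sources[j], fs, 0.0, 3.0)
        hifrac = _band_fraction(sources[j], fs, 20.0, fs / 2.0)
        if fr > frontal_ratio and lofrac > low_frac:
            out.append("blink")
        elif er > edge_ratio and hifrac > high_frac:
            out.append("muscle")
        elif (
            lf and rf
            and np.sign(p[lf].mean()) != np.sign(p[rf].mean())
            and (np.abs(p[lf]).mean() + np.abs(p[rf]).mean()) / 2 / mean_abs
            > frontal_ratio
        ):
            out.append("horizontal_eye")
        else:
            out.append("brain")
    return out


def ica_clean(
    rec: Recording,
    hp_for_ica: float = 1.0,
    epoch_s: float = 1.0,
    sd: float = 5.0,
    manual_remove: list[int] | None = None,
    min_samples_factor: float = 20.0,
    random_state: int = 0,
    method: str = "fastica",
) -> tuple[Recording, dict]:
    """ICA artifact removal fit on a high-passed copy, applied to the data.

    A copy of the recording is high-pass filtered at ``hp_for_ica``, cut
    into consecutive ``epoch_s`` epochs, cleaned by joint-probability
    rejection at ``sd`` SD, and decomposed with (extended) infomax ICA.
    Components flagged by :func:`classify_components` (plus any manual
    overrides) are zeroed and the mixing is back-projected onto the
    original, unfiltered data. Bad channels are left untouched.
    """
    good = [lab for lab in rec.labels if lab not in rec.bads]
    gidx = [rec.labels.index(lab) for lab in good]
    n_good = len(good)
    if rec.n_samples < min_samples_factor * n_good**2:
        raise ValueError(
            f"too few samples for stable ICA: {rec.n_samples} < "
            f"{min_samples_factor} * {n_good}^2"
        )
    # high-passed copy for decomposition
    filt = mne.filter.filter_data(
        rec.data[gidx], rec.fs, l_freq=hp_for_ica, h_freq=None,
        filter_length="auto", l_trans_bandwidth=1.0,
        fir_window="hamming", phase="zero", verbose="ERROR",
    )
    win = int(round(epoch_s * rec.fs))
    n_ep = filt.shape[1] // win
    epochs = filt[:, : n_ep * win].reshape(n_good, n_ep, win)
    epochs = np.moveaxis(epochs, 0, 1)  # epochs x ch x time
    mask = jointprob_reject(epochs, sd)
    kept = epochs[mask].transpose(1, 0, 2).reshape(n_good, -1)

    info = mne.create_info(good, rec.fs, ch_types="eeg")
    raw_fit = mne.io.RawArray(kept * 1e-6, info, verbose="ERROR")
    raw_fit.set_montage(standard_montage(), on_missing="ignore")
    fit_params = {"extended": True} if method == "infomax" else None
    ica = mne.preprocessing.ICA(
        method=method, fit_params=fit_params, random_state=random_state,
        max_iter=1000,
    )
    ica.fit(raw_fit, verbose="ERROR")

    patterns = ica.get_components()
    sources = ica.get_sources(raw_fit).get_data()
    classes = classify_components(patterns, sources, good, rec.fs)
    exclude = [j for j, c in enumerate(classes) if c != "brain"]
    for j in manual_remove or []:
        if j not in exclude:
            exclude.append(j)

    raw_orig = mne.io.RawArray(
        rec.data[gidx].copy() * 1e-6, info.copy(), verbose="ERROR"
    )
    ica.apply(raw_orig, exclude=exclude, verbose="ERROR")
    out = rec.copy()
    out.data[gidx] = raw_orig.get_data() * 1e6
    out.log(
        f"ica_clean removed={exclude} classes="
        f"{[classes[j] if j < len(classes) else 'manual' for j in exclude]} "
        f"epochs_kept={int(mask.sum())}/{n_ep}"
    )
    report = {
        "classes": classes,
        "exclude": exclude,
        "n_epochs_kept": int(mask.sum()),
        "n_epochs": n_ep,
    }
    return out, report


def interpolate_and_reref(rec: Recording, max_bads: int = 5) -> Recording:
    """Spherical-spline interpolation of bad channels, then linked-mastoid
    re-reference (every channel minus the M1/M2 mean)."""
    if len(rec.bads) > max_bads:
        raise ValueError(
            f"{len(rec.bads)} bad channels exceed the cap of {max_bads}"
        )
    out = rec.copy()
    if out.bads:
        raw = out.to_mne()
        raw.interpolate_bads(reset_bads=True, verbose="ERROR")
        out.data = raw.get_data() * 1e6
        out.bads = []
    for m in ("M1", "M2"):
        if m not in out.labels:
            raise ValueError(f"mastoid channel {m} missing")
    ref = out.data[[out.labels.index("M1"), out.labels.index("M2")]].mean(axis=0)
    out.data = out.data - ref
    out.log("interpolate_and_reref ref=linked-mastoids")
    return out
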