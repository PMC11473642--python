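"""Event-related potentials to the spoken-letter stream.

Epochs span -200..600 ms around each (delay- and onset-corrected) letter
marker, are baseline-corrected over -200..0 ms, screened by
joint-probability rejection at 3 SD, and averaged per (participant,
block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preproc import Recording, jointprob_reject


@dataclass
class BlockERP:
    """Average evoked response of one (participant, block)."""

    data: np.ndarray  # channels x time, empty if no epochs survived
    times_ms: np.ndarray
    n_epochs_kept: int
    n_epochs_total: int
    participant: int = 0
    block: int = 0
    condition: int = 0
    mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def empty(self) -> bool:
        return self.data.size == 0


def epoch_times(fs: float, tmin_s: float = -0.2, tmax_s: float = 0.6):
    samples = np.arange(int(round(tmin_s * fs)), int(round(tmax_s * fs)) + 1)
    return samples, samples / fs * 1000.0


def epoch_letters(
    rec: Recording, tmin_s: float = -0.2, tmax_s: float = 0.6
) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract one epoch per letter fully inside the segment.

    Returns ``(epochs, times_ms, n_dropped)`` with epochs shaped
    epochs x channels x time; letters whose epoch would cross a segment
    boundary are dropped (never zero-padded) and counted.
    """
    rel, times_ms = epoch_times(rec.fs, tmin_s, tmax_s)
    letters = rec.markers[rec.markers["label"].str.startswith("letter/")]
    epochs, dropped = [], 0
    for onset in letters["onset_sample"].astype(int):
        lo, hi = onset + rel[0], onset + rel[-1]
        if lo < 0 or hi >= rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, onset + rel])
    if not epochs:
        return np.empty((0, rec.n_channels, rel.size)), times_ms, dropped
    return np.stack(epochs), times_ms, dropped


def baseline_correct(
    epochs: np.ndarray, times_ms: np.ndarray,
    window_ms: tuple[float, float] = (-200.0, 0.0),
) -> np.ndarray:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("empty baseline window")
    return epochs - epochs[..., sel].mean(axis=-1, keepdims=True)


def average_block(
    epochs: np.ndarray,
    times_ms: np.ndarray,
    sd_threshold: float = 3.0,
    mask: np.ndarray | None = None,
    **ids,
) -> BlockERP:
    """Joint-probability screening (3 SD default) then arithmetic mean.

    A precomputed kept-epoch ``mask`` may be supplied; otherwise it is
    derived here. All-rejected blocks yield an empty entry with a
    warning.
    """
    n_total = epochs.shape[0]
    if mask is None:
        if n_total >= 10:
            mask = jointprob_reject(epochs, sd_threshold)
        else:
            mask = np.ones(n_total, dtype=bool)
    if mask.shape[0] != n_total:
        raise ValueError("mask length must equal the number of epochs")
    if n_total == 0 or not mask.any():
        warnings.warn("no epochs kept; empty ERP entry")
        return BlockERP(np.empty((0, 0)), times_ms, 0, n_total,
                        mask=np.asarray(mask, bool), **ids)
    avg = epochs[mask].mean(axis=0)
    return BlockERP(avg, times_ms, int(mask.sum()), n_total,
                    mask=np.asarray(mask, bool), **ids)
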