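"""Generalized eigenvalue decomposition (GED) spatial filters.

For each response family (ERP, envelope-TRF, onset-TRF) and component
(N1, P2, N2) a single cross-participant spatial filter maximizes the
variance contrast between a peri-peak time window (signal covariance S)
and the pre-stimulus baseline (reference covariance R): solve
``S w = mu R w`` after shrinkage-regularizing R. The filter's forward
model ``A = S w`` shows the component's scalp projection; the signed
component time series yields one mean amplitude per (participant, block,
response, component) for the mixed-effects layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .preproc import channel_positions

logger = logging.getLogger(__name__)

#: peak search windows in ms: (response family, component) -> (lo, hi)
SEARCH_WINDOWS_MS = {
    ("ERP", "N1"): (80.0, 150.0),
    ("ERP", "P2"): (150.0, 250.0),
    ("ERP", "N2"): (200.0, 300.0),
    ("TRF_ons", "N1"): (80.0, 150.0),
    ("TRF_ons", "P2"): (150.0, 250.0),
    ("TRF_ons", "N2"): (200.0, 300.0),
    ("TRF_env", "N1"): (50.0, 120.0),
    ("TRF_env", "P2"): (120.0, 220.0),
    ("TRF_env", "N2"): (220.0, 320.0),
}
HALF_WIDTH_MS = {"N1": 25.0, "P2": 50.0, "N2": 50.0}
POLARITY = {"N1": -1, "P2": +1, "N2": -1}


@dataclass
class WindowSpec:
    """Peak search window and averaging half-width for one component."""

    response: str  # ERP | TRF_env | TRF_ons
    component: str  # N1 | P2 | N2
    search_ms: tuple[float, float] = None
    half_width_ms: float = None
    polarity: int = None

    def __post_init__(self):
        if self.search_ms is None:
            self.search_ms = SEARCH_WINDOWS_MS[(self.response, self.component)]
        if self.half_width_ms is None:
            self.half_width_ms = HALF_WIDTH_MS[self.component]
        if self.polarity is None:
            self.polarity = POLARITY[self.component]


@dataclass
class GEDFilter:
    """Eigen-decomposition of the signal/baseline covariance pencil."""

    s_mean: np.ndarray
    r_mean: np.ndarray
    eigvecs: np.ndarray  # columns, sorted by eigenvalue desc
    eigvals: np.ndarray
    shrink: float
    chosen: int = 0
    sign: float = 1.0
    forward: np.ndarray = None  # topographies, unit max-abs columns
    excluded: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def w(self) -> np.ndarray:
        return self.sign * self.eigvecs[:, self.chosen]

    @property
    def topography(self) -> np.ndarray:
        return self.forward[:, self.chosen]


def find_peak(
    response: np.ndarray, times_ms: np.ndarray, spec: WindowSpec
) -> tuple[float, int, bool]:
    """Polarity-consistent extremum inside the search window.

    Returns ``(latency_ms, channel, flagged)``; when no sample of the
    required polarity exists, falls back to the |amplitude| extremum and
    flags the participant.
    """
    sel = (times_ms >= spec.search_ms[0]) & (times_ms <= spec.search_ms[1])
    win = response[:, sel]
    t_win = times_ms[sel]
    signed = spec.polarity * win
    flagged = False
    if (signed > 0).any():
        ch, ti = np.unravel_index(np.argmax(signed), signed.shape)
    else:
        ch, ti = np.unravel_index(np.argmax(np.abs(win)), win.shape)
        flagged = True
        logger.info("no polarity-consistent %s peak; fallback to |max|",
                    spec.component)
    return float(t_win[ti]), int(ch), flagged


def window_covariances(
    response: np.ndarray,
    times_ms: np.ndarray,
    peak_ms: float,
    spec: WindowSpec,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant covariances of mean-centered window and baseline
    samples, normalized by (n - 1). A window truncated by the epoch edge
    shrinks symmetrically (logged)."""
    lo, hi = peak_ms - spec.half_width_ms, peak_ms + spec.half_width_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        over = max(times_ms[0] - lo, hi - times_ms[-1])
        lo, hi = lo + over, hi - over
        logger.info("window truncated by epoch edge; shrunk to +/-%.1f ms",
                    (hi - lo) / 2)
    win = response[:, (times_ms >= lo) & (times_ms <= hi)]
    base = response[:, (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])]
    S = np.cov(win - win.mean(axis=1, keepdims=True))
    R = np.cov(base - base.mean(axis=1, keepdims=True))
    return S, R


def clean_and_average(
    s_list: list[np.ndarray], r_list: list[np.ndarray], sd: float = 3.0
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Outlier-robust grand-average covariances.

    Frobenius distances to the grand mean are computed per participant;
    participants beyond mean + ``sd`` * SD for S or R are excluded
    (jointly from both sets) and the means are recomputed once.
    """
    if len(s_list) < 3:
        raise ValueError("need at least 3 participants")
    S = np.stack(s_list)
    R = np.stack(r_list)
    excluded: set[int] = set()
    for M in (S, R):
        mean = M.mean(axis=0)
        d = np.linalg.norm(M - mean, axis=(1, 2))
        thr = d.mean() + sd * d.std()
        excluded |= set(np.flatnonzero(d > thr))
    keep = [i for i in range(len(s_list)) if i not in excluded]
    if not keep:
        raise ValueError("all participants excluded as covariance outliers")
    return S[keep].mean(axis=0), R[keep].mean(axis=0), sorted(excluded)


def ged_decompose(
    s_mean: np.ndarray, r_mean: np.ndarray, shrink: float = 0.01
) -> GEDFilter:
    """Solve the regularized pencil ``S w = mu R_reg w``.

    ``R_reg = (1 - shrink) R + shrink * mean(eig(R)) * I`` guarantees an
    invertible, symmetric-definite reference so all eigenvalues are real.
    Forward topographies are ``S w`` normalized to unit max-abs.
    """
    if s_mean.shape != r_mean.shape or s_mean.shape[0] != s_mean.shape[1]:
        raise ValueError("covariances must be square and same size")
    evR = np.linalg.eigvalsh(r_mean)
    r_reg = (1.0 - shrink) * r_mean + shrink * evR.mean() * np.eye(
        r_mean.shape[0])
    try:
        vals, vecs = linalg.eigh(s_mean, r_reg)
    except linalg.LinAlgError as err:  # pragma: no cover
        raise linalg.LinAlgError("regularized reference not definite") from err
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    forward = s_mean @ vecs
    scale = np.abs(forward).max(axis=0)
    scale[scale == 0] = 1.0
    forward = forward / scale
    return GEDFilter(s_mean, r_mean, vecs, vals, shrink, forward=forward)


def plausibility_prior(labels: list[str], center: str = "Cz",
                       spread: float = 0.07) -> np.ndarray:
    """Smooth fronto-central template used to score topographies."""
    pos = channel_positions(list(labels))
    c = pos[list(labels).index(center)]
    pat = np.exp(-0.5 * (np.linalg.norm(pos - c, axis=1) / spread) ** 2)
    return pat / np.linalg.norm(pat)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / d) if d > 0 else 0.0


def select_component(
    filt: GEDFilter,
    spec: WindowSpec,
    mean_response: np.ndarray,
    times_ms: np.ndarray,
    peak_ms: float,
    labels: list[str],
    prior_threshold: float = 0.5,
    override: int | None = None,
) -> GEDFilter:
    """Choose the component and fix its sign.

    Component 1 is the default; component 2 is promoted when component
    1's forward topography fails the fronto-central plausibility check
    and component 2 passes it. The sign is flipped so the component's
    mean over the peak window matches the specified polarity. Eigenvector
    sign ambiguity therefore never reaches the output.
    """
    prior = plausibility_prior(labels)
    scores = [abs(_corr(filt.forward[:, j], prior)) for j in (0, 1)]
    if override is not None:
        chosen = override
    elif scores[0] >= prior_threshold:
        chosen = 0
    elif scores[1] >= prior_threshold:
        chosen = 1
        filt.flags.append("component 2 promoted by plausibility check")
    else:
        chosen = 0
        filt.flags.append("no component passed plausibility; kept component 1")
    filt.chosen = chosen

    lo, hi = peak_ms - spec.half_width_ms, peak_ms + spec.half_width_ms
    sel = (times_ms >= lo) & (times_ms <= hi)
    comp = filt.eigvecs[:, chosen] @ mean_response
    wmean = comp[sel].mean()
    filt.sign = 1.0 if np.sign(wmean) == np.sign(spec.polarity) else -1.0
    filt.forward[:, chosen] = filt.forward[:, chosen] * filt.sign
    return filt


def component_amplitudes(
    filt: GEDFilter,
    block_responses: dict,
    times_ms: np.ndarray,
    peak_ms: float,
    spec: WindowSpec,
) -> pd.DataFrame:
    """Mean signed-component amplitude over the peak window, one row per
    (participant, block). Missing blocks yield NA with a log message."""
    lo, hi = peak_ms - spec.half_width_ms, peak_ms + spec.half_width_ms
    sel = (times_ms >= lo) & (times_ms <= hi)
    w = filt.w
    rows = []
    for (participant, block), resp in block_responses.items():
        if resp is None or getattr(resp, "size", 0) == 0:
            logger.info("missing block (%s, %s); NA amplitude",
                        participant, block)
            amp = np.nan
        else:
            amp = float((w @ resp)[sel].mean())
        rows.append(dict(participant=participant, block=block,
                         response=spec.response, component=spec.component,
                         amplitude=amp))
    return pd.DataFrame(rows)
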