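"""Forward (encoding) models relating stimulus features to EEG.

A temporal response function (TRF) is the kernel ``w`` of the lag-expanded
ridge regression ``EEG(t, ch) ~ sum_k w(k, ch) * feature(t - lag_k)``.
Shrinkage follows the mTRF convention: the penalty is ``lambda * m * I``
with ``m`` the mean diagonal of the (centered) design Gram matrix, which
makes the canonical ``10^-8 .. 10^8`` grid dimensionless. Lambda is chosen
by leave-one-segment-out cross-validation over contiguous multi-block
segments; per-block TRFs at the participant's modal lambda are z-scored
across (lag, channel, block) within participant before amplitude
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-8, 9))


def scale_eeg(data: np.ndarray, factor: float = 0.0313) -> np.ndarray:
    """Elementwise EEG scaling applied before TRF estimation."""
    return np.asarray(data, dtype=float) * factor


def lag_samples(lag_min_ms: float, lag_max_ms: float, rate: float) -> np.ndarray:
    """Inclusive lag grid in samples: floor at the minimum, ceil at the
    maximum (0-450 ms at 100 Hz gives 46 lags)."""
    if lag_min_ms > lag_max_ms:
        raise ValueError("lag_min must not exceed lag_max")
    lo = int(np.floor(lag_min_ms / 1000.0 * rate))
    hi = int(np.ceil(lag_max_ms / 1000.0 * rate))
    return np.arange(lo, hi + 1)


@dataclass
class LaggedDesign:
    """Time-lagged design matrix (samples x lags) for one feature."""

    matrix: np.ndarray
    lags: np.ndarray  # in samples
    rate: float
    kind: str = ""

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags / self.rate * 1000.0


def build_lagged(
    feature: np.ndarray, lag_min_ms: float, lag_max_ms: float, rate: float,
    kind: str = "",
) -> LaggedDesign:
    """Column k holds the feature delayed by lag_k; out-of-range samples
    are zero-filled."""
    feature = np.asarray(feature, dtype=float).ravel()
    lags = lag_samples(lag_min_ms, lag_max_ms, rate)
    n = feature.size
    X = np.zeros((n, lags.size))
    for j, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, j] = feature[: n - lag] if lag < n else 0.0
        else:
            X[: n + lag, j] = feature[-lag:]
    return LaggedDesign(X, lags, rate, kind)


@dataclass
class TRFModel:
    """Estimated kernel: weights over (lag x channel) plus intercept."""

    weights: np.ndarray
    bias: np.ndarray
    lam: float
    lags: np.ndarray
    rate: float
    kind: str = ""
    zscored: bool = False

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags / self.rate * 1000.0

    def predict(self, design: LaggedDesign) -> np.ndarray:
        return design.matrix @ self.weights + self.bias


class Gram:
    """Sufficient statistics of (X, Y) for centered ridge solves.

    Grams add across blocks, so per-block statistics are computed once
    and train/test splits reduce to subtraction — the held-out segment
    never contributes to the training normal equations.
    """

    __slots__ = ("n", "sx", "sy", "xtx", "xty", "yty", "ysq")

    def __init__(self, n, sx, sy, xtx, xty):
        self.n, self.sx, self.sy, self.xtx, self.xty = n, sx, sy, xtx, xty

    @classmethod
    def from_arrays(cls, X: np.ndarray, Y: np.ndarray) -> "Gram":
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        return cls(X.shape[0], X.sum(0), Y.sum(0), X.T @ X, X.T @ Y)

    def __add__(self, other: "Gram") -> "Gram":
        return Gram(self.n + other.n, self.sx + other.sx, self.sy + other.sy,
                    self.xtx + other.xtx, self.xty + other.xty)

    def __sub__(self, other: "Gram") -> "Gram":
        return Gram(self.n - other.n, self.sx - other.sx, self.sy - other.sy,
                    self.xtx - other.xtx, self.xty - other.xty)


def _solve_gram(gram: Gram, lam: float) -> tuple[np.ndarray, np.ndarray]:
    xtx_c = gram.xtx - np.outer(gram.sx, gram.sx) / gram.n
    xty_c = gram.xty - np.outer(gram.sx, gram.sy) / gram.n
    p = xtx_c.shape[0]
    mbar = np.trace(xtx_c) / p
    A = xtx_c + lam * mbar * np.eye(p)
    try:
        W = np.linalg.solve(A, xty_c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular normal equations at lambda={lam}; use lambda > 0 "
            "for collinear designs"
        ) from err
    bias = gram.sy / gram.n - W.T @ (gram.sx / gram.n)
    return W, bias


def ridge_fit(
    design: LaggedDesign, Y: np.ndarray, lam: float
) -> TRFModel:
    """Closed-form ridge solution with mTRF-style lambda normalization.

    ``W = (X'X + lambda * m * I)^-1 X'Y`` on mean-centered X and Y, with
    ``m`` the mean diagonal of the centered Gram; the intercept absorbs
    the means. ``lam=0`` reduces to ordinary least squares.
    """
    gram = Gram.from_arrays(design.matrix, np.atleast_2d(Y.T).T)
    W, bias = _solve_gram(gram, lam)
    return TRFModel(W, bias, lam, design.lags.copy(), design.rate,
                    design.kind)


def pearson_by_channel(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Per-channel Pearson r; zero-variance channels yield NaN (skipped
    downstream with a log message)."""
    pred = pred - pred.mean(0)
    obs = obs - obs.mean(0)
    denom = np.sqrt((pred**2).sum(0) * (obs**2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pred * obs).sum(0) / denom
    bad = ~np.isfinite(r)
    if bad.any():
        logger.info("skipping %d zero-variance channel(s)", int(bad.sum()))
        r[bad] = np.nan
    return r


def segment_partition(n_blocks: int, k: int = 10) -> list[list[int]]:
    """Split blocks 0..n-1 into k contiguous segments; remainder blocks go
    to the earliest segments (28 blocks, k=10: eight 3-block then two
    2-block segments)."""
    if n_blocks < k:
        raise ValueError("need at least k blocks")
    base, rem = divmod(n_blocks, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    out, start = [], 0
    for s in sizes:
        out.append(list(range(start, start + s)))
        start += s
    return out


@dataclass
class CVResult:
    """Lambda search record: per-(fold, lambda) mean correlations."""

    best_lambda: float
    table: pd.DataFrame  # columns fold, lam, r
    fold_best: list[float]
    grid: tuple
    lags: np.ndarray
    rate: float

    def modal_lambda(self) -> float:
        """Most frequent per-fold winner; ties break toward the larger."""
        vals, counts = np.unique(self.fold_best, return_counts=True)
        winners = vals[counts == counts.max()]
        return float(winners.max())


def crossval_lambda(
    features: list[np.ndarray],
    eegs: list[np.ndarray],
    rate: float,
    grid=DEFAULT_LAMBDA_GRID,
    lag_min_ms: float = 0.0,
    lag_max_ms: float = 450.0,
    k: int = 10,
    kind: str = "",
) -> CVResult:
    """Leave-one-segment-out search for the shrinkage parameter.

    Blocks are partitioned into ``k`` contiguous segments. For every
    lambda on the grid, models are trained on all but one segment and
    evaluated by per-channel Pearson r on the held-out segment;
    ``best_lambda`` maximizes the fold-and-channel mean.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(features) != len(eegs):
        raise ValueError("features and EEG block lists differ in length")
    designs = [build_lagged(f, lag_min_ms, lag_max_ms, rate, kind)
               for f in features]
    grams = [Gram.from_arrays(d.matrix, e) for d, e in zip(designs, eegs)]
    total = grams[0]
    for g in grams[1:]:
        total = total + g
    folds = segment_partition(len(features), k)

    rows = []
    for fi, seg in enumerate(folds):
        train = total
        for b in seg:
            train = train - grams[b]
        for lam in grid:
            W, bias = _solve_gram(train, lam)
            rs = []
            for b in seg:
                pred = designs[b].matrix @ W + bias
                rs.append(pearson_by_channel(pred, eegs[b]))
            rows.append(dict(fold=fi, lam=lam,
                             r=float(np.nanmean(np.stack(rs)))))
    table = pd.DataFrame(rows)
    mean_r = table.groupby("lam")["r"].mean()
    best = float(mean_r.idxmax())
    fold_best = [
        float(g.loc[g["r"].idxmax(), "lam"])
        for _, g in table.groupby("fold")
    ]
    return CVResult(best, table, fold_best, tuple(grid),
                    lag_samples(lag_min_ms, lag_max_ms, rate), rate)


def prediction_accuracy(
    features: list[np.ndarray],
    eegs: list[np.ndarray],
    rate: float,
    lam: float,
    lag_min_ms: float = 0.0,
    lag_max_ms: float = 450.0,
    k: int = 10,
    kind: str = "",
) -> dict:
    """Cross-validated prediction accuracy at a fixed lambda.

    Per fold, a model trained on the remaining segments predicts the
    held-out blocks. Returns both averaging orders (channels first, then
    blocks — the default — and the reverse); the difference is logged.
    """
    designs = [build_lagged(f, lag_min_ms, lag_max_ms, rate, kind)
               for f in features]
    grams = [Gram.from_arrays(d.matrix, e) for d, e in zip(designs, eegs)]
    total = grams[0]
    for g in grams[1:]:
        total = total + g
    folds = segment_partition(len(features), k)
    r_blocks = []  # per test block: per-channel r
    for seg in folds:
        train = total
        for b in seg:
            train = train - grams[b]
        W, bias = _solve_gram(train, lam)
        for b in seg:
            pred = designs[b].matrix @ W + bias
            r_blocks.append(pearson_by_channel(pred, eegs[b]))
    R = np.stack(r_blocks)  # blocks x channels
    ch_then_block = float(np.nanmean(np.nanmean(R, axis=1)))
    block_then_ch = float(np.nanmean(np.nanmean(R, axis=0)))
    logger.info("prediction r: channel-then-block=%.5f block-then-channel=%.5f",
                ch_then_block, block_then_ch)
    return {
        "r": ch_then_block,
        "r_block_then_channel": block_then_ch,
        "per_block_channel": R,
        "lam": lam,
        "kind": kind,
    }


def per_block_trf(
    features: list[np.ndarray],
    eegs: list[np.ndarray],
    rate: float,
    cv: CVResult,
    lag_min_ms: float = -220.0,
    lag_max_ms: float = 500.0,
    kind: str = "",
    zscore: bool = True,
) -> list[TRFModel]:
    """One TRF per block at the participant's modal cross-validation
    lambda; weights z-scored across (lag, channel, block) within the
    participant."""
    if cv is None:
        raise ValueError("cross-validation record required for modal lambda")
    lam = cv.modal_lambda()
    models = []
    for f, e in zip(features, eegs):
        d = build_lagged(f, lag_min_ms, lag_max_ms, rate, kind)
        models.append(ridge_fit(d, e, lam))
    if zscore:
        allw = np.stack([m.weights for m in models])
        mu, sd = allw.mean(), allw.std()
        if sd == 0:
            raise ValueError("degenerate TRF weights: zero variance")
        for m in models:
            m.weights = (m.weights - mu) / sd
            m.zscored = True
    return models
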