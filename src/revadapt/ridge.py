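"""Ridge regression with contiguous cross-validation for kernels and STRFs.

Both the dereverberation model and neuronal STRF estimation solve the same
problem: predict a target series (an anechoic cochleagram channel, or a
unit's binned spike counts) from the lagged reverberant cochleagram

    y_hat(t) = sum_f sum_h  w[f, h] * x[f, t - h]  +  b

with L2 (ridge) regularisation on w and an unpenalised bias b.  The ridge
strength is selected by k-fold cross-validation whose validation sets are
unbroken, non-overlapping contiguous segments, and the final weights are
refit on the whole series at the selected strength.

All heavy lifting is done through one economy SVD per fold, shared across
regularisation strengths and across targets, so fitting a whole population
of units against the same stimulus costs little more than fitting one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cochlea import Cochleagram


@dataclass(frozen=True)
class FitConfig:
    """Ridge fitting configuration.

    h_max: number of causal lag bins (20 x 10 ms = 200 ms history).
    lambda_grid: ridge strengths; None selects 30 log-spaced values over
        six decades, scaled to the spectral norm of X'X.
    n_folds: contiguous cross-validation folds partitioning the rows.
    standardize: z-score design columns for fitting (weights are mapped
        back to the original units), as standard elastic-net solvers do
        by default.
    """

    h_max: int = 20
    lambda_grid: tuple[float, ...] | None = None
    n_folds: int = 10
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.h_max < 1:
            raise ValueError("h_max must be >= 1")
        if self.lambda_grid is not None and np.any(
            np.asarray(self.lambda_grid) <= 0
        ):
            raise ValueError("ridge strengths must be positive")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class Kernel:
    """A fitted frequency x lag weight matrix with bias.

    weights[f, h] multiplies input channel f at lag h bins into the past
    (h = 0 is the current bin).  target_id names the predicted quantity:
    an output frequency channel for dereverberation kernels, a unit id
    for STRFs.
    """

    weights: np.ndarray  # (n_freq, h_max)
    bias: float
    target_id: int | str = ""
    lam: float = np.nan
    channel_centers: np.ndarray | None = None

    @property
    def n_freq(self) -> int:
        return self.weights.shape[0]

    @property
    def h_max(self) -> int:
        return self.weights.shape[1]


@dataclass
class DereverbModel:
    """One kernel per output (anechoic) frequency channel."""

    kernels: list[Kernel]
    room_label: str = ""
    config: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        shapes = {k.weights.shape for k in self.kernels}
        if len(shapes) > 1:
            raise ValueError("all kernels must share one shape")

    def predict(self, reverb: Cochleagram) -> np.ndarray:
        """Estimated anechoic cochleagram (n_channels x n_bins, dB)."""
        X = build_lag_matrix(reverb, self.kernels[0].h_max)
        W = np.stack([k.weights.ravel() for k in self.kernels])
        b = np.array([k.bias for k in self.kernels])
        return (X @ W.T + b).T


@dataclass
class ResponseSeries:
    """Trial-averaged spike counts of one unit per cochleagram time bin."""

    unit_id: int | str
    counts: np.ndarray
    n_repeats: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("counts must be finite and non-negative")
        self.counts = c


def build_lag_matrix(coch: Cochleagram | np.ndarray, h_max: int) -> np.ndarray:
    """Causal lagged design matrix from a (n_freq, T) cochleagram.

    Row t holds x[f, t - h] for every channel f and lag h = 0..h_max-1;
    lags reaching before the first bin are zero-padded so the row count
    equals the bin count.  Column order is (f, h) with h fastest:
    column f * h_max + h.
    """
    values = coch.values if isinstance(coch, Cochleagram) else np.asarray(coch)
    if values.ndim != 2:
        raise ValueError("expected a (n_freq, T) array")
    n_freq, T = values.shape
    if h_max > T:
        raise ValueError(f"h_max={h_max} exceeds series length {T}")
    X = np.zeros((T, n_freq, h_max))
    for h in range(h_max):
        X[h:, :, h] = values[:, : T - h].T
    return X.reshape(T, n_freq * h_max)


def contiguous_folds(n_rows: int, n_folds: int) -> list[np.ndarray]:
    """Split row indices into contiguous, non-overlapping validation
    segments that exactly partition [0, n_rows)."""
    edges = np.linspace(0, n_rows, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


def _lambda_grid(xtx_norm: float, n: int = 30, decades: float = 6.0) -> np.ndarray:
    return np.geomspace(xtx_norm * 10.0 ** (-decades), xtx_norm, n)


class _Standardizer:
    """Column centring (and optional scaling) fitted on training rows."""

    def __init__(self, X: np.ndarray, scale: bool):
        self.mean = X.mean(axis=0)
        if scale:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            self.sd = sd
        else:
            self.sd = np.ones(X.shape[1])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def ridge_solve(
    X: np.ndarray, y: np.ndarray, lam: float, standardize: bool = True
) -> tuple[np.ndarray, float]:
    """Closed-form ridge at a fixed strength (bias unpenalised).

    Solves min ||y - Xw - b||^2 + lam ||w||^2 on centred (and optionally
    scaled) columns; returns weights in original units plus the bias.
    """
    y = np.asarray(y, dtype=float)
    std = _Standardizer(np.asarray(X, dtype=float), standardize)
    Xc = std.transform(X)
    ym = y.mean()
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    d = s / (s**2 + lam)
    w_std = Vt.T @ (d * (U.T @ (y - ym)))
    w = w_std / std.sd
    b = ym - std.mean @ w
    return w, float(b)


def fit_ridge_cv_multi(
    X: np.ndarray, Y: np.ndarray, cfg: FitConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-validated ridge for many targets sharing one design matrix.

    Y is (T, M).  For each target the ridge strength minimising the mean
    validation MSE across contiguous folds is chosen, then weights are
    refit on all rows.  Returns (W, b, lam) with W of shape (M, P).

    Constant targets get zero weights and bias = mean (their strength is
    reported as the largest grid value).
    """
    cfg = cfg or FitConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T, P = X.shape
    if Y.shape[0] != T:
        raise ValueError("X and Y row counts differ")
    if not np.all(np.isfinite(Y)):
        raise ValueError("targets must be finite")
    M = Y.shape[1]

    std_full = _Standardizer(X, cfg.standardize)
    Xf = std_full.transform(X)
    Uf, sf, Vtf = np.linalg.svd(Xf, full_matrices=False)

    if cfg.lambda_grid is not None:
        grid = np.asarray(cfg.lambda_grid, dtype=float)
    else:
        grid = _lambda_grid(float(sf[0] ** 2))
    n_lam = grid.size

    live = Y.max(axis=0) != Y.min(axis=0)  # exactly-constant targets degenerate
    folds = contiguous_folds(T, cfg.n_folds)
    cv_mse = np.zeros((len(folds), n_lam, M))
    for k, val_idx in enumerate(folds):
        tr_mask = np.ones(T, dtype=bool)
        tr_mask[val_idx] = False
        Xtr, Ytr = X[tr_mask], Y[tr_mask]
        std = _Standardizer(Xtr, cfg.standardize)
        U, s, Vt = np.linalg.svd(std.transform(Xtr), full_matrices=False)
        ym = Ytr.mean(axis=0)
        G = U.T @ (Ytr - ym)
        A = std.transform(X[val_idx]) @ Vt.T
        Yval = Y[val_idx]
        for j, lam in enumerate(grid):
            d = s / (s**2 + lam)
            pred = A @ (d[:, None] * G) + ym
            cv_mse[k, j] = np.mean((pred - Yval) ** 2, axis=0)

    mean_mse = cv_mse.mean(axis=0)  # (n_lam, M)
    best = np.argmin(mean_mse, axis=0)
    best[~live] = n_lam - 1

    ymf = Y.mean(axis=0)
    Gf = Uf.T @ (Y - ymf)
    W = np.zeros((M, P))
    for j in np.unique(best):
        cols = np.nonzero((best == j) & live)[0]
        if cols.size == 0:
            continue
        d = sf / (sf**2 + grid[j])
        W[cols] = (Vtf.T @ (d[:, None] * Gf[:, cols])).T
    W /= std_full.sd
    b = ymf - W @ std_full.mean
    return W, b, grid[best]


def fit_ridge_cv(
    X: np.ndarray, y: np.ndarray, cfg: FitConfig | None = None
) -> tuple[np.ndarray, float, float]:
    """Single-target convenience wrapper: returns (weights, bias, lam)."""
    W, b, lam = fit_ridge_cv_multi(X, np.asarray(y)[:, None], cfg)
    return W[0], float(b[0]), float(lam[0])


def _check_grids(a: Cochleagram, b: Cochleagram) -> None:
    if a.values.shape[1] != b.values.shape[1]:
        raise ValueError("cochleagrams have different numbers of time bins")
    if not np.allclose(a.channel_centers, b.channel_centers):
        raise ValueError("cochleagrams have different channel grids")


def fit_dereverb(
    reverb: Cochleagram, anech: Cochleagram, cfg: FitConfig | None = None
) -> DereverbModel:
    """Fit dereverberation kernels: one independent ridge fit per anechoic
    channel, all sharing the lagged reverberant design matrix."""
    cfg = cfg or FitConfig()
    _check_grids(reverb, anech)
    X = build_lag_matrix(reverb, cfg.h_max)
    W, b, lam = fit_ridge_cv_multi(X, anech.values.T, cfg)
    n_freq = reverb.n_channels
    kernels = [
        Kernel(
            weights=W[i].reshape(n_freq, cfg.h_max),
            bias=float(b[i]),
            target_id=i,
            lam=float(lam[i]),
            channel_centers=reverb.channel_centers,
        )
        for i in range(anech.n_channels)
    ]
    return DereverbModel(kernels=kernels, config=cfg)


def fit_strfs(
    reverb: Cochleagram | np.ndarray,
    responses: np.ndarray,
    cfg: FitConfig | None = None,
    rows: np.ndarray | None = None,
    channel_centers: np.ndarray | None = None,
) -> list[Kernel]:
    """Fit spectrotemporal receptive fields for a population of units.

    responses is (M, T) trial-averaged counts on the cochleagram's time
    grid.  `rows` optionally restricts fitting to a subset of time bins
    (e.g. the probe-free portion of each block); lag context still comes
    from the full series, so excluded bins never appear as targets but may
    appear as history.
    """
    cfg = cfg or FitConfig()
    if isinstance(reverb, Cochleagram):
        centers = reverb.channel_centers
        X = build_lag_matrix(reverb, cfg.h_max)
        n_freq = reverb.n_channels
    else:
        X = np.asarray(reverb)
        n_freq = X.shape[1] // cfg.h_max
        centers = channel_centers
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if rows is not None:
        X = X[rows]
        Y = Y[:, rows]
    W, b, lam = fit_ridge_cv_multi(X, Y.T, cfg)
    return [
        Kernel(
            weights=W[i].reshape(n_freq, cfg.h_max),
            bias=float(b[i]),
            target_id=i,
            lam=float(lam[i]),
            channel_centers=centers,
        )
        for i in range(Y.shape[0])
    ]


def fit_strf(
    reverb: Cochleagram,
    resp: ResponseSeries,
    cfg: FitConfig | None = None,
    rows: np.ndarray | None = None,
) -> Kernel:
    """Fit a single unit's STRF from its trial-averaged counts."""
    if isinstance(reverb, Cochleagram) and len(resp.counts) != reverb.n_bins:
        raise ValueError("response length must match cochleagram bins")
    k = fit_strfs(reverb, resp.counts[None, :], cfg, rows=rows)[0]
    k.target_id = resp.unit_id
    return k


def mse_reduction(
    model: DereverbModel, reverb: Cochleagram, anech: Cochleagram
) -> float:
    """Fractional MSE reduction of the model on (held-out) data.

    1 - MSE(prediction, anechoic) / MSE(reverberant, anechoic); 1 means
    perfect dereverberation, 0 means no better than the reverberant input.
    """
    _check_grids(reverb, anech)
    pred = model.predict(reverb)
    base = np.mean((reverb.values - anech.values) ** 2)
    if base == 0:
        raise ValueError("baseline MSE is zero; reduction undefined")
    return 1.0 - float(np.mean((pred - anech.values) ** 2)) / float(base)
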