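"""Non-adaptive simulated neurons: LNP and NRF-Poisson control models.

A linear-nonlinear-Poisson (LNP) neuron applies a fixed STRF to the
cochleagram, passes the linear drive through a four-parameter sigmoid

    rate(t) = rho1 / (1 + exp(-(y(t) - rho3) / rho2)) + rho4

and draws independent Poisson spike counts per 10 ms bin and trial.  The
network receptive field (NRF) variant replaces the single linear filter
with a small one-hidden-layer sigmoid network (10 hidden units), trained
by MSE with an L1 weight penalty.  Because neither model can change its
filtering between stimulus conditions, both serve as non-adaptive
controls: any receptive-field shift measured from their simulated
responses must be a stimulus-statistics artefact, not adaptation.

Fit quality is scored with the normalised correlation coefficient
(CCnorm), which divides the raw prediction-response correlation by the
fraction of response variance that is repeatable across trials; trial
variability is summarised by the Fano factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cochlea import Cochleagram
from .ridge import Kernel, build_lag_matrix, contiguous_folds


@dataclass
class SigmoidParams:
    """Output nonlinearity parameters (spikes/bin at the output).

    rho1: output range; rho2: slope scale of the linear drive; rho3:
    drive at half height; rho4: baseline.  `fallback` marks a fit that
    failed to converge and was replaced by a near-linear sigmoid
    matching the best affine map.
    """

    rho1: float
    rho2: float
    rho3: float
    rho4: float
    fallback: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rho1, self.rho2, self.rho3, self.rho4])


def sigmoid(x: np.ndarray, p: SigmoidParams | np.ndarray) -> np.ndarray:
    r1, r2, r3, r4 = p.as_array() if isinstance(p, SigmoidParams) else p
    return r1 / (1.0 + np.exp(-np.clip((x - r3) / r2, -500, 500))) + r4


@dataclass
class LNPNeuron:
    """STRF + sigmoid + Poisson spike generation."""

    strf: Kernel
    nonlinearity: SigmoidParams
    unit_id: int | str = ""


@dataclass
class TrialResponses:
    """Integer spike counts, repeats x time bins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be repeats x time bins")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_rate(self) -> np.ndarray:
        """Trial-averaged counts per bin."""
        return self.counts.mean(axis=0)


def fit_sigmoid(linear_pred: np.ndarray, observed: np.ndarray) -> SigmoidParams:
    """Least-squares sigmoid fit with multi-start initialisation.

    Starts span the range of the linear prediction (several thresholds
    and slope scales); the best-MSE solution wins.  If every start fails,
    a near-linear sigmoid reproducing the best affine fit is returned,
    flagged `fallback`.
    """
    x = np.asarray(linear_pred, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("prediction and observation lengths differ")
    if np.any(y < 0):
        raise ValueError("observed rates must be non-negative")

    xm, xs = x.mean(), x.std()
    if xs == 0:
        return SigmoidParams(0.0, 1.0, xm, float(y.mean()), fallback=True)
    yr = max(y.max() - y.min(), 1e-12)

    def residuals(p):
        return sigmoid(x, p) - y

    best = None
    best_cost = np.inf
    thresholds = np.quantile(x, [0.25, 0.5, 0.75])
    slopes = [xs / 2.0, 2.0 * xs]
    starts = [
        np.array([yr, s, t, max(y.min(), 0.0)])
        for t in thresholds
        for s in slopes
    ]
    starts.append(np.array([2.0 * yr, xs, xm, 0.0]))
    starts.append(np.array([yr / 2.0, xs / 4.0, xm, y.mean() / 2.0]))
    for p0 in starts:
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=400)
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)) and res.x[1] != 0:
            best_cost = res.cost
            best = res.x
    if best is None:
        a, b = np.polyfit(x, y, 1)
        r2 = 100.0 * xs
        r1 = 4.0 * r2 * a
        return SigmoidParams(r1, r2, xm, float(b + a * xm - r1 / 2.0), fallback=True)
    return SigmoidParams(*[float(v) for v in best])


def linear_drive(strf: Kernel, coch: Cochleagram | np.ndarray) -> np.ndarray:
    """Linear stage of the model: lagged cochleagram times STRF + bias.

    Accepts a Cochleagram, a raw (n_freq, T) array, or a prebuilt lagged
    design matrix whose column count equals the kernel size.
    """
    if isinstance(coch, Cochleagram):
        X = build_lag_matrix(coch, strf.h_max)
    else:
        arr = np.asarray(coch)
        X = arr if arr.shape[1] == strf.weights.size else build_lag_matrix(arr, strf.h_max)
    return X @ strf.weights.ravel() + strf.bias


def simulate_lnp(
    neuron: LNPNeuron,
    coch: Cochleagram,
    n_trials: int = 10,
    rng: np.random.Generator | int | None = None,
) -> TrialResponses:
    """Poisson trials from the neuron's rate (clamped at 0) per bin."""
    rng = np.random.default_rng(rng)
    rate = np.clip(sigmoid(linear_drive(neuron.strf, coch), neuron.nonlinearity), 0.0, None)
    counts = rng.poisson(rate, size=(n_trials, rate.size))
    return TrialResponses(counts=counts)


def poisson_trials(
    rate: np.ndarray, n_trials: int, rng: np.random.Generator | int | None = None
) -> TrialResponses:
    """Poisson trials from an arbitrary non-negative rate series."""
    rng = np.random.default_rng(rng)
    rate = np.clip(np.asarray(rate, dtype=float), 0.0, None)
    return TrialResponses(counts=rng.poisson(rate, size=(n_trials, rate.size)))


def ccnorm(prediction: np.ndarray, trials: TrialResponses) -> float:
    """Normalised correlation coefficient of a prediction with a noisy
    multi-trial response.

    The raw correlation with the trial mean is divided by the estimated
    ceiling sqrt(signal power / variance of trial mean), where the
    signal power SP = (Var(sum of trials) - sum of trial variances)
    / (N (N - 1)).  NaN when the signal-power estimate is not positive.
    """
    pred = np.asarray(prediction, dtype=float)
    R = np.asarray(trials.counts, dtype=float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    if pred.size != R.shape[1]:
        raise ValueError("prediction length must match trial bins")
    mean_resp = R.mean(axis=0)
    sp = (R.sum(axis=0).var(ddof=0) - R.var(axis=1, ddof=0).sum()) / (n * (n - 1))
    vp = pred.var(ddof=0)
    if sp <= 0 or vp == 0:
        return float("nan")
    cov = np.mean((pred - pred.mean()) * (mean_resp - mean_resp.mean()))
    return float(cov / np.sqrt(vp * sp))


def fano_factor(trials: TrialResponses) -> float:
    """Median across bins of variance/mean of counts over trials.

    Bins with zero mean are excluded; 1 for an ideal Poisson process,
    0 for identical deterministic trials.  NaN for an all-zero response.
    """
    R = np.asarray(trials.counts, dtype=float)
    if R.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    mean = R.mean(axis=0)
    keep = mean > 0
    if not keep.any():
        return float("nan")
    var = R.var(axis=0, ddof=1)
    return float(np.median(var[keep] / mean[keep]))


# ---------------------------------------------------------------------------
# Network receptive field (one hidden layer of sigmoid units)


@dataclass
class NRFConfig:
    """Training configuration for the network receptive field."""

    h_max: int = 20
    n_hidden: int = 10
    l1_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    n_folds: int = 10
    epochs: int = 400
    learning_rate: float = 0.02
    seed: int = 0


@dataclass
class NRFModel:
    """sigmoid(X W1 + b1) -> hidden; rate = gain * sigmoid(z w2 + b2).

    Weights act on standardised design columns; `x_mean`/`x_sd` store the
    standardisation so prediction works on raw lagged cochleagrams.
    """

    W1: np.ndarray  # (P, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    gain: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    l1: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X) - self.x_mean) / self.x_sd
        z = _logistic(Xs @ self.W1 + self.b1)
        return self.gain * _logistic(z @ self.w2 + self.b2)


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


def _nrf_init(P: int, H: int, rng: np.random.Generator):
    W1 = rng.normal(0.0, 1.0 / np.sqrt(P), size=(P, H))
    b1 = np.zeros(H)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(H), size=H)
    return W1, b1, w2


def _nrf_train(
    Xs: np.ndarray,
    y: np.ndarray,
    H: int,
    l1: float,
    epochs: int,
    lr: float,
    rng: np.random.Generator,
):
    """Full-batch Adam on MSE + l1 * (|W1| + |w2|); returns parameters."""
    T, P = Xs.shape
    W1, b1, w2 = _nrf_init(P, H, rng)
    b2 = 0.0
    gain = max(2.0 * y.max(), 1e-6)
    params = [W1, b1, w2, np.array([b2]), np.array([gain])]
    m = [np.zeros_like(p, dtype=float) for p in params]
    v = [np.zeros_like(p, dtype=float) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for step in range(1, epochs + 1):
        W1, b1, w2, b2a, gaina = params
        b2 = float(b2a[0])
        gain = float(gaina[0])
        z = _logistic(Xs @ W1 + b1)  # (T, H)
        s_out = _logistic(z @ w2 + b2)  # (T,)
        pred = gain * s_out
        err = pred - y  # (T,)
        # gradients of mean squared error
        g_gain = 2.0 * np.mean(err * s_out)
        d_out = 2.0 * err * gain * s_out * (1.0 - s_out) / T  # (T,)
        g_w2 = z.T @ d_out + l1 * np.sign(w2)
        g_b2 = d_out.sum()
        d_hid = np.outer(d_out, w2) * z * (1.0 - z)  # (T, H)
        g_W1 = Xs.T @ d_hid + l1 * np.sign(W1)
        g_b1 = d_hid.sum(axis=0)
        grads = [g_W1, g_b1, g_w2, np.array([g_b2]), np.array([g_gain])]
        for i, g in enumerate(grads):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1**step)
            vh = v[i] / (1 - beta2**step)
            params[i] = params[i] - lr * mh / (np.sqrt(vh) + eps)
        if not np.all(np.isfinite(params[0])):
            # diverged: restart deterministically with a smaller step
            return _nrf_train(Xs, y, H, l1, epochs, lr / 4.0, rng)
    W1, b1, w2, b2a, gaina = params
    return W1, b1, w2, float(b2a[0]), float(gaina[0])


def fit_nrf(
    coch: Cochleagram | np.ndarray,
    response: np.ndarray,
    cfg: NRFConfig | None = None,
) -> NRFModel:
    """Fit the network receptive field with L1 strength chosen by
    contiguous k-fold cross-validation (same fold layout as the ridge
    fits), then retrain on all data at the selected strength."""
    cfg = cfg or NRFConfig()
    X = build_lag_matrix(coch, cfg.h_max) if isinstance(coch, Cochleagram) else np.asarray(coch)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("design and response lengths differ")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    folds = contiguous_folds(X.shape[0], cfg.n_folds)
    cv = np.zeros(len(cfg.l1_grid))
    for j, l1 in enumerate(cfg.l1_grid):
        for k, val_idx in enumerate(folds):
            tr = np.ones(X.shape[0], dtype=bool)
            tr[val_idx] = False
            rng = np.random.default_rng((cfg.seed, j, k))
            W1, b1, w2, b2, gain = _nrf_train(
                Xs[tr], y[tr], cfg.n_hidden, l1, cfg.epochs, cfg.learning_rate, rng
            )
            z = _logistic(Xs[val_idx] @ W1 + b1)
            pred = gain * _logistic(z @ w2 + b2)
            cv[j] += np.mean((pred - y[val_idx]) ** 2)
    l1_best = cfg.l1_grid[int(np.argmin(cv))]
    rng = np.random.default_rng((cfg.seed, len(cfg.l1_grid)))
    W1, b1, w2, b2, gain = _nrf_train(
        Xs, y, cfg.n_hidden, l1_best, cfg.epochs, cfg.learning_rate, rng
    )
    return NRFModel(
        W1=W1, b1=b1, w2=w2, b2=b2, gain=gain, x_mean=mean, x_sd=sd, l1=float(l1_best)
    )
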