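"""Weighted GrC readouts (predicted PkC component) and population time
decoding.

A readout is a weighted sum of GrC activity per frame; with LTD-derived
weights it predicts the component of Purkinje-cell output shaped by
reward-evoked climbing-fiber plasticity.  Timing quality is quantified by
the pooled correlation between the readout and elapsed time, and by the
coefficient of determination over a stated window.  The optimal reference
is 10-fold cross-validated ordinary-least-squares decoding of delay time
from the full population, with folds partitioning trials (never frames, to
avoid temporal leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold

from .classification import AlignedTensor
from .plasticity import WeightSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReadoutResult",
    "DecodingResult",
    "weighted_readout",
    "timing_accuracy",
    "decode_time_cv",
    "compare_readouts",
    "behavior_readout_correlation",
]


@dataclass
class ReadoutResult:
    traces: np.ndarray            # trials x time
    time: np.ndarray
    trial_average: np.ndarray
    normalized_average: np.ndarray  # trial-average affinely mapped onto the time range
    r: float                      # pooled correlation between time and readout
    norm_slope: float
    norm_intercept: float
    degenerate: bool = False      # flat readout, r undefined


@dataclass
class DecodingResult:
    predictions: np.ndarray       # trials x time, cross-validated
    time: np.ndarray
    r2: float
    mae_ms: float
    seed: int
    n_folds: int


def weighted_readout(tensor: AlignedTensor, weights: WeightSet | np.ndarray,
                     window: tuple[float, float] | None = None) -> ReadoutResult:
    """Per-trial weighted sum of GrCs, its trial average, and its pooled
    correlation with time.

    The trial-average is also affinely mapped so its range spans the time
    window (oriented by the correlation sign), the normalization used for
    display and timing-accuracy comparisons.  A zero or constant readout is
    flagged degenerate with ``r`` = NaN.
    """
    w = weights.readout_vector if isinstance(weights, WeightSet) else np.asarray(weights, dtype=float)
    if w.size != tensor.values.shape[0]:
        raise ValueError("weight length does not match number of GrCs")
    mask = tensor.window_mask(window) if window is not None else np.ones(tensor.time.size, bool)
    vals = tensor.values[:, mask, :]
    time = tensor.time[mask]
    traces = np.einsum("c,ctk->kt", w, vals)
    avg = traces.mean(axis=0)

    t_pool = np.tile(time, traces.shape[0])
    y_pool = traces.reshape(-1)
    degenerate = bool(np.std(y_pool) == 0)
    r = float("nan") if degenerate else float(stats.pearsonr(t_pool, y_pool)[0])

    rng_y = avg.max() - avg.min()
    if rng_y == 0:
        slope, intercept = 0.0, float(time[0])
        norm = np.full_like(avg, time[0])
    else:
        sign = 1.0 if (degenerate or r >= 0) else -1.0
        slope = sign * (time[-1] - time[0]) / rng_y
        anchor = avg.min() if sign > 0 else avg.max()
        intercept = time[0] - slope * anchor
        norm = slope * avg + intercept
    return ReadoutResult(traces=traces, time=time, trial_average=avg,
                         normalized_average=norm, r=r, norm_slope=slope,
                         norm_intercept=intercept, degenerate=degenerate)


def timing_accuracy(result: ReadoutResult,
                    window: tuple[float, float] | None = None) -> float:
    """Coefficient of determination (squared pooled correlation) between
    frame time and readout over ``window``, pooled across trials."""
    mask = np.ones(result.time.size, bool) if window is None else (
        (result.time >= window[0]) & (result.time <= window[1]))
    t_pool = np.tile(result.time[mask], result.traces.shape[0])
    y_pool = result.traces[:, mask].reshape(-1)
    if np.std(y_pool) == 0:
        return float("nan")
    return float(stats.pearsonr(t_pool, y_pool)[0] ** 2)


def decode_time_cv(tensor: AlignedTensor, n_folds: int = 10, seed: int = 0,
                   ridge: bool = False, alpha: float = 1.0) -> DecodingResult:
    """10-fold cross-validated OLS decoding of elapsed time.

    Trials are concatenated along the time axis into an
    (n_trials x T, n_cells) design matrix with the relative time axis as
    target; folds partition trials.  Held-out predictions are retained for
    every (trial, frame) exactly once; R² and mean absolute error (ms) are
    computed on the pooled held-out predictions.  Raises when the OLS
    problem is ill-posed (more cells than training samples) unless
    ``ridge=True``.
    """
    n_cells, T, n_trials = tensor.values.shape
    if n_trials < n_folds:
        raise ValueError("need at least as many trials as folds")
    n_train = (n_trials - int(np.ceil(n_trials / n_folds))) * T
    if n_cells >= n_train and not ridge:
        raise ValueError("more cells than training samples: OLS ill-posed; "
                         "use ridge=True")
    X = tensor.values.transpose(2, 1, 0)   # trials x time x cells
    preds = np.full((n_trials, T), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(np.arange(n_trials)):
        Xtr = X[train_idx].reshape(-1, n_cells)
        ytr = np.tile(tensor.time, train_idx.size)
        model = Ridge(alpha=alpha) if ridge else LinearRegression()
        model.fit(Xtr, ytr)
        preds[test_idx] = model.predict(
            X[test_idx].reshape(-1, n_cells)).reshape(test_idx.size, T)
    y_true = np.tile(tensor.time, n_trials)
    y_hat = preds.reshape(-1)
    ss_res = float(((y_true - y_hat) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    mae_ms = float(np.abs(y_true - y_hat).mean() * 1000.0)
    return DecodingResult(predictions=preds, time=tensor.time, r2=r2,
                          mae_ms=mae_ms, seed=seed, n_folds=n_folds)


def compare_readouts(tensor: AlignedTensor, weight_sets: dict[str, WeightSet],
                     window: tuple[float, float] | None = None,
                     decode_seed: int = 0,
                     decode_folds: int = 10) -> pd.DataFrame:
    """Readout |r| and R² for each weight provenance plus the optimal
    cross-validated decoder, on the same session tensor."""
    rows = []
    for name, ws in weight_sets.items():
        res = weighted_readout(tensor, ws, window)
        rows.append({"provenance": name,
                     "abs_r": abs(res.r) if np.isfinite(res.r) else np.nan,
                     "r2": timing_accuracy(res)})
    try:
        dec = decode_time_cv(tensor, n_folds=decode_folds, seed=decode_seed)
        rows.append({"provenance": "optimal_decoder", "abs_r": np.nan,
                     "r2": dec.r2})
    except ValueError as err:
        logger.warning("optimal decoder skipped: %s", err)
    return pd.DataFrame(rows)


def behavior_readout_correlation(lick_preferences: np.ndarray,
                                 readout_accuracies: np.ndarray
                                 ) -> tuple[float, float]:
    """Spearman rank correlation between per-session lick-timing preference
    and per-session readout timing accuracy.  Returns (rho, p)."""
    rho, p = stats.spearmanr(lick_preferences, readout_accuracies)
    return float(rho), float(p)
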