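"""Leave-one-condition-out crossvalidation and prediction-quality metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TensorPair
from .npls import FitSettings, NPLSError, fit, predict
from .standardize import StandardizationSpec, apply_state, invert_predictions, standardize

__all__ = [
    "CVResult",
    "loo_crossvalidate",
    "select_optimal_lvs",
    "prediction_correlations",
]


@dataclass
class CVResult:
    rmse: np.ndarray  # standardized-scale RMSE per LV count 1..max_lvs
    rmse_raw: np.ndarray  # measurement-scale RMSE per LV count
    predicted: np.ndarray  # max_lvs x i x l x m, standardized scale
    measured: np.ndarray  # i x l x m, standardized (per-fold) scale
    conditions: tuple[str, ...]
    skipped_folds: list[tuple[str, str]] = field(default_factory=list)

    @property
    def max_lvs(self) -> int:
        return len(self.rmse)

    @property
    def optimal_n_lvs(self) -> int:
        return select_optimal_lvs(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lv_count": np.arange(1, self.max_lvs + 1),
                "rmse": self.rmse,
                "rmse_raw": self.rmse_raw,
            }
        )


def loo_crossvalidate(
    tensors: TensorPair,
    spec: StandardizationSpec,
    settings: FitSettings,
    max_lvs: int,
    refit_standardization: bool = True,
) -> CVResult:
    """Leave one condition out; refit standardization and model on the rest.

    ``tensors`` are the raw (pre-standardization) averaged arrays.  With
    ``refit_standardization=False`` the scaling state is computed once on the
    full data (the leakage-prone variant some pipelines use) instead of per
    fold.
    """
    i = len(tensors.conditions)
    if i < 3:
        raise NPLSError(f"leave-one-out needs >= 3 conditions, got {i}")
    if max_lvs < 1:
        raise NPLSError("max_lvs must be >= 1")
    if max_lvs > i - 1:
        raise NPLSError(f"max_lvs={max_lvs} exceeds i - 1 = {i - 1}")

    l, m = tensors.Y.shape[1], tensors.Y.shape[2]
    predicted = np.full((max_lvs, i, l, m), np.nan)
    measured = np.full((i, l, m), np.nan)
    raw_predicted = np.full((max_lvs, i, l, m), np.nan)
    skipped: list[tuple[str, str]] = []

    global_state = None
    if not refit_standardization:
        _, global_state = standardize(tensors, spec)

    for c in range(i):
        keep = [x for x in range(i) if x != c]
        train = TensorPair(
            X=tensors.X[keep], Y=tensors.Y[keep],
            conditions=tuple(tensors.conditions[x] for x in keep),
            x_times=tensors.x_times, x_vars=tensors.x_vars,
            y_times=tensors.y_times, y_vars=tensors.y_vars,
        )
        held = TensorPair(
            X=tensors.X[[c]], Y=tensors.Y[[c]],
            conditions=(tensors.conditions[c],),
            x_times=tensors.x_times, x_vars=tensors.x_vars,
            y_times=tensors.y_times, y_vars=tensors.y_vars,
        )
        try:
            if refit_standardization:
                train_std, state = standardize(train, spec)
            else:
                train_std, state = apply_state(train, global_state)
            model = fit(train_std.X, train_std.Y, FitSettings(
                n_lvs=max_lvs, tol=settings.tol,
                max_iterations=settings.max_iterations, seed=settings.seed,
            ))
            held_std, held_state = apply_state(held, state)
        except (NPLSError, ValueError) as exc:
            skipped.append((tensors.conditions[c], str(exc)))
            continue
        measured[c] = held_std.Y[0]
        for n in range(1, max_lvs + 1):
            # models on numerically exhausted residuals carry fewer LVs than
            # requested; the curve plateaus at the achievable count
            y_hat = predict(model, held_std.X, min(n, model.n_lvs))
            predicted[n - 1, c] = y_hat[0]
            raw_predicted[n - 1, c] = invert_predictions(y_hat, held_state)[0]

    ok = ~np.isnan(measured[:, 0, 0])
    if not ok.any():
        raise NPLSError("every crossvalidation fold failed")
    rmse = np.empty(max_lvs)
    rmse_raw = np.empty(max_lvs)
    for n in range(max_lvs):
        err = predicted[n, ok] - measured[ok]
        rmse[n] = float(np.sqrt(np.mean(err**2)))
        raw_err = raw_predicted[n, ok] - tensors.Y[ok]
        rmse_raw[n] = float(np.sqrt(np.mean(raw_err**2)))

    return CVResult(
        rmse=rmse, rmse_raw=rmse_raw, predicted=predicted, measured=measured,
        conditions=tensors.conditions, skipped_folds=skipped,
    )


def select_optimal_lvs(cv_result: CVResult) -> int:
    """Smallest LV count attaining the minimum crossvalidated RMSE."""
    if cv_result.max_lvs == 0:
        raise NPLSError("empty RMSE curve")
    return int(np.argmin(cv_result.rmse)) + 1


def prediction_correlations(
    cv_result: CVResult, n_lvs: int | None = None
) -> tuple[float, float]:
    """Pearson R and Spearman rho of pooled crossvalidated predictions.

    Returns ``(nan, nan)`` when either pooled vector has zero variance.
    """
    n = cv_result.optimal_n_lvs if n_lvs is None else n_lvs
    ok = ~np.isnan(cv_result.measured[:, 0, 0])
    pred = cv_result.predicted[n - 1, ok].ravel()
    meas = cv_result.measured[ok].ravel()
    if pred.size < 3:
        raise NPLSError("need >= 3 pooled prediction/measurement pairs")
    if np.std(pred) == 0 or np.std(meas) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(pred, meas).statistic)
    rho = float(stats.spearmanr(pred, meas).statistic)
    return r, rho
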