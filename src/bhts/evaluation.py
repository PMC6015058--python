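"""ROC/AUC evaluation, binary threshold sweeps, hyperparameter sensitivity,
and MCMC trace diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bhts_core import BhtsHyperparameters, run_sampler
from .errors import DomainError, UndefinedRocError, ValidationError
from .plate_io import ScreenDataset

__all__ = [
    "RocCurve",
    "ThresholdSweep",
    "roc",
    "binary_sweep_auc",
    "sensitivity_sweep",
    "mcmc_diagnostics",
]


@dataclass
class RocCurve:
    """ROC points (FPR, TPR) from (0,0) to (1,1) plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self):
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass
class ThresholdSweep:
    """AUC of the binary predictor 1(score > t) across a cutoff grid."""

    thresholds: np.ndarray
    auc_at_threshold: np.ndarray
    best_threshold: float
    best_auc: float


def _check_binary(scores, truth):
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape or s.ndim != 1:
        raise DomainError("scores and truth must be equal-length 1-D vectors")
    if t.all() or not t.any():
        raise UndefinedRocError("truth labels contain a single class")
    return s, t


def roc(scores, truth) -> RocCurve:
    """ROC curve with tied scores collapsed into single cutoffs.

    The trapezoidal AUC then equals the Mann-Whitney U statistic divided by
    n1*n0 (ties counted 1/2).
    """
    s, t = _check_binary(scores, truth)
    fpr, tpr, _ = _sk_roc_curve(t.astype(int), s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def binary_sweep_auc(scores, truth, n_grid: int = 101) -> ThresholdSweep:
    """Best achievable AUC of a single binarization of the score.

    For each cutoff ``t`` in an even grid between min and max score, the
    binary predictor ``1(score > t)`` has AUC ``(TPR + TNR) / 2``; the sweep
    reports the whole curve and its maximizer (first cutoff attaining the
    maximum).
    """
    s, t = _check_binary(scores, truth)
    if n_grid < 2:
        raise DomainError("n_grid must be >= 2")
    grid = np.linspace(s.min(), s.max(), n_grid)
    pred = s[None, :] > grid[:, None]  # (n_grid, n)
    tprs = pred[:, t].mean(axis=1)
    tnrs = (~pred)[:, ~t].mean(axis=1)
    aucs = 0.5 * (tprs + tnrs)
    best = int(np.argmax(aucs))
    return ThresholdSweep(
        thresholds=grid,
        auc_at_threshold=aucs,
        best_threshold=float(grid[best]),
        best_auc=float(aucs[best]),
    )


def sensitivity_sweep(
    dataset: ScreenDataset,
    base_hyper: BhtsHyperparameters,
    deltas,
    n_iter: int = 3000,
    burn_in: int = 1000,
    thin: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC of posterior hit probabilities across a grid of prior-mean gaps.

    For each ``delta`` the sampler is rerun with ``mu10 = mu00 + delta``
    (all other hyperparameters fixed); requires truth labels.
    """
    if dataset.truth is None:
        raise ValidationError("sensitivity sweep requires truth labels")
    rows = []
    for delta in deltas:
        if delta <= 0:
            raise ValidationError(f"prior-mean gap must be positive, got {delta}")
        hyper = replace(base_hyper, mu10=base_hyper.mu00 + float(delta))
        summary = run_sampler(
            dataset, hyper, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed
        )
        curve = roc(summary.hit_prob, dataset.truth)
        rows.append({"delta": float(delta), "auc": curve.auc})
    return pd.DataFrame(rows)


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(x[:-k] @ x[k:]) / denom
    return acf


def mcmc_diagnostics(traces: dict, max_lag: int = 50) -> dict:
    """Per-trace autocorrelations, effective sample size, and mean.

    ESS uses the initial-positive-sequence truncation (sum autocorrelations
    until the first negative lag, capped at ``max_lag``).  Constant traces
    are flagged; their ACF beyond lag 0 is undefined (NaN).
    """
    out = {}
    for name, trace in traces.items():
        x = np.asarray(trace, dtype=float)
        if x.size < 10:
            raise DomainError(f"trace {name!r}: need >= 10 kept samples")
        lag = min(max_lag, x.size - 1)
        if np.ptp(x) == 0.0:
            acf = np.full(lag + 1, np.nan)
            acf[0] = 1.0
            out[name] = {
                "mean": float(x[0]),
                "acf": acf,
                "ess": float("nan"),
                "constant": True,
            }
            continue
        acf = _acf(x, lag)
        rho_sum = 0.0
        for k in range(1, lag + 1):
            if acf[k] < 0:
                break
            rho_sum += acf[k]
        ess = x.size / (1.0 + 2.0 * rho_sum)
        out[name] = {
            "mean": float(x.mean()),
            "acf": acf,
            "ess": float(ess),
            "constant": False,
        }
    return out
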