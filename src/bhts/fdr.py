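"""Bayesian FDR estimation from posterior hit probabilities.

The estimated FDR at threshold ``r`` is the mean posterior probability of
being a non-hit among the wells called (those with posterior probability
strictly above ``r``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UndefinedFdrError

__all__ = ["FdrResult", "estimate_fdr", "select_threshold"]


@dataclass
class FdrResult:
    """Outcome of threshold selection at a target FDR."""

    threshold: float
    fdr_estimate: float
    n_called: int
    calls: np.ndarray
    attained: bool


def _check_probs(hit_prob) -> np.ndarray:
    p = np.asarray(hit_prob, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("hit probabilities must be a non-empty 1-D vector")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise DomainError("hit probabilities must lie in [0, 1]")
    return p


def estimate_fdr(hit_prob, r: float) -> float:
    """Estimated Bayesian FDR of calling every well with probability > r.

    Raises :class:`UndefinedFdrError` when no well exceeds ``r`` (distinct
    from an estimate of 0).
    """
    p = _check_probs(hit_prob)
    called = p > r
    n_called = int(called.sum())
    if n_called == 0:
        raise UndefinedFdrError(f"no well has posterior probability > {r}")
    return float((1.0 - p[called]).sum() / n_called)


def select_threshold(hit_prob, target_fdr: float) -> FdrResult:
    """Smallest threshold on the observed probability grid meeting the target.

    The estimator is a step function of ``r``, so only observed unique
    probabilities are candidate thresholds; the smallest qualifying one is
    returned (equivalently, the one making the most calls).  If no
    threshold attains the target, the result is flagged and calls nothing.
    """
    p = _check_probs(hit_prob)
    if not (0.0 < target_fdr < 1.0):
        raise DomainError("target FDR must lie strictly between 0 and 1")
    grid = np.unique(p)
    for r in grid[:-1] if grid.size > 1 else []:
        fdr = estimate_fdr(p, r)
        if fdr <= target_fdr:
            calls = p > r
            return FdrResult(
                threshold=float(r),
                fdr_estimate=fdr,
                n_called=int(calls.sum()),
                calls=calls,
                attained=True,
            )
    return FdrResult(
        threshold=float("nan"),
        fdr_estimate=float("nan"),
        n_called=0,
        calls=np.zeros(p.size, dtype=bool),
        attained=False,
    )
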