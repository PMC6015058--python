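"""Classical per-plate normalization scores: NPI, Z-score, B-score, R-score.

B and R scores are computed on the complete rectangular sub-grid of compound
wells (control columns are stripped first); control wells carry NaN in the
returned score matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConvergenceError,
    DegeneratePlateError,
    DegenerateResidualError,
    DegenerateScaleError,
    GeometryError,
    InputError,
    UndefinedControlWindowError,
)
from .plate_io import Plate

__all__ = [
    "PolishDecomposition",
    "ScoreMatrix",
    "npi",
    "npi_plate",
    "zscore",
    "median_polish",
    "bscore",
    "rscore",
    "mad",
]

#: normal-consistency constant for the median absolute deviation
MAD_CONSTANT = 1.4826


@dataclass
class PolishDecomposition:
    """Additive two-way decomposition from Tukey's median polish.

    ``overall + row_effects[i] + col_effects[j] + residuals[i, j]``
    reconstructs the input matrix.
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


@dataclass
class ScoreMatrix:
    """Per-plate score values aligned to plate geometry.

    ``method`` is one of ``NPI``/``Z``/``B``/``R``; wells that are not
    scored (controls for Z/B/R) hold NaN.
    """

    plate_id: str
    method: str
    values: np.ndarray


def mad(x: np.ndarray, constant: float = MAD_CONSTANT) -> float:
    """Median absolute deviation about the median, normal-consistent."""
    x = np.asarray(x, dtype=float)
    return constant * float(np.median(np.abs(x - np.median(x))))


def npi(z: float, z_n: float, z_p: float) -> float:
    """Normalized percent inhibition, in percent.

    Scales a readout between the positive (0%) and negative (100%) control
    levels: ``(z_p - z) / (z_p - z_n) * 100``.
    """
    if z_p == z_n:
        raise UndefinedControlWindowError("positive and negative controls coincide")
    return (z_p - z) / (z_p - z_n) * 100.0


def npi_plate(plate: Plate) -> ScoreMatrix:
    """NPI for each compound well, using mean plate control readouts."""
    from .plate_io import WellRole

    roles = plate.roles
    neg = plate.values[np.vectorize(lambda r: r is WellRole.NEGATIVE_CONTROL)(roles)]
    pos = plate.values[np.vectorize(lambda r: r is WellRole.POSITIVE_CONTROL)(roles)]
    if neg.size == 0 or pos.size == 0:
        raise UndefinedControlWindowError(
            f"plate {plate.plate_id!r}: NPI requires both control roles"
        )
    z_n, z_p = float(neg.mean()), float(pos.mean())
    if z_p == z_n:
        raise UndefinedControlWindowError(
            f"plate {plate.plate_id!r}: control window is zero"
        )
    values = np.full(plate.values.shape, np.nan)
    mask = plate.compound_mask
    values[mask] = (z_p - plate.values[mask]) / (z_p - z_n) * 100.0
    return ScoreMatrix(plate.plate_id, "NPI", values)


def zscore(plate: Plate) -> ScoreMatrix:
    """Per-plate Z-score over compound wells (sample-sd convention)."""
    mask = plate.compound_mask
    vals = plate.values[mask]
    if vals.size < 2:
        raise DegeneratePlateError(
            f"plate {plate.plate_id!r}: Z-score needs >= 2 compound wells"
        )
    sd = vals.std(ddof=1)
    if sd == 0.0:
        raise DegeneratePlateError(f"plate {plate.plate_id!r}: zero compound variance")
    values = np.full(plate.values.shape, np.nan)
    values[mask] = (vals - vals.mean()) / sd
    return ScoreMatrix(plate.plate_id, "Z", values)


def median_polish(matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> PolishDecomposition:
    """Tukey's median polish of a complete two-way table.

    Alternates subtraction of row and column medians until the total
    absolute adjustment of a full sweep drops below ``tol`` times the scale
    of the matrix, or ``max_iter`` sweeps are reached.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise InputError("median_polish expects a non-empty 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise InputError("median_polish: non-finite entries")
    n_rows, n_cols = x.shape
    residuals = x.copy()
    overall = 0.0
    row_effects = np.zeros(n_rows)
    col_effects = np.zeros(n_cols)
    scale = float(np.abs(x).max())
    if scale == 0.0:
        scale = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(residuals, axis=1)
        residuals -= rdelta[:, None]
        row_effects += rdelta
        delta = float(np.median(col_effects))
        col_effects -= delta
        overall += delta
        cdelta = np.median(residuals, axis=0)
        residuals -= cdelta[None, :]
        col_effects += cdelta
        delta2 = float(np.median(row_effects))
        row_effects -= delta2
        overall += delta2
        adjustment = float(np.abs(rdelta).sum() + np.abs(cdelta).sum())
        if adjustment < tol * scale:
            converged = True
            break
    return PolishDecomposition(
        overall=overall,
        row_effects=row_effects,
        col_effects=col_effects,
        residuals=residuals,
        n_iter=it,
        converged=converged,
    )


def _compound_subgrid(plate: Plate):
    """Extract the complete rectangular compound sub-grid of a plate."""
    mask = plate.compound_mask
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    if not mask[np.ix_(rows, cols)].all():
        raise GeometryError(
            f"plate {plate.plate_id!r}: compound wells do not form a complete sub-grid"
        )
    return plate.values[np.ix_(rows, cols)], rows, cols


def bscore(plate: Plate, tol: float = 1e-10, max_iter: int = 100) -> ScoreMatrix:
    """B-score: median-polish residuals over their MAD.

    Controls are stripped before polishing; the polish runs on the compound
    sub-grid only.
    """
    sub, rows, cols = _compound_subgrid(plate)
    polish = median_polish(sub, tol=tol, max_iter=max_iter)
    scale = mad(polish.residuals.ravel())
    if scale == 0.0:
        raise DegenerateResidualError(
            f"plate {plate.plate_id!r}: polish residuals have zero MAD"
        )
    values = np.full(plate.values.shape, np.nan)
    values[np.ix_(rows, cols)] = polish.residuals / scale
    return ScoreMatrix(plate.plate_id, "B", values)


def _additive_design(n_rows: int, n_cols: int) -> np.ndarray:
    """Design matrix for mu + row_i + col_j with sum-to-zero coding."""
    n = n_rows * n_cols
    p = 1 + (n_rows - 1) + (n_cols - 1)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    idx = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if i < n_rows - 1:
                X[idx, 1 + i] = 1.0
            else:
                X[idx, 1 : n_rows] = -1.0
            if j < n_cols - 1:
                X[idx, n_rows + j] = 1.0
            else:
                X[idx, n_rows : n_rows + n_cols - 1] = -1.0
            idx += 1
    return X


def rscore(
    plate: Plate,
    tuning: float = 1.345,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ScoreMatrix:
    """R-score: robust (Huber IRLS) additive row/column fit residuals over
    the robust scale estimate.

    The scale is the MAD of the residuals (constant 1.4826), re-estimated at
    every IRLS iteration.
    """
    sub, rows, cols = _compound_subgrid(plate)
    n_rows, n_cols = sub.shape
    if n_rows + n_cols - 1 >= sub.size:
        raise GeometryError(
            f"plate {plate.plate_id!r}: too few compound wells for an additive fit"
        )
    X = _additive_design(n_rows, n_cols)
    y = sub.ravel()
    # scale below this is numerically indistinguishable from an exact fit
    scale_floor = 1e-10 * max(1.0, float(np.abs(y).max()))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = mad(resid)
    converged = False
    for _ in range(max_iter):
        if scale <= scale_floor:
            raise DegenerateScaleError(
                f"plate {plate.plate_id!r}: robust scale collapsed to zero"
            )
        u = np.abs(resid) / scale
        w = np.where(u <= tuning, 1.0, tuning / np.maximum(u, 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        resid = y - X @ beta
        scale = mad(resid)
        if step <= tol * (1.0 + float(np.max(np.abs(beta)))):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"plate {plate.plate_id!r}: IRLS did not converge in {max_iter} iterations",
            last_iterate=beta,
        )
    if scale <= scale_floor:
        raise DegenerateScaleError(
            f"plate {plate.plate_id!r}: robust scale collapsed to zero"
        )
    values = np.full(plate.values.shape, np.nan)
    values[np.ix_(rows, cols)] = (resid / scale).reshape(n_rows, n_cols)
    return ScoreMatrix(plate.plate_id, "R", values)
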