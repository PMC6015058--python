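"""Data model for multi-plate compound screens and long-format table I/O.

The canonical interchange format is a CSV with header
``plate_id,row,col,role,readout[,truth]``; coordinates are 0-based and
row-major, roles are ``compound``/``pos``/``neg``.  A :class:`ScreenDataset`
holds an ordered list of rectangular :class:`Plate` grids plus an optional
flat vector of ground-truth hit labels covering exactly the compound wells
(plate file order, then row-major within each plate).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePlateError,
    FormatError,
    IntegrityError,
    ParseError,
)

__all__ = [
    "WellRole",
    "Well",
    "Plate",
    "ScreenDataset",
    "read_plates",
    "write_results",
    "standardize_plates",
]


class WellRole(enum.Enum):
    """Role of a well on a plate; values are the on-disk tokens."""

    COMPOUND = "compound"
    POSITIVE_CONTROL = "pos"
    NEGATIVE_CONTROL = "neg"


_ROLE_ALIASES = {
    "compound": WellRole.COMPOUND,
    "pos": WellRole.POSITIVE_CONTROL,
    "positive_control": WellRole.POSITIVE_CONTROL,
    "neg": WellRole.NEGATIVE_CONTROL,
    "negative_control": WellRole.NEGATIVE_CONTROL,
}

_REQUIRED_COLUMNS = ("plate_id", "row", "col", "role", "readout")


@dataclass(frozen=True)
class Well:
    """A single well; mostly a convenience view into a :class:`Plate`."""

    plate_id: str
    row: int
    col: int
    role: WellRole
    readout: float


@dataclass
class Plate:
    """One rectangular grid of readouts with per-well roles.

    ``values`` is an ``(n_rows, n_cols)`` float array; ``roles`` an object
    array of :class:`WellRole` of the same shape.  The grid is always
    complete.
    """

    plate_id: str
    values: np.ndarray
    roles: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.values.ndim != 2 or self.values.shape != self.roles.shape:
            raise IntegrityError(
                f"plate {self.plate_id!r}: values and roles must be equal 2-D shapes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError(f"plate {self.plate_id!r}: non-finite readout")
        for r in self.roles.ravel():
            if not isinstance(r, WellRole):
                raise IntegrityError(f"plate {self.plate_id!r}: bad role {r!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def compound_mask(self) -> np.ndarray:
        return np.vectorize(lambda r: r is WellRole.COMPOUND, otypes=[bool])(self.roles)

    @property
    def compound_values(self) -> np.ndarray:
        """Readouts of compound wells, row-major order."""
        return self.values[self.compound_mask]

    def well(self, row: int, col: int) -> Well:
        return Well(self.plate_id, row, col, self.roles[row, col], float(self.values[row, col]))

    def n_compound_wells(self) -> int:
        return int(self.compound_mask.sum())


@dataclass
class ScreenDataset:
    """Ordered collection of plates, optionally with ground-truth hit labels.

    ``truth`` (when present) is a flat boolean array over compound wells in
    canonical order: plates in list order, row-major within each plate.
    """

    plates: list = field(default_factory=list)
    truth: np.ndarray | None = None

    def __post_init__(self):
        if len(self.plates) < 1:
            raise IntegrityError("dataset must contain at least one plate")
        ids = [p.plate_id for p in self.plates]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate plate_id in dataset")
        for p in self.plates:
            if p.n_compound_wells() < 1:
                raise IntegrityError(f"plate {p.plate_id!r} has no compound wells")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=bool)
            if self.truth.shape != (self.n_compound_wells,):
                raise IntegrityError(
                    "truth must cover exactly the compound wells "
                    f"({self.n_compound_wells}), got {self.truth.shape}"
                )
        self._flat_cache = None

    @property
    def M(self) -> int:
        """Number of plates."""
        return len(self.plates)

    @property
    def n_per_plate(self) -> list:
        """Number of compound wells on each plate (n_m)."""
        return [p.n_compound_wells() for p in self.plates]

    @property
    def n_compound_wells(self) -> int:
        return int(sum(self.n_per_plate))

    def _flat(self):
        """Flat (readouts, plate_index, rows, cols) over compound wells."""
        if self._flat_cache is None:
            z, pidx, rows, cols = [], [], [], []
            for m, p in enumerate(self.plates):
                mask = p.compound_mask
                rr, cc = np.nonzero(mask)
                z.append(p.values[rr, cc])
                pidx.append(np.full(rr.size, m, dtype=np.int64))
                rows.append(rr)
                cols.append(cc)
            self._flat_cache = (
                np.concatenate(z),
                np.concatenate(pidx),
                np.concatenate(rows),
                np.concatenate(cols),
            )
        return self._flat_cache

    def compound_readouts(self) -> np.ndarray:
        return self._flat()[0]

    def compound_plate_index(self) -> np.ndarray:
        return self._flat()[1]

    def compound_coords(self) -> pd.DataFrame:
        _, pidx, rows, cols = self._flat()
        ids = np.array([p.plate_id for p in self.plates], dtype=object)
        return pd.DataFrame(
            {"plate_id": ids[pidx], "row": rows.astype(int), "col": cols.astype(int)}
        )

    def to_table(self) -> pd.DataFrame:
        """Full long-format table over all wells in canonical order."""
        recs = []
        truth_iter = iter(self.truth) if self.truth is not None else None
        for p in self.plates:
            for r in range(p.n_rows):
                for c in range(p.n_cols):
                    role = p.roles[r, c]
                    rec = {
                        "plate_id": p.plate_id,
                        "row": r,
                        "col": c,
                        "role": role.value,
                        "readout": float(p.values[r, c]),
                    }
                    if truth_iter is not None:
                        rec["truth"] = (
                            int(next(truth_iter)) if role is WellRole.COMPOUND else np.nan
                        )
                    recs.append(rec)
        return pd.DataFrame.from_records(recs)


def read_plates(path, sep: str = ",") -> ScreenDataset:
    """Read a long-format plate table into a :class:`ScreenDataset`.

    Plates appear in file order; each plate's geometry is inferred from the
    maximum row/column index and the grid must be complete.  An optional
    ``truth`` column (0/1 on compound wells) is loaded as ground truth.
    """
    df = pd.read_csv(path, sep=sep, dtype={"plate_id": str}, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError("empty plate table")
    readout = pd.to_numeric(df["readout"], errors="coerce")
    if readout.isna().any():
        bad = df.loc[readout.isna()].iloc[0]
        raise ParseError(
            f"non-numeric readout at ({bad['plate_id']},{bad['row']},{bad['col']})"
        )
    df = df.assign(readout=readout.astype(float))
    try:
        df = df.assign(row=df["row"].astype(int), col=df["col"].astype(int))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-integer row/col index: {exc}") from exc
    dup = df.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate well ({bad['plate_id']},{bad['row']},{bad['col']})"
        )

    has_truth = "truth" in df.columns
    plates = []
    truth_parts = []
    for pid in pd.unique(df["plate_id"]):
        sub = df[df["plate_id"] == pid]
        n_rows = int(sub["row"].max()) + 1
        n_cols = int(sub["col"].max()) + 1
        if sub["row"].min() < 0 or sub["col"].min() < 0:
            raise IntegrityError(f"plate {pid!r}: negative well coordinate")
        if len(sub) != n_rows * n_cols:
            raise IntegrityError(
                f"plate {pid!r}: incomplete grid ({len(sub)} wells for "
                f"{n_rows}x{n_cols} geometry)"
            )
        values = np.full((n_rows, n_cols), np.nan)
        roles = np.empty((n_rows, n_cols), dtype=object)
        for _, rec in sub.iterrows():
            tok = str(rec["role"]).strip().lower()
            if tok not in _ROLE_ALIASES:
                raise ParseError(f"plate {pid!r}: unknown role {rec['role']!r}")
            roles[rec["row"], rec["col"]] = _ROLE_ALIASES[tok]
            values[rec["row"], rec["col"]] = rec["readout"]
        plates.append(Plate(plate_id=str(pid), values=values, roles=roles))
        if has_truth:
            sub = sub.sort_values(["row", "col"], kind="stable")
            mask = sub["role"].map(lambda t: _ROLE_ALIASES[str(t).strip().lower()]
                                   is WellRole.COMPOUND)
            tvals = pd.to_numeric(sub.loc[mask, "truth"], errors="coerce")
            if tvals.isna().any():
                raise ParseError(f"plate {pid!r}: missing/non-numeric truth on compound well")
            truth_parts.append(tvals.to_numpy().astype(bool))
    truth = np.concatenate(truth_parts) if has_truth else None
    return ScreenDataset(plates=plates, truth=truth)


def write_results(dataset: ScreenDataset, scores: pd.DataFrame | None, path) -> None:
    """Write a long-format results file.

    ``scores`` is keyed by ``(plate_id,row,col)`` with one extra column per
    method; ``None`` writes every well with no method columns.  Rows appear
    in canonical dataset order (plate order, then row-major), restricted to
    the wells present in ``scores``.  Readouts are written with shortest
    round-tripping decimal representation.
    """
    fmt = lambda v: repr(float(v))  # noqa: E731 — shortest exact round-trip
    base = dataset.to_table()
    if scores is None:
        base.to_csv(path, index=False, float_format=fmt)
        return
    for key in ("plate_id", "row", "col"):
        if key not in scores.columns:
            raise FormatError(f"score table missing key column {key!r}")
    method_cols = [c for c in scores.columns if c not in ("plate_id", "row", "col")]
    merged = base.merge(scores, on=["plate_id", "row", "col"], how="inner")
    if len(merged) != len(scores):
        raise IntegrityError("score table references wells absent from dataset")
    merged.to_csv(path, index=False, float_format=fmt)


def standardize_plates(dataset: ScreenDataset) -> ScreenDataset:
    """Per plate, rescale compound readouts to sample mean 0 / variance 1.

    Control wells pass through untouched; truth labels are preserved.
    Idempotent up to floating-point error.
    """
    plates = []
    for p in dataset.plates:
        mask = p.compound_mask
        vals = p.values[mask]
        if vals.size < 2:
            raise DegeneratePlateError(
                f"plate {p.plate_id!r}: needs >= 2 compound wells to standardize"
            )
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0.0:
            raise DegeneratePlateError(
                f"plate {p.plate_id!r}: zero within-plate variance"
            )
        new_values = p.values.copy()
        new_values[mask] = (vals - mu) / sd
        plates.append(Plate(plate_id=p.plate_id, values=new_values, roles=p.roles))
    truth = None if dataset.truth is None else dataset.truth.copy()
    return ScreenDataset(plates=plates, truth=truth)
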