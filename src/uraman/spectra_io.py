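"""Reading, writing and aligning Raman spectra and specimen metadata.

Spectra travel in two plain-CSV dialects:

* **wide** — first column ``raman_shift_cm-1``, one column per scan headed
  ``<specimen_id>:<scan_index>`` (or a bare specimen id for averaged,
  single-scan-per-specimen sets);
* **long** — columns ``specimen_id,scan_index,raman_shift_cm-1,intensity``.

Specimen metadata is a CSV with the fixed, case-sensitive header
``specimen_id,donor_id,sex,birth_year,collection_date,menstruation,is_control``.

All downstream analysis operates on a :class:`SpectrumSet`: an intensity
matrix whose rows are scans (or specimens, after replicate averaging)
aligned on a common Raman-shift grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    FormatError,
    GridRangeError,
    ParseError,
    ValidationError,
)

#: Default working grid: 250-1950 cm^-1 at 2 cm^-1 spacing (851 channels).
#: The acquisition range of a dispersive instrument with ~8 cm^-1 spectral
#: resolution; 2 cm^-1 oversamples that resolution safely.
DEFAULT_GRID = np.arange(250.0, 1952.0, 2.0)

METADATA_COLUMNS = (
    "specimen_id",
    "donor_id",
    "sex",
    "birth_year",
    "collection_date",
    "menstruation",
    "is_control",
)

_SHIFT_HEADER = "raman_shift_cm-1"


@dataclass
class RamanSpectrum:
    """A single Raman scan: intensities over an ascending shift axis."""

    shifts: np.ndarray
    intensities: np.ndarray
    specimen_id: str
    scan_index: int = 1

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("shifts and intensities must be 1-D")
        if self.shifts.size != self.intensities.size:
            raise ValidationError(
                f"shifts ({self.shifts.size}) and intensities "
                f"({self.intensities.size}) differ in length"
            )
        if self.shifts.size < 2:
            raise ValidationError("a spectrum needs at least 2 channels")
        if not np.all(np.isfinite(self.shifts)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValidationError(
                f"non-finite values in spectrum {self.specimen_id!r}"
            )
        if not np.all(np.diff(self.shifts) > 0):
            raise ValidationError(
                f"shifts not strictly increasing in spectrum {self.specimen_id!r}"
            )
        self.scan_index = int(self.scan_index)
        if self.scan_index < 1:
            raise ValidationError("scan_index must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.shifts.size


@dataclass
class SpectrumSet:
    """Aligned intensity matrix: one row per scan or specimen.

    ``scan_indices`` is present while rows are individual scans (row keys
    are then (specimen_id, scan_index) pairs); after replicate averaging it
    is ``None`` and specimen_ids themselves must be unique.
    """

    grid: np.ndarray
    matrix: np.ndarray
    specimen_ids: list[str]
    scan_indices: list[int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        if self.grid.ndim != 1 or not np.all(np.diff(self.grid) > 0):
            raise ValidationError("grid must be 1-D and strictly increasing")
        n, p = self.matrix.shape
        if n != len(self.specimen_ids):
            raise ValidationError(
                f"{n} matrix rows but {len(self.specimen_ids)} specimen_ids"
            )
        if p != self.grid.size:
            raise DimensionError(
                f"{p} matrix columns but {self.grid.size} grid channels"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite intensities in SpectrumSet")
        if self.scan_indices is not None:
            self.scan_indices = [int(i) for i in self.scan_indices]
            if len(self.scan_indices) != n:
                raise ValidationError("scan_indices length mismatch")
            keys = list(zip(self.specimen_ids, self.scan_indices))
        else:
            keys = list(self.specimen_ids)
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate row keys: {dupes[:5]}")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.grid.size

    def subset(self, row_indices) -> "SpectrumSet":
        """Row subset, preserving order of ``row_indices``."""
        idx = np.asarray(row_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(
            grid=self.grid,
            matrix=self.matrix[idx],
            specimen_ids=[self.specimen_ids[i] for i in idx],
            scan_indices=(
                None
                if self.scan_indices is None
                else [self.scan_indices[i] for i in idx]
            ),
        )

    def row(self, specimen_id: str) -> np.ndarray:
        try:
            i = self.specimen_ids.index(specimen_id)
        except ValueError:
            raise KeyError(specimen_id) from None
        return self.matrix[i]


def read_scan_matrix(path: str | Path, dialect: str = "wide") -> list[RamanSpectrum]:
    """Read raw scans from a wide or long CSV into RamanSpectrum objects."""
    path = Path(path)
    if dialect == "wide":
        return _read_wide(path)
    if dialect == "long":
        return _read_long(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    # numpy's string->double conversion is correctly rounded, unlike the
    # pandas CSV fast path; required for the bit-for-bit round-trip.
    raw = df.to_numpy(dtype=object)
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        values = np.empty(raw.shape, dtype=float)
        for (r, c), cell in np.ndenumerate(raw):
            try:
                values[r, c] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell at data row {r + 1}, "
                    f"column {df.columns[c]!r} (value {cell!r})"
                ) from None
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-finite cell at data row {r + 1}, "
            f"column {df.columns[c]!r} (value {raw[r, c]!r})"
        )
    return pd.DataFrame(values, columns=df.columns)


def _split_scan_header(header: str) -> tuple[str, int]:
    if ":" in header:
        sid, _, idx = header.rpartition(":")
        try:
            return sid, int(idx)
        except ValueError as exc:
            raise FormatError(f"bad scan header {header!r}") from exc
    return header, 1


def _read_wide(path: Path) -> list[RamanSpectrum]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a shift column plus >=1 scan column")
    if df.columns[0] != _SHIFT_HEADER:
        raise FormatError(
            f"{path}: first column must be {_SHIFT_HEADER!r}, got {df.columns[0]!r}"
        )
    num = _to_numeric(df, path)
    shifts = num.iloc[:, 0].to_numpy()
    if np.unique(shifts).size != shifts.size:
        raise FormatError(f"{path}: duplicate Raman-shift values")
    order = np.argsort(shifts)
    spectra = []
    for col in df.columns[1:]:
        sid, scan = _split_scan_header(col)
        spectra.append(
            RamanSpectrum(
                shifts=shifts[order],
                intensities=num[col].to_numpy()[order],
                specimen_id=sid,
                scan_index=scan,
            )
        )
    return spectra


def _read_long(path: Path) -> list[RamanSpectrum]:
    df = pd.read_csv(path, dtype=str)
    expected = ["specimen_id", "scan_index", _SHIFT_HEADER, "intensity"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: long dialect header must be {expected}")
    num = _to_numeric(df[[_SHIFT_HEADER, "intensity"]], path)
    df = df.assign(
        _shift=num[_SHIFT_HEADER].to_numpy(), _int=num["intensity"].to_numpy()
    )
    spectra = []
    for (sid, scan), grp in df.groupby(
        ["specimen_id", "scan_index"], sort=False
    ):
        shifts = grp["_shift"].to_numpy()
        if np.unique(shifts).size != shifts.size:
            raise FormatError(
                f"{path}: duplicate shift within scan {sid}:{scan}"
            )
        order = np.argsort(shifts)
        spectra.append(
            RamanSpectrum(
                shifts=shifts[order],
                intensities=grp["_int"].to_numpy()[order],
                specimen_id=str(sid),
                scan_index=int(scan),
            )
        )
    return spectra


def write_scan_matrix(
    spectra: list[RamanSpectrum] | SpectrumSet, path: str | Path
) -> None:
    """Write scans in the wide dialect with full float precision.

    ``repr`` of a Python float is the shortest string that round-trips,
    so write→read reproduces values bit-for-bit.
    """
    path = Path(path)
    if isinstance(spectra, SpectrumSet):
        grid = spectra.grid
        columns = []
        for i, sid in enumerate(spectra.specimen_ids):
            head = (
                sid
                if spectra.scan_indices is None
                else f"{sid}:{spectra.scan_indices[i]}"
            )
            columns.append((head, spectra.matrix[i]))
    else:
        if not spectra:
            raise ValidationError("no spectra to write")
        grid = spectra[0].shifts
        for s in spectra[1:]:
            if s.shifts.size != grid.size or not np.allclose(
                s.shifts, grid, rtol=0, atol=0
            ):
                raise DimensionError(
                    "wide dialect requires a shared shift axis; resample first"
                )
        columns = [
            (f"{s.specimen_id}:{s.scan_index}", s.intensities) for s in spectra
        ]
    with open(path, "w") as fh:
        fh.write(",".join([_SHIFT_HEADER] + [c for c, _ in columns]) + "\n")
        for j in range(grid.size):
            row = [repr(float(grid[j]))] + [
                repr(float(v[j])) for _, v in columns
            ]
            fh.write(",".join(row) + "\n")


def read_set(path: str | Path) -> SpectrumSet:
    """Read a wide CSV directly into a SpectrumSet (rows = columns of file)."""
    spectra = _read_wide(Path(path))
    grid = spectra[0].shifts
    return assemble_set(spectra, grid)


def resample_to_grid(spectrum: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto ``grid``; never extrapolates."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.shifts[0], spectrum.shifts[-1]
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise GridRangeError(
            f"grid [{grid[0]}, {grid[-1]}] exceeds source range [{lo}, {hi}] "
            f"for specimen {spectrum.specimen_id!r}"
        )
    if grid.size == spectrum.shifts.size and np.array_equal(grid, spectrum.shifts):
        intensities = spectrum.intensities.copy()
    else:
        intensities = np.interp(grid, spectrum.shifts, spectrum.intensities)
    return RamanSpectrum(
        shifts=grid,
        intensities=intensities,
        specimen_id=spectrum.specimen_id,
        scan_index=spectrum.scan_index,
    )


def assemble_set(
    spectra: list[RamanSpectrum], grid: np.ndarray | None = None
) -> SpectrumSet:
    """Resample scans onto a common grid and stack them, input order kept."""
    if not spectra:
        raise ValidationError("assemble_set: empty spectrum list")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    rows = [resample_to_grid(s, grid).intensities for s in spectra]
    return SpectrumSet(
        grid=grid,
        matrix=np.vstack(rows),
        specimen_ids=[s.specimen_id for s in spectra],
        scan_indices=[s.scan_index for s in spectra],
    )


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(value: str, row: int, column: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise ValidationError(
            f"row {row}: {column} must be one of true/false/0/1, got {value!r}"
        )
    return _BOOL_MAP[key]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the specimen metadata table."""
    df = pd.read_csv(Path(path), dtype=str)
    if sorted(df.columns) != sorted(METADATA_COLUMNS):
        raise FormatError(
            f"{path}: metadata header must be exactly {list(METADATA_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    df = df[list(METADATA_COLUMNS)].copy()
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw metadata frame and coerce column dtypes."""
    out = df.copy().reset_index(drop=True)
    dup = out["specimen_id"][out["specimen_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"duplicate specimen_id values: {sorted(set(dup))[:5]}"
        )
    sexes = out["sex"].astype(str)
    bad_sex = ~sexes.isin(["F", "M"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise ValidationError(
            f"row {row}: unknown sex code {sexes.iloc[row]!r} (must be F or M)"
        )
    try:
        out["birth_year"] = out["birth_year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"birth_year not integer: {exc}") from exc
    for col in ("menstruation", "is_control"):
        if out[col].dtype != bool:
            out[col] = [
                _parse_bool(v, i, col) for i, v in enumerate(out[col])
            ]
    for i, value in enumerate(out["collection_date"]):
        try:
            date.fromisoformat(str(value))
        except ValueError as exc:
            raise ValidationError(
                f"row {i}: collection_date {value!r} is not an ISO date"
            ) from exc
    offending = out["menstruation"] & (
        (out["sex"] != "F") | out["is_control"]
    )
    if offending.any():
        row = int(np.flatnonzero(offending)[0])
        raise ValidationError(
            f"row {row} (specimen {out['specimen_id'].iloc[row]!r}): "
            "menstruation=true requires sex=F and is_control=false"
        )
    out["sex"] = sexes.to_numpy()
    out["specimen_id"] = out["specimen_id"].astype(str)
    out["donor_id"] = out["donor_id"].astype(str)
    return out


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df = df[list(METADATA_COLUMNS)].copy()
    for col in ("menstruation", "is_control"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(Path(path), index=False)
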