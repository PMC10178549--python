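"""Domain types for transmission spectra, plus readers/writers and windowing.

A spectra table is the universal carrier between pipeline stages: one shared
wavelength axis in nm, an ``n_samples x n_wavelengths`` intensity matrix, and
an optional origin label per sample. Origin labels are fixed integer codes:
0 = Sichuan, 1 = Jiangsu, 2 = Henan.

The on-disk format is a delimited text table (comma by default, tab
accepted): header ``sample_id, origin, <wavelength>, <wavelength>, ...``
with one sample per row. The wavelength axis may be non-uniform; all
operations index by position and never assume uniform spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ovotrace.errors import FormatError, ValidationError

#: Fixed label-to-origin mapping; hard-coded to prevent silent permutations.
ORIGIN_NAMES: Mapping[int, str] = {0: "Sichuan", 1: "Jiangsu", 2: "Henan"}

VALID_LABELS = frozenset(ORIGIN_NAMES)

_ID_COL = "sample_id"
_LABEL_COL = "origin"


def _check_axis(wavelengths_nm: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths_nm, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValidationError("wavelength axis must be 1-D with >= 2 points")
    if not np.all(np.diff(w) > 0):
        raise ValidationError("wavelength axis must be strictly increasing")
    return w


@dataclass(frozen=True)
class Spectrum:
    """A single transmission spectrum with an optional origin label."""

    sample_id: str
    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    origin: int | None = None

    def __post_init__(self) -> None:
        w = _check_axis(self.wavelengths_nm)
        x = np.asarray(self.intensities, dtype=float)
        if x.shape != w.shape:
            raise ValidationError(
                f"sample {self.sample_id!r}: intensities length {x.size} "
                f"!= axis length {w.size}"
            )
        if self.origin is not None and self.origin not in VALID_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: origin {self.origin!r} "
                f"not in {sorted(VALID_LABELS)}"
            )
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", x)


@dataclass
class SpectraTable:
    """Spectra sharing one wavelength axis, with optional per-sample labels.

    Attributes
    ----------
    wavelengths_nm
        Shared axis, strictly increasing, length ``n_wavelengths``.
    X
        Intensity matrix, shape ``(n_samples, n_wavelengths)``.
    y
        Integer origin codes in {0, 1, 2}, length ``n_samples``, or None.
    sample_ids
        One identifier per row.
    """

    wavelengths_nm: np.ndarray
    X: np.ndarray
    y: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths_nm = _check_axis(self.wavelengths_nm)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[None, :]
        # zero-row tables are legal (they arise from degenerate splits);
        # operations that need samples validate that themselves
        if self.X.shape[1] != self.wavelengths_nm.size:
            raise ValidationError(
                f"X has {self.X.shape[1]} columns but axis has "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (self.X.shape[0],):
                raise ValidationError("y length must equal the number of rows")
            bad = set(np.unique(self.y).tolist()) - VALID_LABELS
            if bad:
                raise ValidationError(f"unknown origin codes: {sorted(bad)}")
            self.y = self.y.astype(int)
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.X.shape[0])]
        elif len(self.sample_ids) != self.X.shape[0]:
            raise ValidationError("sample_ids length must equal number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def row(self, i: int) -> Spectrum:
        return Spectrum(
            sample_id=self.sample_ids[i],
            wavelengths_nm=self.wavelengths_nm,
            intensities=self.X[i],
            origin=None if self.y is None else int(self.y[i]),
        )

    def subset_columns(self, indices: Sequence[int]) -> "SpectraTable":
        """Restrict the table to the given axis positions (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        order = np.argsort(self.wavelengths_nm[idx])
        idx = idx[order]
        return SpectraTable(
            wavelengths_nm=self.wavelengths_nm[idx],
            X=self.X[:, idx],
            y=self.y,
            sample_ids=list(self.sample_ids),
        )

    def subset_rows(self, indices: Sequence[int]) -> "SpectraTable":
        idx = np.asarray(indices, dtype=int)
        return SpectraTable(
            wavelengths_nm=self.wavelengths_nm,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def equals(self, other: "SpectraTable") -> bool:
        same_labels = (self.y is None) == (other.y is None) and (
            self.y is None or bool(np.array_equal(self.y, other.y))
        )
        return (
            bool(np.array_equal(self.wavelengths_nm, other.wavelengths_nm))
            and bool(np.array_equal(self.X, other.X))
            and same_labels
            and self.sample_ids == other.sample_ids
        )


@dataclass(frozen=True)
class WavelengthWindow:
    """Inclusive wavelength window in nm."""

    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise ValidationError(
                f"window requires low < high, got [{self.low_nm}, {self.high_nm}]"
            )


#: Valid transmission range for a tungsten-halogen source read on a
#: 200-1100 nm spectrometer: the intersection of the two instrument ranges.
DEFAULT_WINDOW = WavelengthWindow(400.0, 1100.0)


def read_spectra(path: str | Path, delimiter: str | None = None) -> SpectraTable:
    """Read a delimited spectra table.

    The first header cell must be ``sample_id``; an ``origin`` column is
    optional; the remaining header cells are wavelengths in nm. Rows whose
    intensities fail to parse as numbers are rejected with their row indices
    reported in a warning.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    cols = list(df.columns)
    if not cols or cols[0] != _ID_COL:
        raise FormatError(f"first header column must be {_ID_COL!r}, got {cols[:1]}")
    has_labels = len(cols) > 1 and cols[1] == _LABEL_COL
    wl_cols = cols[2:] if has_labels else cols[1:]
    if not wl_cols:
        raise FormatError("no wavelength columns found in header")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header: {exc}") from exc
    if len(set(wl_cols)) != len(wl_cols):
        raise FormatError("duplicate wavelength columns in header")
    if not np.all(np.diff(wavelengths) > 0):
        raise ValidationError("wavelength header is not strictly increasing")

    def _to_float(value: object) -> float:
        try:
            return float(value)  # exact round-trip of shortest-repr floats
        except (TypeError, ValueError):
            return np.nan

    raw = df[wl_cols].map(_to_float).to_numpy(dtype=float)
    bad_rows = np.where(np.isnan(raw).any(axis=1))[0]
    if bad_rows.size:
        warnings.warn(
            f"rejected {bad_rows.size} row(s) with unparseable intensities "
            f"at indices {bad_rows.tolist()}",
            stacklevel=2,
        )
        keep = np.setdiff1d(np.arange(len(df)), bad_rows)
        if keep.size == 0:
            raise FormatError("no parseable data rows in file")
        df = df.iloc[keep]
        raw = raw[keep]

    y = None
    if has_labels:
        y = pd.to_numeric(df[_LABEL_COL], errors="raise").to_numpy(dtype=int)
    return SpectraTable(
        wavelengths_nm=wavelengths,
        X=raw,
        y=y,
        sample_ids=df[_ID_COL].astype(str).tolist(),
    )


def write_spectra(
    table: SpectraTable, path: str | Path, delimiter: str = ","
) -> Path:
    """Write a spectra table so that :func:`read_spectra` round-trips it."""
    path = Path(path)
    data: dict[str, object] = {_ID_COL: table.sample_ids}
    if table.y is not None:
        data[_LABEL_COL] = table.y
    df = pd.DataFrame(data)
    # shortest-repr float formatting keeps the round-trip bitwise exact
    wl_names = [repr(float(w)) for w in table.wavelengths_nm]
    spec_df = pd.DataFrame(table.X, columns=wl_names, index=df.index)
    out = pd.concat([df, spec_df], axis=1)
    out.to_csv(path, sep=delimiter, index=False)
    return path


def crop_wavelengths(table: SpectraTable, window: WavelengthWindow) -> SpectraTable:
    """Keep exactly the columns whose wavelength lies inside the window.

    Both window bounds are inclusive; column order is preserved. Raises
    :class:`ValidationError` when no wavelength falls inside the window.
    """
    mask = (table.wavelengths_nm >= window.low_nm) & (
        table.wavelengths_nm <= window.high_nm
    )
    if not mask.any():
        raise ValidationError(
            f"window [{window.low_nm}, {window.high_nm}] nm does not "
            "intersect the wavelength axis"
        )
    return SpectraTable(
        wavelengths_nm=table.wavelengths_nm[mask],
        X=table.X[:, mask],
        y=table.y,
        sample_ids=list(table.sample_ids),
    )


def class_mean_spectra(table: SpectraTable) -> dict[int, Spectrum]:
    """Average the spectra of each origin class wavelength-by-wavelength."""
    if table.y is None:
        raise ValidationError("class_mean_spectra requires origin labels")
    means: dict[int, Spectrum] = {}
    for label in sorted(np.unique(table.y).tolist()):
        mean = table.X[table.y == label].mean(axis=0)
        means[int(label)] = Spectrum(
            sample_id=f"mean_{ORIGIN_NAMES[int(label)]}",
            wavelengths_nm=table.wavelengths_nm,
            intensities=mean,
            origin=int(label),
        )
    return means
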