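"""Scatter and noise correction for transmission spectra.

Three transforms, applied one at a time (a pipeline configuration uses
exactly one of them):

* **SNV** (standard normal variate): per-spectrum standardization to mean 0
  and sample standard deviation 1; removes per-sample offset and gain caused
  by uneven particle distribution.
* **MSC** (multiplicative scatter correction): per-spectrum affine
  regression against a reference spectrum (by default the training-set mean);
  the corrected spectrum is ``(x - a) / b`` where ``x ~ a + b * reference``
  is the ordinary least-squares fit. The reference is fitted on training
  data only and reused for held-out samples.
* **Savitzky-Golay**: local least-squares polynomial smoothing (optionally a
  derivative). Edges are handled by fitting the polynomial to the edge
  windows so output length equals input length and wavelength indexing is
  stable for downstream selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ovotrace.core import SpectraTable
from ovotrace.errors import DegenerateDataError, ParameterError, ValidationError


@dataclass(frozen=True)
class MSCReference:
    """Reference spectrum for MSC, typically the training-set mean."""

    reference: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reference, dtype=float)
        if r.ndim != 1:
            raise ValidationError("MSC reference must be a 1-D vector")
        if np.var(r) <= 0:
            raise ValidationError("MSC reference must be non-constant")
        object.__setattr__(self, "reference", r)

    @classmethod
    def from_table(cls, table: SpectraTable) -> "MSCReference":
        return cls(reference=table.X.mean(axis=0))


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay window length (points), polynomial order, derivative.

    Defaults (11 / 2 / 0) are conventional smoothing settings for
    ~1400-point visible/NIR spectra.
    """

    window_length: int = 11
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ParameterError(
                f"window_length must be an odd integer >= 3, got {self.window_length}"
            )
        if not 0 <= self.polyorder < self.window_length:
            raise ParameterError(
                f"polyorder must satisfy 0 <= polyorder < window_length, "
                f"got {self.polyorder}"
            )
        if not 0 <= self.deriv <= self.polyorder:
            raise ParameterError(
                f"deriv must satisfy 0 <= deriv <= polyorder, got {self.deriv}"
            )


def _replace_X(table: SpectraTable, X: np.ndarray) -> SpectraTable:
    return SpectraTable(
        wavelengths_nm=table.wavelengths_nm,
        X=X,
        y=table.y,
        sample_ids=list(table.sample_ids),
    )


def snv(table: SpectraTable) -> SpectraTable:
    """Standardize each spectrum to mean 0, sample standard deviation 1."""
    X = table.X
    if X.shape[1] < 2:
        raise ValidationError("SNV requires at least 2 points per spectrum")
    sd = X.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [table.sample_ids[i] for i in bad]
        raise DegenerateDataError(f"constant spectra cannot be SNV-scaled: {names}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return _replace_X(table, out)


def msc(
    table: SpectraTable,
    reference: MSCReference | None = None,
    *,
    slope_tol: float = 1e-12,
) -> SpectraTable:
    """Remove per-sample multiplicative and additive scatter against a reference.

    When ``reference`` is None the mean spectrum of ``table`` is used; for a
    train/test workflow pass the reference fitted on the training partition.
    """
    if reference is None:
        reference = MSCReference.from_table(table)
    r = reference.reference
    if r.size != table.n_wavelengths:
        raise ValidationError(
            f"reference length {r.size} != axis length {table.n_wavelengths}"
        )
    rc = r - r.mean()
    denom = rc @ rc
    X = table.X
    # per-row OLS of x on (1, reference): slope b, intercept a
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * r.mean()
    bad = np.where(np.abs(b) < slope_tol)[0]
    if bad.size:
        names = [table.sample_ids[i] for i in bad]
        raise DegenerateDataError(
            f"degenerate MSC fit (|slope| < {slope_tol}) for samples {names}"
        )
    out = (X - a[:, None]) / b[:, None]
    return _replace_X(table, out)


def savitzky_golay(table: SpectraTable, params: SGParams | None = None) -> SpectraTable:
    """Apply a Savitzky-Golay filter row-wise; output length equals input."""
    if params is None:
        params = SGParams()
    if params.window_length > table.n_wavelengths:
        raise ParameterError(
            f"window_length {params.window_length} exceeds axis length "
            f"{table.n_wavelengths}"
        )
    out = savgol_filter(
        table.X,
        window_length=params.window_length,
        polyorder=params.polyorder,
        deriv=params.deriv,
        axis=1,
        mode="interp",
    )
    return _replace_X(table, out)
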