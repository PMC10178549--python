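"""Feature-wavelength selection: SPA and CARS over a small PLS engine.

Both selectors treat the origin code (0/1/2) as a numeric response and score
candidate wavelength subsets by cross-validated root mean squared error of a
linear calibration, the standard single-response formulation for
classification-oriented wavelength selection in chemometrics.

* **SPA** (successive projections algorithm) grows a chain from each
  starting wavelength by repeatedly adding the column whose component
  orthogonal to the span of the already-selected columns has the largest
  norm — a forward selection that minimizes collinearity. Every
  (start, chain-length) candidate is scored by K-fold cross-validated RMSE
  of a multivariate linear calibration; the minimum wins, ties going to the
  smaller subset.

* **CARS** (competitive adaptive reweighted sampling) runs a Monte Carlo
  loop: each run fits a PLS model on a random subsample, converts the
  regression coefficients to importance weights ``w_i = |k_i| / sum|k_i|``,
  removes low-weight wavelengths with an exponentially decreasing retention
  schedule (forced removal), then resamples survivors in proportion to their
  weights (adaptive reweighted sampling). The run whose surviving subset has
  the lowest cross-validated RMSE (RMSECV, computed on the full training
  set) delivers the final selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from ovotrace.core import SpectraTable
from ovotrace.errors import DegenerateDataError, ParameterError, ValidationError

# relative threshold below which a residual column counts as collinear with
# the selected set and is excluded from SPA chains
_COLLINEAR_TOL = 1e-10


@dataclass
class PLSModel:
    """Linear calibration ``prediction = X @ coefficients + bias``.

    ``coefficients`` collapses the PLS latent structure to one coefficient
    per wavelength; ``bias`` is the model intercept.
    """

    n_components: int
    coefficients: np.ndarray
    bias: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.bias


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a partial least squares regression with the given latent dimension.

    With ``n_components`` equal to the column count of a full-rank matrix
    the fit reproduces ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components must be in [1, min(n_samples-1, n_variables)] = "
            f"[1, {min(n - 1, p)}], got {n_components}"
        )
    if np.ptp(y) == 0:
        return PLSModel(
            n_components=n_components,
            coefficients=np.zeros(p),
            bias=float(y.mean()),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # harmless residual-deflation warnings
        model = PLSRegression(n_components=n_components, scale=False).fit(X, y)
    coef = np.asarray(model.coef_).reshape(-1)
    bias = float(y.mean() - X.mean(axis=0) @ coef)
    return PLSModel(n_components=n_components, coefficients=coef, bias=bias)


def spa_project(candidate: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Component of ``candidate`` orthogonal to ``anchor``.

    This is the single-anchor projection step of SPA; chains generalize it
    to the span of all previously selected columns.
    """
    candidate = np.asarray(candidate, dtype=float)
    anchor = np.asarray(anchor, dtype=float)
    if candidate.shape != anchor.shape:
        raise ValidationError("candidate and anchor must have equal length")
    denom = anchor @ anchor
    if denom == 0:
        raise ValidationError("anchor vector must be non-zero")
    return candidate - (candidate @ anchor) / denom * anchor


def spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Build one SPA chain from ``start`` by successive orthogonal projection.

    At each step every remaining column is replaced by its component
    orthogonal to the span of the selected set; the column with the largest
    residual norm joins the chain. Columns whose residual norm falls below a
    collinearity tolerance (e.g. duplicates of selected columns) are
    excluded, so the chain may stop short of ``max_vars``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = X.copy()
    norms0 = np.linalg.norm(X, axis=0)
    scale = norms0.max()
    if scale == 0:
        raise ValidationError("all-zero matrix has no SPA chain")
    chain = [start]
    for _ in range(max_vars - 1):
        q = R[:, chain[-1]]
        qn = np.linalg.norm(q)
        if qn < _COLLINEAR_TOL * scale:
            break
        q = q / qn
        R = R - np.outer(q, q @ R)
        res = np.linalg.norm(R, axis=0)
        res[chain] = -1.0
        res[res < _COLLINEAR_TOL * scale] = -1.0
        nxt = int(np.argmax(res))
        if res[nxt] < 0:
            break
        chain.append(nxt)
    return chain


@dataclass
class SPAResult:
    """Outcome of SPA selection: the chosen subset and its RMSE-vs-size curve."""

    selected_indices: list[int]
    selected_wavelengths_nm: np.ndarray
    rmse_by_size: dict[int, float]
    chosen_size: int
    start_by_size: dict[int, int] = field(default_factory=dict)


def _stratified_folds(
    y_class: np.ndarray, cv_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    _, counts = np.unique(y_class, return_counts=True)
    k = min(cv_folds, counts.min())
    if k < 2:
        raise ParameterError("cross-validation needs >= 2 samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y_class)), y_class))


def spa_select(
    table: SpectraTable,
    max_vars: int,
    cv_folds: int = 10,
    *,
    seed: int = 0,
    ridge: float = 1e-10,
) -> SPAResult:
    """Run SPA over all starting wavelengths and pick the CV-RMSE minimizer.

    Every (start, size<=max_vars) candidate subset is scored by K-fold
    cross-validated RMSE of an ordinary linear calibration on the numeric
    origin codes. ``rmse_by_size`` records, for each subset size, the best
    RMSE over starts; ``chosen_size`` is the curve minimum with ties broken
    toward fewer variables.
    """
    if table.y is None:
        raise ValidationError("spa_select requires origin labels")
    if max_vars < 1:
        raise ParameterError("max_vars must be >= 1")
    if max_vars > table.n_wavelengths:
        raise ParameterError(
            f"max_vars {max_vars} exceeds {table.n_wavelengths} wavelengths"
        )
    X = table.X
    y = table.y.astype(float)
    n, p = X.shape
    folds = _stratified_folds(table.y, cv_folds, seed)

    # intercept as an always-included augmented column
    X1 = np.hstack([X, np.ones((n, 1))])
    gram = []
    for train_idx, test_idx in folds:
        Xt = X1[train_idx]
        gram.append((Xt.T @ Xt, Xt.T @ y[train_idx], train_idx, test_idx))

    def cv_rmse(cols: list[int]) -> float:
        ix = np.array(cols + [p])
        sq = 0.0
        for G, h, _, test_idx in gram:
            Gs = G[np.ix_(ix, ix)]
            Gs = Gs + ridge * np.trace(Gs) / len(ix) * np.eye(len(ix))
            beta = np.linalg.solve(Gs, h[ix])
            pred = X1[np.ix_(test_idx, ix)] @ beta
            sq += float(np.sum((y[test_idx] - pred) ** 2))
        return float(np.sqrt(sq / n))

    best_rmse_by_size: dict[int, float] = {}
    best_chain_by_size: dict[int, list[int]] = {}
    start_by_size: dict[int, int] = {}
    for start in range(p):
        chain = spa_chain(X, start, max_vars)
        for size in range(1, len(chain) + 1):
            r = cv_rmse(chain[:size])
            if size not in best_rmse_by_size or r < best_rmse_by_size[size]:
                best_rmse_by_size[size] = r
                best_chain_by_size[size] = chain[:size]
                start_by_size[size] = start

    chosen_size = min(
        best_rmse_by_size, key=lambda s: (best_rmse_by_size[s], s)
    )
    selected = best_chain_by_size[chosen_size]
    return SPAResult(
        selected_indices=list(selected),
        selected_wavelengths_nm=table.wavelengths_nm[np.array(selected)],
        rmse_by_size=dict(sorted(best_rmse_by_size.items())),
        chosen_size=chosen_size,
        start_by_size=start_by_size,
    )


def cars_weights(coefficients: np.ndarray) -> np.ndarray:
    """Normalize PLS coefficient magnitudes to importance weights.

    ``w_i = |k_i| / sum_j |k_j|``: non-negative and summing to 1.
    """
    k = np.abs(np.asarray(coefficients, dtype=float))
    total = k.sum()
    if total == 0:
        raise DegenerateDataError("all-zero coefficients admit no weights")
    return k / total


def cars_schedule(n_variables: int, n_runs: int) -> np.ndarray:
    """Number of wavelengths retained at each run (exponential decay).

    The retained fraction at run i is ``r_i = a * exp(-k*i)`` with ``a`` and
    ``k`` fixed by ``r_1 = 1`` (all variables) and ``r_N = 2/p`` (two
    variables at the final run).
    """
    p = n_variables
    if p < 3 or n_runs < 2:
        raise ParameterError("schedule needs >= 3 variables and >= 2 runs")
    k = np.log(p / 2) / (n_runs - 1)
    a = np.exp(k)
    i = np.arange(1, n_runs + 1)
    counts = np.round(a * np.exp(-k * i) * p).astype(int)
    return np.clip(counts, 2, p)


@dataclass
class CARSResult:
    """Outcome of CARS: per-run traces and the RMSECV-minimizing subset."""

    selected_indices: list[int]
    rmsecv_by_run: np.ndarray
    best_run: int
    weights_history: list[np.ndarray]
    retained_counts: list[int]


def _pls_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    y_class: np.ndarray,
    n_components: int,
    cv_folds: int,
    seed: int,
) -> float:
    sq = 0.0
    folds = _stratified_folds(y_class, cv_folds, seed)
    for train_idx, test_idx in folds:
        ncomp = min(n_components, len(train_idx) - 1, X.shape[1])
        model = pls_fit(X[train_idx], y[train_idx], ncomp)
        pred = model.predict(X[test_idx])
        sq += float(np.sum((y[test_idx] - pred) ** 2))
    return float(np.sqrt(sq / len(y)))


def cars_select(
    table: SpectraTable,
    n_runs: int = 100,
    cv_folds: int = 10,
    sample_fraction: float = 0.8,
    n_components: int | None = None,
    seed: int = 0,
) -> CARSResult:
    """Competitive adaptive reweighted sampling over Monte Carlo PLS runs.

    Per run: subsample ``sample_fraction`` of the samples, fit PLS on the
    currently surviving wavelengths, convert coefficients to weights
    (zero-weight wavelengths are eliminated outright), force-remove down to
    the exponential-decay count, then resample survivors proportionally to
    their weights. RMSECV of each run's survivors is measured on the full
    table; the best run's set is returned.
    """
    if table.y is None:
        raise ValidationError("cars_select requires origin labels")
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2")
    if not 0 < sample_fraction <= 1:
        raise ParameterError("sample_fraction must be in (0, 1]")
    X = table.X
    y = table.y.astype(float)
    n, p = X.shape
    if n_components is None:
        n_components = min(10, n - 2, p)
    schedule = cars_schedule(p, n_runs)
    rng = np.random.default_rng(seed)

    survivors = np.arange(p)
    rmsecv = np.empty(n_runs)
    weights_history: list[np.ndarray] = []
    retained_counts: list[int] = []
    survivor_history: list[np.ndarray] = []

    n_sub = max(2, int(round(sample_fraction * n)))
    for run in range(n_runs):
        mc = rng.choice(n, size=n_sub, replace=False)
        ncomp = min(n_components, len(survivors), n_sub - 1)
        model = pls_fit(X[np.ix_(mc, survivors)], y[mc], ncomp)
        w = cars_weights(model.coefficients)
        # eliminate exact-zero weights before any sampling
        nz = w > 0
        survivors, w = survivors[nz], w[nz]
        w = w / w.sum()
        wfull = np.zeros(p)
        wfull[survivors] = w
        weights_history.append(wfull)

        n_keep = min(int(schedule[run]), len(survivors))
        if n_keep < len(survivors):
            # forced removal: keep the top-weight wavelengths
            top = np.argsort(w)[::-1][:n_keep]
            survivors, w = survivors[top], w[top]
            w = w / w.sum()
            # adaptive reweighted sampling: weighted draws, survivors = unique
            if len(survivors) > 2:
                drawn = rng.choice(len(survivors), size=n_keep, replace=True, p=w)
                keep = np.unique(drawn)
                if len(keep) >= 2:
                    survivors = survivors[keep]
        survivors = np.sort(survivors)

        retained_counts.append(len(survivors))
        survivor_history.append(survivors.copy())
        rmsecv[run] = _pls_rmsecv(
            X[:, survivors],
            y,
            table.y,
            min(n_components, len(survivors)),
            cv_folds,
            seed,
        )

    best_run = int(np.argmin(rmsecv))
    return CARSResult(
        selected_indices=survivor_history[best_run].tolist(),
        rmsecv_by_run=rmsecv,
        best_run=best_run,
        weights_history=weights_history,
        retained_counts=retained_counts,
    )
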