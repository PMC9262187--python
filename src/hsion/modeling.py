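"""Partial least squares regression (NIPALS) and repeated-split model search.

The estimator relates a samples x bands spectra matrix to a univariate ion
content.  Components are extracted one at a time by NIPALS: the weight vector
is the covariance direction between the deflated predictors and the response,
scores are the projections, and the predictor matrix is deflated by its
rank-one reconstruction after each component.  With as many components as the
rank of the centred predictors, predictions coincide with ordinary least
squares.

Model selection follows the repeated random-split protocol: each iteration
draws a random half split, fits up to ``max_components`` components on the
training half, picks the component count minimising held-out RMSEP, and the
best split overall (lowest RMSEP, squared Pearson R^2 as tie-breaker) is kept
along with the full iteration log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SpectraMatrix

__all__ = [
    "PLSModel",
    "PLSResults",
    "ModelSearchResult",
    "ModelSnapshot",
    "BandMismatchError",
    "fit_plsr",
    "rmsep",
    "r_squared",
    "repeated_split_search",
    "predict_timeseries",
    "save_model",
    "load_model",
]


class BandMismatchError(ValueError):
    """Raised when prediction bands do not match the training bands."""


class PLSModel:
    """Univariate-response PLS regression model (NIPALS algorithm).

    Parameters
    ----------
    endog : (n,) response values (ion content).
    exog : (n, p) predictor matrix (spectra).
    wavelengths_nm : optional per-column wavelength grid, carried through to
        results so predictions can verify band compatibility.
    """

    def __init__(self, endog, exog, wavelengths_nm=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        if not np.all(np.isfinite(self.exog)) or not np.all(np.isfinite(self.endog)):
            raise ValueError("missing values are not supported")
        self.wavelengths_nm = (
            None if wavelengths_nm is None else np.asarray(wavelengths_nm, dtype=float)
        )

    @classmethod
    def from_spectra(cls, matrix: SpectraMatrix, y) -> "PLSModel":
        return cls(y, matrix.values, matrix.wavelengths_nm)

    def fit(self, n_components: int) -> "PLSResults":
        n, p = self.exog.shape
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={n_components} exceeds min(n_samples - 1, n_bands)"
                f" = {min(n - 1, p)}"
            )
        y = self.endog
        if np.ptp(y) == 0:
            raise ValueError("response has zero variance")
        x_mean = self.exog.mean(axis=0)
        y_mean = float(y.mean())
        X = self.exog - x_mean
        yc = y - y_mean
        scale = float(np.linalg.norm(X)) or 1.0

        W = np.zeros((p, n_components))
        P = np.zeros((p, n_components))
        T = np.zeros((n, n_components))
        q = np.zeros(n_components)
        a_eff = 0
        for a in range(n_components):
            w = X.T @ yc
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * scale:
                break  # predictor rank (or covariance) exhausted
            w /= nw
            t = X @ w
            tt = float(t @ t)
            if tt <= (1e-12 * scale) ** 2:
                break
            pv = X.T @ t / tt
            qa = float(yc @ t) / tt
            X = X - np.outer(t, pv)
            yc = yc - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pv, t, qa
            a_eff = a + 1
        if a_eff == 0:
            raise ValueError("no PLS component could be extracted")
        W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]

        # coefficient path: B_a = W_a (P_a' W_a)^{-1} q_a for a = 1..a_eff
        coefs_path = np.zeros((p, a_eff))
        PtW = P.T @ W
        for a in range(1, a_eff + 1):
            beta = np.linalg.solve(PtW[:a, :a], q[:a])
            coefs_path[:, a - 1] = W[:, :a] @ beta
        intercept_path = y_mean - x_mean @ coefs_path

        return PLSResults(
            model=self,
            n_components=a_eff,
            n_components_requested=n_components,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            x_scores=T,
            coefs_path=coefs_path,
            intercept_path=intercept_path,
            wavelengths_nm=self.wavelengths_nm,
        )


@dataclass
class PLSResults:
    """Fitted PLS regression: latent structure, coefficient path, predictions."""

    model: PLSModel
    n_components: int
    n_components_requested: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    coefs_path: np.ndarray
    intercept_path: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    trained_on: np.ndarray | None = None

    @property
    def coef(self) -> np.ndarray:
        return self.coefs_path[:, self.n_components - 1]

    @property
    def intercept(self) -> float:
        return float(self.intercept_path[self.n_components - 1])

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def _check_bands(self, X: np.ndarray) -> None:
        if X.shape[1] != self.coefs_path.shape[0]:
            raise BandMismatchError(
                f"model trained on {self.coefs_path.shape[0]} bands, "
                f"got {X.shape[1]}"
            )

    def predict(self, exog, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError("n_components out of fitted range")
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        self._check_bands(X)
        return X @ self.coefs_path[:, a - 1] + self.intercept_path[a - 1]

    def predict_path(self, exog) -> np.ndarray:
        """Predictions for every component count 1..n_components, (n, A)."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        self._check_bands(X)
        return X @ self.coefs_path + self.intercept_path

    def summary(self) -> str:
        lines = [
            "PLS Regression Results (NIPALS)",
            "=" * 46,
            f"{'No. observations:':<28}{self.model.exog.shape[0]}",
            f"{'No. bands:':<28}{self.model.exog.shape[1]}",
            f"{'Components:':<28}{self.n_components}",
            f"{'Intercept:':<28}{self.intercept:.6g}",
            f"{'Training RMSEP:':<28}"
            f"{float(np.sqrt(np.mean((self.fittedvalues - self.model.endog) ** 2))):.6g}",
        ]
        return "\n".join(lines)


def fit_plsr(X, y, n_components: int, wavelengths_nm=None) -> PLSResults:
    """Fit a PLS regression of ``y`` on ``X`` with ``n_components`` components."""
    if isinstance(X, SpectraMatrix):
        return PLSModel.from_spectra(X, y).fit(n_components)
    return PLSModel(y, X, wavelengths_nm).fit(n_components)


def rmsep(results: PLSResults, X_test, y_test, n_components: int | None = None) -> float:
    """Root mean squared error of prediction on held-out samples."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("empty test set")
    pred = results.predict(X_test, n_components)
    return float(np.sqrt(np.mean((pred - y_test) ** 2)))


def r_squared(
    results: PLSResults, X_test, y_test, n_components: int | None = None
) -> float:
    """Squared Pearson correlation of predicted vs observed held-out values."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    pred = results.predict(X_test, n_components)
    return _pearson_r2(pred, y_test)


def _pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("R^2 undefined: zero-variance predictions or observations")
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


@dataclass
class ModelSearchResult:
    """Best-of-many-random-splits PLS selection outcome with full log."""

    best_results: PLSResults
    best_rmsep: float
    best_r_squared: float
    best_n_components: int
    best_iteration: int
    n_iterations: int
    n_train: int
    seed: int | None
    log: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        r2 = self.best_r_squared
        lines = [
            "Repeated-split PLSR model search",
            "=" * 46,
            f"{'Iterations:':<28}{self.n_iterations}",
            f"{'Training samples:':<28}{self.n_train}",
            f"{'Best iteration:':<28}{self.best_iteration}",
            f"{'Best components:':<28}{self.best_n_components}",
            f"{'Best held-out RMSEP:':<28}{self.best_rmsep:.6g}",
            f"{'Best held-out R^2:':<28}"
            + ("undefined" if np.isnan(r2) else f"{r2:.4f}"),
        ]
        return "\n".join(lines)


def repeated_split_search(
    X,
    y,
    n_iterations: int = 2000,
    max_components: int = 10,
    split_fraction: float = 0.5,
    seed: int | None = None,
) -> ModelSearchResult:
    """Repeated random-split PLSR selection.

    Each iteration draws a random ``split_fraction`` training subset, fits up
    to ``max_components`` PLS components, and selects the component count
    minimising RMSEP on the held-out rest.  Across iterations the split with
    the lowest held-out RMSEP wins (higher R^2 breaks exact ties).  Fully
    reproducible from ``seed``; the per-iteration log is returned.
    """
    wavelengths = None
    if isinstance(X, SpectraMatrix):
        wavelengths = X.wavelengths_nm
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_train = int(round(split_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError("split leaves too few samples for training or testing")

    rng = np.random.default_rng(seed)
    log_ncomp = np.zeros(n_iterations, dtype=int)
    log_rmsep = np.zeros(n_iterations)
    log_r2 = np.zeros(n_iterations)
    best = None  # (rmsep, -r2_for_ties, iteration, train_idx, ncomp)

    for it in range(n_iterations):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        a_max = min(max_components, n_train - 1, X.shape[1])
        res = PLSModel(y[train], X[train]).fit(a_max)
        preds = res.predict_path(X[test])  # (n_test, a_eff)
        errs = np.sqrt(np.mean((preds - y[test, None]) ** 2, axis=0))
        a_best = int(np.argmin(errs))  # ties -> fewer components
        it_rmsep = float(errs[a_best])
        try:
            it_r2 = _pearson_r2(preds[:, a_best], y[test])
        except ValueError:
            it_r2 = float("nan")
        log_ncomp[it] = a_best + 1
        log_rmsep[it] = it_rmsep
        log_r2[it] = it_r2
        key = (it_rmsep, -(-1.0 if np.isnan(it_r2) else it_r2))
        if best is None or key < best[0]:
            best = (key, it, train, a_best + 1)

    _, best_it, best_train, best_ncomp = best
    best_res = PLSModel(
        y[best_train], X[best_train], wavelengths_nm=wavelengths
    ).fit(min(max_components, n_train - 1, X.shape[1]))
    best_res.n_components = min(best_ncomp, best_res.n_components)
    best_res.trained_on = np.sort(best_train)

    log = pd.DataFrame(
        {
            "iteration": np.arange(n_iterations),
            "n_components": log_ncomp,
            "rmsep": log_rmsep,
            "r_squared": log_r2,
        }
    )
    return ModelSearchResult(
        best_results=best_res,
        best_rmsep=float(log_rmsep[best_it]),
        best_r_squared=float(log_r2[best_it]),
        best_n_components=best_ncomp,
        best_iteration=best_it,
        n_iterations=n_iterations,
        n_train=n_train,
        seed=seed,
        log=log,
    )


def predict_timeseries(model, spectra: SpectraMatrix) -> pd.DataFrame:
    """Apply a fitted model to every row of ``spectra`` (all plants, all days).

    Negative predictions are returned as-is and flagged in the ``negative``
    column: on content scales they signal model extrapolation problems rather
    than data errors, and downstream summaries need to see them.
    """
    if isinstance(model, ModelSearchResult):
        model = model.best_results
    if model.wavelengths_nm is not None:
        if len(model.wavelengths_nm) != spectra.n_bands or not np.allclose(
            model.wavelengths_nm, spectra.wavelengths_nm
        ):
            raise BandMismatchError("spectra bands do not match the model's bands")
    pred = model.predict(spectra.values)
    out = spectra.annotations.copy()
    out["prediction"] = pred
    out["negative"] = pred < 0
    return out


@dataclass
class ModelSnapshot:
    """Minimal serialized form of a fitted model: a linear predictor."""

    wavelengths_nm: np.ndarray | None
    coef: np.ndarray
    intercept: float
    n_components: int
    metadata: dict

    def predict(self, exog, n_components: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != len(self.coef):
            raise BandMismatchError(
                f"model trained on {len(self.coef)} bands, got {X.shape[1]}"
            )
        return X @ self.coef + self.intercept


def save_model(results, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize the final coefficient vector and metadata as JSON."""
    if isinstance(results, ModelSearchResult):
        meta = {
            "best_rmsep": results.best_rmsep,
            "best_r_squared": results.best_r_squared,
            "n_iterations": results.n_iterations,
            "n_train": results.n_train,
            "seed": results.seed,
        }
        results = results.best_results
    else:
        meta = {}
    meta.update(metadata or {})
    payload = {
        "n_components": results.n_components,
        "intercept": results.intercept,
        "coef": results.coef.tolist(),
        "wavelengths_nm": (
            None
            if results.wavelengths_nm is None
            else np.asarray(results.wavelengths_nm).tolist()
        ),
        "metadata": meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ModelSnapshot:
    payload = json.loads(Path(path).read_text())
    wl = payload.get("wavelengths_nm")
    return ModelSnapshot(
        wavelengths_nm=None if wl is None else np.asarray(wl, dtype=float),
        coef=np.asarray(payload["coef"], dtype=float),
        intercept=float(payload["intercept"]),
        n_components=int(payload["n_components"]),
        metadata=payload.get("metadata", {}),
    )
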