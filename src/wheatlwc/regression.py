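"""LWC regression models: PLSR, random forest, extra trees, KNN, index SLR.

All models consume a feature matrix of reflectances at an explicit ascending
wavelength list (a characteristic-band subset or the full retained grid) and
predict leaf water content in percent.  Hyperparameters follow the study
protocol: tree ensembles use 500 trees with sqrt feature subsampling (extra
trees without bootstrap, each tree seeing the whole training set); KNN uses
Euclidean distance with k = 3 by default or k chosen by seeded 5-fold CV over
1..15; PLSR picks its component count at the leave-one-out RMSE minimum,
capped at min(20, n - 2).  Predictors are not standardised (PLS centres
internally); reflectance bands share units, so distance- and tree-based
methods operate on the raw fractions.

A fitted model remembers its feature wavelengths and projects them out of any
spectra it is asked to predict, so a model trained on 28 characteristic bands
applies directly to full-grid spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, LeaveOneOut, cross_val_predict
from sklearn.neighbors import KNeighborsRegressor

from .bandselect import SelectedBands
from .errors import DomainError, InsufficientDataError
from .indices import IndexDefinition, compute_index
from .spectra import SpectraSet

DEFAULT_SEED = 20180101

METHODS = ("PLSR", "RFR", "ERT", "KNN", "INDEX_SLR")


@dataclass(frozen=True)
class ModelSpec:
    """A model method plus its hyperparameters."""

    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DomainError(f"method must be one of {METHODS}, got {self.method!r}")


def plsr_spec(max_components: int = 20, n_components: int | None = None) -> ModelSpec:
    """PLSR spec; ``n_components`` fixes the count and skips LOO selection."""
    return ModelSpec(
        "PLSR", {"max_components": max_components, "n_components": n_components}
    )


def rfr_spec(n_trees: int = 500, seed: int = DEFAULT_SEED) -> ModelSpec:
    if n_trees < 1:
        raise DomainError("n_trees must be >= 1")
    return ModelSpec("RFR", {"n_trees": n_trees, "seed": seed})


def ert_spec(n_trees: int = 500, seed: int = DEFAULT_SEED) -> ModelSpec:
    if n_trees < 1:
        raise DomainError("n_trees must be >= 1")
    return ModelSpec("ERT", {"n_trees": n_trees, "seed": seed})


def knn_spec(k: int = 3, select_k: bool = False, seed: int = DEFAULT_SEED) -> ModelSpec:
    if k < 1:
        raise DomainError("k must be >= 1")
    return ModelSpec("KNN", {"k": k, "select_k": select_k, "seed": seed})


def index_slr_spec(index: IndexDefinition) -> ModelSpec:
    return ModelSpec("INDEX_SLR", {"index": index})


@dataclass
class FittedModel:
    """A trained regressor bound to its feature wavelengths."""

    spec: ModelSpec
    feature_wavelengths: np.ndarray | None  # None for index-based models
    estimator: Any
    summary: dict = field(default_factory=dict)


def _feature_matrix(spectra: SpectraSet, wavelengths: Sequence[int]) -> np.ndarray:
    idx = spectra.grid.indices_of(wavelengths)
    return spectra.reflectance[:, idx]


def _resolve_bands(spectra: SpectraSet, bands) -> np.ndarray:
    if bands is None or (isinstance(bands, str) and bands == "full"):
        return spectra.grid.wavelengths.copy()
    if isinstance(bands, SelectedBands):
        return bands.wavelengths.copy()
    return np.sort(np.asarray(bands, dtype=np.int64))


def fit(
    spec: ModelSpec,
    spectra: SpectraSet,
    bands=None,
    lwc: np.ndarray | None = None,
) -> FittedModel:
    """Train a model of the given spec on reflectance features (or an index).

    ``bands`` is a :class:`SelectedBands`, an explicit wavelength sequence,
    ``"full"``/``None`` for the whole grid; it is ignored by INDEX_SLR, whose
    single feature is the configured spectral index.
    """
    y = np.asarray(spectra.lwc if lwc is None else lwc, dtype=float)
    if y.shape != (spectra.n_samples,):
        raise DomainError("lwc vector length must equal the sample count")
    if not np.all(np.isfinite(y)):
        raise DomainError("training LWC must be finite for every sample")
    n = y.size
    if n < 10:
        raise InsufficientDataError(f"need at least 10 training samples, have {n}")

    method = spec.method
    if method == "INDEX_SLR":
        definition: IndexDefinition = spec.params["index"]
        x = compute_index(definition, spectra).values
        ok = np.isfinite(x)
        if ok.sum() < 10:
            raise InsufficientDataError("fewer than 10 samples with a defined index value")
        est = LinearRegression().fit(x[ok, None], y[ok])
        return FittedModel(
            spec=spec,
            feature_wavelengths=None,
            estimator=est,
            summary={
                "n": int(ok.sum()),
                "slope": float(est.coef_[0]),
                "intercept": float(est.intercept_),
                "index": definition.name,
            },
        )

    wavelengths = _resolve_bands(spectra, bands)
    X = _feature_matrix(spectra, wavelengths)
    summary: dict = {"n": n, "n_bands": int(wavelengths.size)}

    if method == "PLSR":
        cap = min(int(spec.params.get("max_components", 20)), n - 2, X.shape[1])
        if cap < 1:
            raise InsufficientDataError("not enough samples/bands for PLSR")
        fixed = spec.params.get("n_components")
        if fixed is not None:
            n_comp = int(fixed)
            if not 1 <= n_comp <= min(n - 1, X.shape[1]):
                raise DomainError(f"fixed n_components {n_comp} out of range")
            summary.update(n_components=n_comp, components_fixed=True)
        else:
            loo = LeaveOneOut()
            rmse = np.empty(cap)
            for k in range(1, cap + 1):
                pred = cross_val_predict(
                    PLSRegression(n_components=k, scale=False), X, y, cv=loo
                ).ravel()
                rmse[k - 1] = np.sqrt(np.mean((y - pred) ** 2))
            # parsimony on numerical ties: smallest count within tolerance of
            # the LOO minimum, so noise-free data does not over-select
            best = rmse.min()
            n_comp = int(np.flatnonzero(rmse <= best * (1 + 1e-8) + 1e-12)[0]) + 1
            summary.update(n_components=n_comp, loo_rmse=float(rmse[n_comp - 1]))
        est = PLSRegression(n_components=n_comp, scale=False).fit(X, y)
    elif method == "RFR":
        est = RandomForestRegressor(
            n_estimators=int(spec.params.get("n_trees", 500)),
            max_features="sqrt",
            random_state=int(spec.params.get("seed", DEFAULT_SEED)),
        ).fit(X, y)
        summary.update(n_trees=est.n_estimators, seed=est.random_state)
    elif method == "ERT":
        est = ExtraTreesRegressor(
            n_estimators=int(spec.params.get("n_trees", 500)),
            max_features="sqrt",
            bootstrap=False,
            random_state=int(spec.params.get("seed", DEFAULT_SEED)),
        ).fit(X, y)
        summary.update(n_trees=est.n_estimators, seed=est.random_state)
    elif method == "KNN":
        if spec.params.get("select_k", False):
            cvk = KFold(
                n_splits=5, shuffle=True,
                random_state=int(spec.params.get("seed", DEFAULT_SEED)),
            )
            search = GridSearchCV(
                KNeighborsRegressor(),
                {"n_neighbors": list(range(1, min(16, n)))},
                cv=cvk,
                scoring="neg_root_mean_squared_error",
            ).fit(X, y)
            est = search.best_estimator_
            summary.update(k=int(est.n_neighbors), k_selected_by_cv=True)
        else:
            k = int(spec.params.get("k", 3))
            est = KNeighborsRegressor(n_neighbors=k).fit(X, y)
            summary.update(k=k, k_selected_by_cv=False)
    else:  # pragma: no cover - guarded by ModelSpec
        raise DomainError(f"unknown method {method!r}")
    return FittedModel(
        spec=spec, feature_wavelengths=wavelengths, estimator=est, summary=summary
    )


def predict(model: FittedModel, spectra: SpectraSet) -> np.ndarray:
    """Predict LWC (%) for every sample; deterministic given the model."""
    if model.spec.method == "INDEX_SLR":
        definition: IndexDefinition = model.spec.params["index"]
        x = compute_index(definition, spectra).values
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        if ok.any():
            out[ok] = model.estimator.predict(x[ok, None])
        return out
    X = _feature_matrix(spectra, model.feature_wavelengths)
    return np.asarray(model.estimator.predict(X)).ravel()
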