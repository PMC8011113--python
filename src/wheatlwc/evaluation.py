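"""Model evaluation: R-squared, RMSE, RPD, sample statistics, and the
calibration/validation model-comparison table.

R-squared is the coefficient of determination 1 - SS_res/SS_tot computed on
the split's own predictions (out of sample for validation), which can go
negative for models worse than the mean predictor; RMSE carries LWC units
(percent); RPD = SD(measured)/RMSE with the sample (n-1) standard deviation,
and a model is deemed adequate when RPD exceeds 1.4.

The comparison workflow splits by season (earliest year calibrates, latest
validates), screens characteristic bands on the calibration season only (no
validation leakage), and crosses every band set (full grid, CA, x-Lw) with
every model (PLSR, RFR, ERT, KNN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bandselect, regression
from .bandselect import SelectedBands
from .errors import DomainError
from .spectra import BandMask, SpectraSet, apply_atmospheric_mask

#: RPD above this is considered acceptable predictive ability.
RPD_ADEQUACY_THRESHOLD = 1.4


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise DomainError("y and yhat must be equal-length 1-D vectors")
    if y.size < 2:
        raise DomainError("need at least 2 observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise DomainError("measured values have zero variance")
    return 1.0 - float(((y - yhat) ** 2).sum()) / sst


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, in LWC percent."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 1:
        raise DomainError("y and yhat must be equal-length non-empty 1-D vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y: np.ndarray, yhat: np.ndarray, ddof: int = 1) -> float:
    """Ratio of performance to deviation: SD(y) / RMSE(y, yhat).

    Uses the sample (n-1) standard deviation by default; returns ``inf`` for
    a perfect fit.
    """
    e = rmse(y, yhat)
    sd = float(np.std(np.asarray(y, dtype=float), ddof=ddof))
    if e == 0.0:
        return float("inf")
    return sd / e


def rpd_is_adequate(value: float, threshold: float = RPD_ADEQUACY_THRESHOLD) -> bool:
    return value > threshold


@dataclass
class EvalReport:
    """R-squared / RMSE / RPD for one dataset split."""

    split: str
    n: int
    r2: float
    rmse: float
    rpd: float

    @property
    def adequate(self) -> bool:
        return rpd_is_adequate(self.rpd)


def evaluate(y: np.ndarray, yhat: np.ndarray, split: str = "") -> EvalReport:
    return EvalReport(
        split=split, n=int(np.asarray(y).size),
        r2=r2(y, yhat), rmse=rmse(y, yhat), rpd=rpd(y, yhat),
    )


def describe(splits: Mapping[str, np.ndarray], ddof: int = 1) -> pd.DataFrame:
    """Max/min/mean/SD/CV% summary per split (the sample-statistics table)."""
    rows = {}
    for name, values in splits.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise DomainError(f"split {name!r} needs at least 2 values for an SD")
        sd = float(np.std(v, ddof=ddof))
        mean = float(v.mean())
        rows[name] = {
            "n": v.size,
            "max": float(v.max()),
            "min": float(v.min()),
            "mean": mean,
            "sd": sd,
            "cv_percent": sd / mean * 100.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def year_split(spectra: SpectraSet) -> tuple[SpectraSet, SpectraSet]:
    """Earliest season -> calibration, latest -> validation.

    Any middle seasons are left out with a warning.
    """
    years = sorted({m.year for m in spectra.meta})
    if len(years) < 2:
        raise DomainError("year_split needs at least two distinct year labels")
    if len(years) > 2:
        warnings.warn(
            f"years {years[1:-1]} fall between calibration and validation and are unused",
            stacklevel=2,
        )
    year_arr = np.array([m.year for m in spectra.meta])
    cal = spectra.subset(np.flatnonzero(year_arr == years[0]))
    val = spectra.subset(np.flatnonzero(year_arr == years[-1]))
    return cal, val


@dataclass
class ComparisonConfig:
    """Knobs of the model-comparison workflow, all seeded/deterministic."""

    seed: int = regression.DEFAULT_SEED
    mask: BandMask | None = field(default_factory=BandMask.default)
    ca_n_target: int = 100
    ca_window: int = 10
    ca_min_separation: int = 2
    xlw_components: int = 3
    xlw_max_components: int = 10
    xlw_window: int = 10
    pls_cv: str = "loo"
    pls_max_components: int = 20
    knn_k: int = 3
    n_trees: int = 500
    pooled_band_selection: bool = False  # if True, screen bands on all samples (leaky)


@dataclass
class ComparisonRow:
    model: str
    band_method: str
    n_bands: int
    calibration: EvalReport
    validation: EvalReport


@dataclass
class ComparisonTable:
    """The model x band-set comparison: one row per combination."""

    rows: list[ComparisonRow]
    selected_bands: dict[str, np.ndarray]
    config: ComparisonConfig

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append(
                {
                    "model": row.model,
                    "band_method": row.band_method,
                    "n_bands": row.n_bands,
                    "cal_n": row.calibration.n,
                    "cal_r2": row.calibration.r2,
                    "cal_rmse": row.calibration.rmse,
                    "cal_rpd": row.calibration.rpd,
                    "val_n": row.validation.n,
                    "val_r2": row.validation.r2,
                    "val_rmse": row.validation.rmse,
                    "val_rpd": row.validation.rpd,
                }
            )
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        return path

    def to_text(self) -> str:
        df = self.to_frame().copy()
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].map(lambda x: f"{x:.2f}")
        return df.to_string(index=False)


_MODEL_FACTORIES = {
    "PLSR": lambda cfg: regression.plsr_spec(max_components=cfg.pls_max_components),
    "RFR": lambda cfg: regression.rfr_spec(n_trees=cfg.n_trees, seed=cfg.seed),
    "ERT": lambda cfg: regression.ert_spec(n_trees=cfg.n_trees, seed=cfg.seed),
    "KNN": lambda cfg: regression.knn_spec(k=cfg.knn_k, seed=cfg.seed),
}


def run_comparison(
    spectra: SpectraSet,
    band_set_methods: Sequence[str] = ("full", "CA", "x-Lw"),
    model_methods: Sequence[str] = ("PLSR", "RFR", "ERT", "KNN"),
    config: ComparisonConfig | None = None,
) -> ComparisonTable:
    """Fit every model on every band set and report calibration/validation
    R-squared, RMSE and RPD.

    Input spectra should be unmasked (the configured atmospheric mask is
    applied here) with LWC present in the metadata.  Characteristic bands are
    screened on the calibration season only unless
    ``config.pooled_band_selection`` is set.
    """
    config = config or ComparisonConfig()
    if config.mask is not None:
        spectra = apply_atmospheric_mask(spectra, config.mask)
    cal, val = year_split(spectra)
    y_cal = cal.lwc
    y_val = val.lwc
    if not (np.all(np.isfinite(y_cal)) and np.all(np.isfinite(y_val))):
        raise DomainError("every sample needs a finite LWC for the comparison")

    screen = spectra if config.pooled_band_selection else cal
    band_sets: dict[str, np.ndarray] = {}
    for bm in band_set_methods:
        if bm == "full":
            band_sets[bm] = spectra.grid.wavelengths.copy()
        elif bm == "CA":
            curve = bandselect.correlation_curve(screen, screen.lwc)
            band_sets[bm] = bandselect.select_bands_ca(
                curve,
                n_target=config.ca_n_target,
                window=config.ca_window,
                min_separation=config.ca_min_separation,
            ).wavelengths
        elif bm == "x-Lw":
            loadings = bandselect.fit_pls_loadings(
                screen,
                screen.lwc,
                max_components=config.xlw_max_components,
                cv=config.pls_cv,
                random_state=config.seed,
            )
            band_sets[bm] = bandselect.select_bands_xlw(
                loadings,
                n_components=min(config.xlw_components, loadings.n_components),
                window=config.xlw_window,
            ).wavelengths
        else:
            raise DomainError(f"unknown band-set method {bm!r}")

    rows = []
    for model_name in model_methods:
        if model_name not in _MODEL_FACTORIES:
            raise DomainError(f"unknown model method {model_name!r}")
        spec = _MODEL_FACTORIES[model_name](config)
        for bm in band_set_methods:
            wavelengths = band_sets[bm]
            fitted = regression.fit(spec, cal, bands=wavelengths, lwc=y_cal)
            rows.append(
                ComparisonRow(
                    model=model_name,
                    band_method=bm,
                    n_bands=int(wavelengths.size),
                    calibration=evaluate(
                        y_cal, regression.predict(fitted, cal), "calibration"
                    ),
                    validation=evaluate(
                        y_val, regression.predict(fitted, val), "validation"
                    ),
                )
            )
    return ComparisonTable(rows=rows, selected_bands=band_sets, config=config)
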