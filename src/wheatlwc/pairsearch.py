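"""Exhaustive two-band index optimisation against leaf water content.

For every pair of retained bands (l1, l2) the generic index (normalized
difference, simple ratio, or difference) is computed per sample and its
squared Pearson correlation with LWC fills an R-squared matrix — the
contour-map computation used to locate "hot spot" wavelength regions and the
single best pair.  R-squared here equals the coefficient of determination of
a univariate linear fit of LWC on the index.

Undefined index values (zero denominators) are excluded pairwise per cell;
cells with fewer than three valid samples or a zero-variance index stay
missing.  The normalized and difference forms are antisymmetric in (l1, l2),
so their matrices are symmetric in R-squared and only the upper triangle is
computed and mirrored; the ratio form is evaluated over all ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyResultError, InsufficientDataError
from .spectra import SpectraSet, WavelengthGrid

PAIR_KINDS = ("normalized", "ratio", "difference")
SYMMETRIC_KINDS = ("normalized", "difference")

_MIN_VALID = 3
_VAR_FLOOR = 1e-24  # below this an index column is treated as constant


@dataclass
class PairSearchResult:
    """R-squared grid over all two-band combinations of one index form."""

    kind: str
    grid: WavelengthGrid
    r2_matrix: np.ndarray  # n_bands x n_bands, NaN where undefined
    n_valid: np.ndarray    # per-cell valid-sample count

    @property
    def symmetric(self) -> bool:
        return self.kind in SYMMETRIC_KINDS


@dataclass(frozen=True)
class PairHotspot:
    lambda1: int
    lambda2: int
    r2: float
    rank: int


def _row_index_values(kind: str, r1: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Index values of band l1 (column vector r1) against a block of l2 bands."""
    a = r1[:, None]
    if kind == "difference":
        return a - rest
    if kind == "normalized":
        den = a + rest
        out = np.full(rest.shape, np.nan)
        ok = den != 0.0
        out[ok] = ((a - rest)[ok]) / den[ok]
        return out
    if kind == "ratio":
        out = np.full(rest.shape, np.nan)
        ok = rest != 0.0
        out[ok] = (np.broadcast_to(a, rest.shape)[ok]) / rest[ok]
        return out
    raise DomainError(f"unknown pair kind {kind!r}")


def _r2_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Pearson correlation of y with each column of X, excluding
    non-finite entries of X pairwise.  Returns (r2, n_valid) per column."""
    V = np.isfinite(X)
    n = V.sum(axis=0).astype(float)
    Xz = np.where(V, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xz.sum(axis=0) / n
        sy = y @ V
        my = sy / n
    A = np.where(V, X - mx, 0.0)
    Yc = np.where(V, y[:, None] - my, 0.0)
    cross = (A * Yc).sum(axis=0)
    varx = (A * A).sum(axis=0)
    vary = (Yc * Yc).sum(axis=0)
    r2 = np.full(X.shape[1], np.nan)
    ok = (n >= _MIN_VALID) & (varx > _VAR_FLOOR) & (vary > _VAR_FLOOR)
    r2[ok] = np.clip(cross[ok] ** 2 / (varx[ok] * vary[ok]), 0.0, 1.0)
    return r2, n.astype(np.int64)


def pair_r2_map(spectra: SpectraSet, lwc: np.ndarray, kind: str) -> PairSearchResult:
    """R-squared between LWC and every two-band index of the given form.

    ``spectra`` should already be atmospherically masked; only bands on its
    grid are searched.
    """
    if kind not in PAIR_KINDS:
        raise DomainError(f"kind must be one of {PAIR_KINDS}, got {kind!r}")
    y = np.asarray(lwc, dtype=float)
    if y.shape != (spectra.n_samples,):
        raise DomainError("lwc vector length must equal the sample count")
    finite = np.isfinite(y)
    if finite.sum() < _MIN_VALID:
        raise InsufficientDataError(
            f"need at least {_MIN_VALID} samples with finite LWC, have {int(finite.sum())}"
        )
    R = spectra.reflectance[finite]
    y = y[finite]
    n_bands = len(spectra.grid)
    r2 = np.full((n_bands, n_bands), np.nan)
    n_valid = np.zeros((n_bands, n_bands), dtype=np.int64)
    symmetric = kind in SYMMETRIC_KINDS
    for i in range(n_bands):
        if symmetric:
            if i + 1 >= n_bands:
                continue
            cols = slice(i + 1, n_bands)
        else:
            cols = slice(0, n_bands)
        X = _row_index_values(kind, R[:, i], R[:, cols])
        row_r2, row_n = _r2_columns(X, y)
        r2[i, cols] = row_r2
        n_valid[i, cols] = row_n
        if not symmetric:
            # the diagonal index is constant (ratio = 1): zero variance
            r2[i, i] = np.nan
            n_valid[i, i] = 0
    if symmetric:
        iu = np.triu_indices(n_bands, k=1)
        r2[(iu[1], iu[0])] = r2[iu]
        n_valid[(iu[1], iu[0])] = n_valid[iu]
    return PairSearchResult(kind=kind, grid=spectra.grid, r2_matrix=r2, n_valid=n_valid)


def best_pair(result: PairSearchResult, top_k: int = 10) -> list[PairHotspot]:
    """Top-k cells by R-squared, deduplicated under the form's symmetry.

    Symmetric forms report l1 < l2.  Ties break toward smaller l1, then
    smaller l2.
    """
    if top_k < 1:
        raise DomainError("top_k must be >= 1")
    r2 = result.r2_matrix
    wl = result.grid.wavelengths
    if result.symmetric:
        ii, jj = np.triu_indices(len(wl), k=1)
    else:
        ii, jj = np.where(~np.eye(len(wl), dtype=bool))
    vals = r2[ii, jj]
    defined = np.isfinite(vals)
    if not defined.any():
        raise EmptyResultError("every cell of the R-squared matrix is undefined")
    ii, jj, vals = ii[defined], jj[defined], vals[defined]
    order = np.lexsort((wl[jj], wl[ii], -vals))
    hotspots = []
    for rank, k in enumerate(order[:top_k], start=1):
        hotspots.append(
            PairHotspot(
                lambda1=int(wl[ii[k]]),
                lambda2=int(wl[jj[k]]),
                r2=float(vals[k]),
                rank=rank,
            )
        )
    return hotspots


def export_contour(result: PairSearchResult, path: str | Path) -> Path:
    """Write the R-squared matrix as CSV with wavelength headers; missing
    cells are left empty."""
    path = Path(path)
    wl = result.grid.wavelengths
    df = pd.DataFrame(result.r2_matrix, index=wl, columns=wl)
    df.to_csv(path, float_format="%.12g", na_rep="")
    return path


def read_contour(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Re-import an exported contour CSV -> (wavelengths, r2 matrix)."""
    df = pd.read_csv(path, index_col=0)
    wl = df.index.to_numpy(dtype=np.int64)
    return wl, df.to_numpy(dtype=float)
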