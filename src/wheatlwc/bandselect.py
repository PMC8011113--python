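"""Characteristic-band screening: correlation extrema and PLS loading weights.

Two screening rules reduce the ~1900 retained bands to a workable subset:

CA (correlation analysis)
    Compute the per-band Pearson correlation r between reflectance and LWC,
    then pick wavelengths at local extrema of |r| — the crests and troughs of
    the correlation curve.  If the extrema over- or under-shoot the requested
    count, the set is trimmed (largest |r| first) or topped up from the
    remaining bands by |r|, subject to a minimum spacing so the top-up does
    not collapse onto one shoulder.

x-Lw (PLS x-loading weights)
    Fit a PLS1 decomposition of centred spectra against centred LWC, inspect
    the loading-weight vector of each leading component, and take the union
    of its peaks and troughs.  The number of components defaults to 3 and can
    instead be chosen at the cross-validated RMSEP minimum.

Both rules operate per contiguous grid segment: extremum neighbourhoods never
straddle an excluded atmospheric window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut, cross_val_predict

from .errors import DomainError, InsufficientDataError
from .spectra import SpectraSet, WavelengthGrid


@dataclass
class CorrelationCurve:
    """Per-band Pearson correlation between reflectance and LWC."""

    grid: WavelengthGrid
    r: np.ndarray  # in [-1, 1]; NaN where the band has zero variance


@dataclass
class LoadingCurves:
    """PLS1 diagnostics: loading weights, response variance explained, RMSEP."""

    grid: WavelengthGrid
    n_components: int
    weights: np.ndarray                 # n_components x n_bands, sign-fixed
    explained_variance: np.ndarray      # % of response variance per component
    rmsep_by_components: np.ndarray     # cross-validated RMSEP for 1..n_components


@dataclass
class SelectedBands:
    """An ordered characteristic-band subset with its diagnostics."""

    method: str  # "CA" or "x-Lw"
    wavelengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.int64)
        if wl.size != np.unique(wl).size:
            raise DomainError("selected wavelengths must be unique")
        self.wavelengths = np.sort(wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)


def correlation_curve(spectra: SpectraSet, lwc: np.ndarray) -> CorrelationCurve:
    """Pearson r between each band's reflectance and LWC across samples."""
    y = np.asarray(lwc, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise InsufficientDataError("need at least 3 samples with finite LWC")
    R = spectra.reflectance[finite]
    y = y[finite]
    yc = y - y.mean()
    Rc = R - R.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((Rc**2).sum(axis=0))
    r = np.full(R.shape[1], np.nan)
    ok = (sx > 0) & (sy > 0)
    r[ok] = (Rc[:, ok].T @ yc) / (sx[ok] * sy)
    return CorrelationCurve(grid=spectra.grid, r=np.clip(r, -1.0, 1.0))


def local_extrema(
    values: np.ndarray,
    window: int,
    segments: list[slice] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local peaks and troughs within a sliding window.

    An interior index i is a peak when its value strictly exceeds every value
    up to ``window`` positions to its left and is at least every value up to
    ``window`` positions to its right (within the same contiguous segment),
    so a flat plateau reports its leftmost index; troughs are symmetric.
    Segment endpoints are never extrema.  NaN values break segments.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise DomainError("window must be >= 1")
    if segments is None:
        segments = [slice(0, v.size)]
    peaks: list[int] = []
    troughs: list[int] = []
    for seg in segments:
        idx = np.arange(seg.start, seg.stop)
        finite = np.isfinite(v[idx])
        # split further at NaN runs
        for run in _finite_runs(idx, finite):
            s, e = run  # inclusive start, exclusive stop
            for i in range(s + 1, e - 1):
                lo = max(s, i - window)
                hi = min(e, i + window + 1)
                left = v[lo:i]
                right = v[i + 1 : hi]
                if np.all(v[i] > left) and np.all(v[i] >= right):
                    peaks.append(i)
                elif np.all(v[i] < left) and np.all(v[i] <= right):
                    troughs.append(i)
    return np.array(peaks, dtype=np.intp), np.array(troughs, dtype=np.intp)


def _finite_runs(idx: np.ndarray, finite: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for pos, ok in zip(idx, finite):
        if ok and start is None:
            start = pos
        elif not ok and start is not None:
            runs.append((start, pos))
            start = None
    if start is not None:
        runs.append((start, idx[-1] + 1))
    return runs


def select_bands_ca(
    curve: CorrelationCurve,
    n_target: int = 100,
    window: int = 10,
    min_separation: int = 2,
) -> SelectedBands:
    """Correlation-extremum band screening.

    Seeds are the peaks of |r|; the set is trimmed or topped up to exactly
    ``n_target`` wavelengths as described in the module docstring.  Fully
    deterministic: ties rank toward the smaller wavelength.
    """
    a = np.abs(curve.r)
    valid = np.isfinite(a)
    n_avail = int(valid.sum())
    if n_target < 1:
        raise DomainError("n_target must be >= 1")
    if n_target > n_avail:
        raise DomainError(
            f"n_target={n_target} exceeds the {n_avail} bands with defined correlation"
        )
    wl = curve.grid.wavelengths
    seeds, _ = local_extrema(a, window=window, segments=curve.grid.segments())

    def rank_order(indices: np.ndarray) -> np.ndarray:
        return indices[np.lexsort((wl[indices], -a[indices]))]

    if seeds.size >= n_target:
        selected = list(rank_order(seeds)[:n_target])
    else:
        selected = list(seeds)
        chosen = set(selected)
        remaining = rank_order(
            np.array([i for i in np.flatnonzero(valid) if i not in chosen], dtype=np.intp)
        )
        for i in remaining:
            if len(selected) >= n_target:
                break
            if all(abs(i - s) >= min_separation for s in selected):
                selected.append(int(i))
        if len(selected) < n_target:
            # spacing exhausted the candidates; fill the remainder by |r| alone
            for i in remaining:
                if len(selected) >= n_target:
                    break
                if int(i) not in set(selected):
                    selected.append(int(i))
    selected_arr = np.array(sorted(selected), dtype=np.intp)
    return SelectedBands(
        method="CA",
        wavelengths=wl[selected_arr],
        diagnostics={
            "r": curve.r[selected_arr].copy(),
            "seed_wavelengths": wl[np.sort(seeds)].copy(),
            "curve": curve,
        },
    )


def fit_pls_loadings(
    spectra: SpectraSet,
    lwc: np.ndarray,
    max_components: int = 10,
    cv: str = "loo",
    n_splits: int = 5,
    random_state: int = 0,
) -> LoadingCurves:
    """PLS1 decomposition of centred spectra against centred LWC.

    Returns the sign-fixed x-loading-weight vector, the percentage of
    response variance explained per component, and the cross-validated RMSEP
    for every component count (``cv`` = "loo" or "kfold").  Each weight
    vector is oriented so its largest-magnitude element is positive, making
    peak/trough positions reproducible across runs and libraries.
    """
    y = np.asarray(lwc, dtype=float)
    finite = np.isfinite(y)
    X = spectra.reflectance[finite]
    y = y[finite]
    n = y.size
    if n < max_components + 2:
        raise InsufficientDataError(
            f"need at least max_components + 2 = {max_components + 2} samples, have {n}"
        )
    cap = min(max_components, n - 1, X.shape[1])
    if cap < max_components:
        warnings.warn(
            f"max_components truncated from {max_components} to {cap} (data rank limit)",
            stacklevel=2,
        )
    if cv == "loo":
        splitter = LeaveOneOut()
    elif cv == "kfold":
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    else:
        raise DomainError(f"cv must be 'loo' or 'kfold', got {cv!r}")

    rmsep = np.empty(cap)
    for k in range(1, cap + 1):
        pred = cross_val_predict(
            PLSRegression(n_components=k, scale=False), X, y, cv=splitter
        ).ravel()
        rmsep[k - 1] = float(np.sqrt(np.mean((y - pred) ** 2)))

    pls = PLSRegression(n_components=cap, scale=False).fit(X, y)
    weights = pls.x_weights_.T.copy()  # cap x n_bands
    for k in range(cap):
        if weights[k, np.argmax(np.abs(weights[k]))] < 0:
            weights[k] = -weights[k]

    # response variance explained per component: incremental R^2 of y on the
    # (orthogonal) X-score sequence
    T = pls.x_scores_
    yc = y - y.mean()
    sst = float((yc**2).sum())
    explained = np.empty(cap)
    prev = 0.0
    for k in range(1, cap + 1):
        beta, *_ = np.linalg.lstsq(T[:, :k], yc, rcond=None)
        ssr = float(((T[:, :k] @ beta) ** 2).sum())
        r2k = ssr / sst
        explained[k - 1] = max(r2k - prev, 0.0) * 100.0
        prev = r2k
    return LoadingCurves(
        grid=spectra.grid,
        n_components=cap,
        weights=weights,
        explained_variance=explained,
        rmsep_by_components=rmsep,
    )


def best_n_components(loadings: LoadingCurves) -> int:
    """Component count at the RMSEP minimum.

    Numerical ties resolve to the smallest count, so noise-free data does not
    over-select components on floating-point jitter.
    """
    rmsep = loadings.rmsep_by_components
    best = rmsep.min()
    return int(np.flatnonzero(rmsep <= best * (1 + 1e-8) + 1e-12)[0]) + 1


def select_bands_xlw(
    loadings: LoadingCurves,
    n_components: int = 3,
    window: int = 10,
) -> SelectedBands:
    """Loading-weight band screening: union of the peaks and troughs of the
    first ``n_components`` loading-weight curves."""
    if n_components < 1 or n_components > loadings.n_components:
        raise DomainError(
            f"n_components must be in 1..{loadings.n_components}, got {n_components}"
        )
    segments = loadings.grid.segments()
    wl = loadings.grid.wavelengths
    chosen: dict[int, tuple[int, float]] = {}
    for k in range(n_components):
        peaks, troughs = local_extrema(loadings.weights[k], window=window, segments=segments)
        for i in np.concatenate((peaks, troughs)):
            chosen.setdefault(int(i), (k + 1, float(loadings.weights[k, i])))
    idx = np.array(sorted(chosen), dtype=np.intp)
    return SelectedBands(
        method="x-Lw",
        wavelengths=wl[idx],
        diagnostics={
            "component": np.array([chosen[int(i)][0] for i in idx]),
            "weight": np.array([chosen[int(i)][1] for i in idx]),
            "loadings": loadings,
        },
    )
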