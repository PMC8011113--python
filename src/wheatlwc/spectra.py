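"""Core data model for canopy reflectance spectra.

A :class:`SpectraSet` couples a matrix of per-sample reflectances (unitless
fractions in [0, 1]) with a strictly increasing integer wavelength grid in
nanometres and per-sample agronomic metadata.  Reflectance is *always* held
internally as a fraction; percent appears only at the CSV boundary, because
ratio-type indices are scale invariant but difference indices and spectral
derivatives are not, and a single internal convention prevents silent
factor-of-100 bugs.

Field spectroradiometer data in the 350-2500 nm range are unreliable inside
the atmospheric water-vapour windows; :func:`apply_atmospheric_mask` drops
those bands.  The default exclusion windows are 1350-1400, 1800-1950 and
2450-2500 nm, applied with a half-open convention (the lower endpoint is
retained) so that the default 2151-band grid retains exactly 1901 bands.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DomainError,
    MissingBandError,
    SpectraFormatError,
    SpectraValidationError,
)

GRID_MIN_NM = 350
GRID_MAX_NM = 2500

#: Irrigation treatments of the field design: w0 = irrigation at the bottom
#: (pre-winter) stage only, w1 = bottom + jointing, w2 = bottom + jointing +
#: grain filling.
TREATMENTS = ("w0", "w1", "w2")

MAX_DATE_INDEX = 6

#: Atmospheric water-vapour exclusion windows (nm), half-open (low, high].
DEFAULT_EXCLUDED_WINDOWS = ((1350, 1400), (1800, 1950), (2450, 2500))

META_COLUMNS = ("sample_id", "year", "cultivar", "treatment", "date_index", "lwc")

_WL_COLUMN = re.compile(r"^wl_(\d+)$")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing integer wavelengths (nm) in [350, 2500]."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.int64)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise DomainError("wavelength grid must be a non-empty 1-D sequence")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if wl[0] < GRID_MIN_NM or wl[-1] > GRID_MAX_NM:
            raise DomainError(
                f"wavelengths must lie in [{GRID_MIN_NM}, {GRID_MAX_NM}] nm"
            )

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The instrument grid: 350..2500 nm at 1 nm (2151 bands)."""
        return cls(np.arange(GRID_MIN_NM, GRID_MAX_NM + 1))

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __contains__(self, nm: int) -> bool:
        i = int(np.searchsorted(self.wavelengths, nm))
        return i < len(self) and self.wavelengths[i] == nm

    def index_of(self, nm: int) -> int:
        """Position of an exact integer wavelength; no interpolation."""
        i = int(np.searchsorted(self.wavelengths, nm))
        if i >= len(self) or self.wavelengths[i] != nm:
            raise MissingBandError(f"wavelength {nm} nm is not on the grid")
        return i

    def indices_of(self, nms: Iterable[int]) -> np.ndarray:
        return np.array([self.index_of(int(nm)) for nm in nms], dtype=np.intp)

    def step(self) -> int:
        """Smallest spacing on the grid (the sampling step between mask gaps)."""
        if len(self) < 2:
            return 1
        return int(np.diff(self.wavelengths).min())

    def segments(self) -> list[slice]:
        """Contiguous runs of the grid, split where masking left a gap.

        A gap is any spacing larger than the grid's base step, e.g. the jump
        across an excluded atmospheric window.
        """
        if len(self) == 1:
            return [slice(0, 1)]
        d = np.diff(self.wavelengths)
        step = d.min()
        breaks = np.flatnonzero(d > step) + 1
        starts = np.concatenate(([0], breaks))
        stops = np.concatenate((breaks, [len(self)]))
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


@dataclass
class SampleMeta:
    """Per-sample agronomic metadata.

    ``date_index`` numbers the six sampling dates from green-up (1) to late
    grain filling (6); ``lwc`` is leaf water content in percent of fresh mass
    and may be absent until measured/assigned.
    """

    sample_id: str
    year: str
    cultivar: int
    treatment: str
    date_index: int
    lwc: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise DomainError(
                f"treatment {self.treatment!r} not in {TREATMENTS}"
            )
        if not 1 <= int(self.date_index) <= MAX_DATE_INDEX:
            raise DomainError(f"date_index {self.date_index} outside 1..{MAX_DATE_INDEX}")
        if int(self.cultivar) < 1:
            raise DomainError("cultivar must be a positive integer")
        if self.lwc is not None:
            if not (0.0 < float(self.lwc) <= 100.0):
                raise DomainError(f"lwc {self.lwc} outside (0, 100]")


@dataclass
class SpectraSet:
    """Reflectance matrix (n_samples x n_bands, fraction) with metadata."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    meta: list[SampleMeta]

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=np.float64)
        if r.ndim != 2:
            raise SpectraValidationError("reflectance must be a 2-D matrix")
        if r.shape[1] != len(self.grid):
            raise SpectraValidationError(
                f"reflectance has {r.shape[1]} columns but grid has {len(self.grid)} bands"
            )
        if r.shape[0] != len(self.meta):
            raise SpectraValidationError(
                f"reflectance has {r.shape[0]} rows but {len(self.meta)} metadata entries"
            )
        if r.size and (np.nanmin(r) < 0.0 or np.nanmax(r) > 1.0):
            bad = np.argwhere((r < 0.0) | (r > 1.0))[0]
            raise SpectraValidationError(
                "reflectance outside [0, 1] at sample "
                f"{self.meta[bad[0]].sample_id!r}, wl_{self.grid.wavelengths[bad[1]]}"
            )
        self.reflectance = r

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def lwc(self) -> np.ndarray:
        """Per-sample LWC (%) with NaN where unassigned."""
        return np.array(
            [np.nan if m.lwc is None else float(m.lwc) for m in self.meta]
        )

    def band(self, nm: int) -> np.ndarray:
        """Reflectance column at an exact wavelength."""
        return self.reflectance[:, self.grid.index_of(nm)]

    def select_bands(self, wavelengths: Sequence[int]) -> "SpectraSet":
        """Restrict to an explicit ascending wavelength subset."""
        idx = self.grid.indices_of(wavelengths)
        return SpectraSet(
            grid=WavelengthGrid(self.grid.wavelengths[idx]),
            reflectance=self.reflectance[:, idx],
            meta=[replace(m) for m in self.meta],
        )

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows, dtype=np.intp)
        return SpectraSet(
            grid=self.grid,
            reflectance=self.reflectance[rows],
            meta=[replace(self.meta[i]) for i in rows],
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "year": [m.year for m in self.meta],
                "cultivar": [m.cultivar for m in self.meta],
                "treatment": [m.treatment for m in self.meta],
                "date_index": [m.date_index for m in self.meta],
                "lwc": [m.lwc for m in self.meta],
            }
        )


@dataclass(frozen=True)
class BandMask:
    """Set of excluded wavelength windows.

    ``half_open=True`` (default) drops wavelengths with low < nm <= high, so
    the lower endpoint of each window is retained; with the three default
    atmospheric windows this leaves 1901 of the 2151 instrument bands.
    """

    excluded_intervals: tuple[tuple[int, int], ...] = DEFAULT_EXCLUDED_WINDOWS
    half_open: bool = True

    def __post_init__(self) -> None:
        ivals = tuple(
            (int(lo), int(hi)) for lo, hi in self.excluded_intervals
        )
        object.__setattr__(self, "excluded_intervals", ivals)
        prev_hi = None
        for lo, hi in sorted(ivals):
            if lo >= hi:
                raise DomainError(f"empty or inverted mask interval ({lo}, {hi})")
            if lo < GRID_MIN_NM or hi > GRID_MAX_NM:
                raise DomainError(
                    f"mask interval ({lo}, {hi}) outside [{GRID_MIN_NM}, {GRID_MAX_NM}]"
                )
            if prev_hi is not None and lo < prev_hi:
                raise DomainError("mask intervals overlap")
            prev_hi = hi

    @classmethod
    def default(cls) -> "BandMask":
        return cls()

    @classmethod
    def empty(cls) -> "BandMask":
        return cls(excluded_intervals=())

    def keep(self, wavelengths: np.ndarray) -> np.ndarray:
        """Boolean mask of wavelengths that survive the exclusion windows."""
        wl = np.asarray(wavelengths)
        drop = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.excluded_intervals:
            if self.half_open:
                drop |= (wl > lo) & (wl <= hi)
            else:
                drop |= (wl >= lo) & (wl <= hi)
        return ~drop


def apply_atmospheric_mask(spectra: SpectraSet, mask: BandMask | None = None) -> SpectraSet:
    """Drop the bands falling in the mask's exclusion windows.

    Returns a new :class:`SpectraSet`; the input is untouched.  Retained
    reflectance values are carried over exactly.
    """
    mask = BandMask.default() if mask is None else mask
    keep = mask.keep(spectra.grid.wavelengths)
    if not keep.any():
        raise DegenerateInputError("mask removes every band on the grid")
    return SpectraSet(
        grid=WavelengthGrid(spectra.grid.wavelengths[keep]),
        reflectance=spectra.reflectance[:, keep],
        meta=[replace(m) for m in spectra.meta],
    )


def decimate(spectra: SpectraSet, step: int) -> SpectraSet:
    """Keep every ``step``-th band — a coarse grid for exploratory searches."""
    if step < 1:
        raise DomainError("decimation step must be >= 1")
    idx = np.arange(0, len(spectra.grid), step)
    return SpectraSet(
        grid=WavelengthGrid(spectra.grid.wavelengths[idx]),
        reflectance=spectra.reflectance[:, idx],
        meta=[replace(m) for m in spectra.meta],
    )


def lwc_from_mass(fresh_mass: float, dry_mass: float) -> float:
    """Leaf water content (%) from fresh and oven-dry leaf mass in grams.

    LWC = (m_f - m_d) / m_f * 100.
    """
    mf = float(fresh_mass)
    md = float(dry_mass)
    if mf <= 0.0 or md <= 0.0:
        raise DomainError("leaf masses must be positive")
    if md > mf:
        raise DomainError("dry mass cannot exceed fresh mass")
    return (mf - md) / mf * 100.0


def first_derivative(spectra: SpectraSet) -> "DerivativeSet":
    """First derivative of reflectance with respect to wavelength.

    Central differences on the interior of each contiguous grid segment,
    one-sided differences at segment ends; units are reflectance fraction per
    nm.  Segments shorter than two bands get NaN (no difference is defined).
    """
    deriv = np.full_like(spectra.reflectance, np.nan)
    wl = spectra.grid.wavelengths.astype(np.float64)
    for seg in spectra.grid.segments():
        if seg.stop - seg.start < 2:
            continue
        deriv[:, seg] = np.gradient(spectra.reflectance[:, seg], wl[seg], axis=1)
    return DerivativeSet(grid=spectra.grid, values=deriv)


@dataclass
class DerivativeSet:
    """Per-band first-derivative spectra (fraction per nm); not reflectance."""

    grid: WavelengthGrid
    values: np.ndarray

    def band(self, nm: int) -> np.ndarray:
        col = self.values[:, self.grid.index_of(nm)]
        if np.all(np.isnan(col)):
            raise MissingBandError(
                f"derivative undefined at {nm} nm (isolated band)"
            )
        return col


def read_spectra_csv(path: str | Path, reflectance_scale: str = "fraction") -> SpectraSet:
    """Read a one-row-per-sample spectra CSV.

    The header must name every metadata column (sample_id, year, cultivar,
    treatment, date_index, lwc) plus one reflectance column per wavelength
    named ``wl_<nm>``.  ``reflectance_scale`` is ``"fraction"`` or
    ``"percent"``; percent inputs are divided by 100 on read.
    """
    path = Path(path)
    if reflectance_scale not in ("fraction", "percent"):
        raise DomainError(f"unknown reflectance scale {reflectance_scale!r}")
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    seen: set[str] = set()
    dups = [c for c in header if c in seen or seen.add(c)]  # type: ignore[func-returns-value]
    if dups:
        raise SpectraFormatError(f"duplicated columns in {path.name}: {sorted(set(dups))}")
    missing_meta = [c for c in META_COLUMNS if c not in header]
    if missing_meta:
        raise SpectraFormatError(f"missing metadata columns: {missing_meta}")
    wl_cols = {}
    for c in header:
        m = _WL_COLUMN.match(c)
        if m:
            wl_cols[int(m.group(1))] = c
        elif c not in META_COLUMNS:
            raise SpectraFormatError(f"unrecognised column {c!r}")
    if not wl_cols:
        raise SpectraFormatError("no wavelength columns (wl_<nm>) found")

    df = pd.read_csv(path)
    wavelengths = np.array(sorted(wl_cols), dtype=np.int64)
    grid = WavelengthGrid(wavelengths)
    refl = df[[wl_cols[w] for w in wavelengths]].to_numpy(dtype=np.float64)
    if reflectance_scale == "percent":
        refl = refl / 100.0
    bad = np.argwhere((refl < 0.0) | (refl > 1.0) | ~np.isfinite(refl))
    if bad.size:
        i, j = bad[0]
        raise SpectraValidationError(
            f"reflectance out of [0, 1] at row {df['sample_id'].iloc[i]!r}, "
            f"column wl_{wavelengths[j]} (value {refl[i, j]!r})"
        )
    meta = []
    for _, row in df.iterrows():
        lwc = row["lwc"]
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                year=str(row["year"]),
                cultivar=int(row["cultivar"]),
                treatment=str(row["treatment"]),
                date_index=int(row["date_index"]),
                lwc=None if pd.isna(lwc) else float(lwc),
            )
        )
    return SpectraSet(grid=grid, reflectance=refl, meta=meta)


def write_spectra_csv(
    spectra: SpectraSet, path: str | Path, reflectance_scale: str = "fraction"
) -> Path:
    """Write a spectra CSV that :func:`read_spectra_csv` round-trips to 1e-9."""
    if reflectance_scale not in ("fraction", "percent"):
        raise DomainError(f"unknown reflectance scale {reflectance_scale!r}")
    path = Path(path)
    refl = spectra.reflectance
    if reflectance_scale == "percent":
        refl = refl * 100.0
    df = spectra.meta_frame()
    wl_df = pd.DataFrame(
        refl, columns=[f"wl_{w}" for w in spectra.grid.wavelengths]
    )
    out = pd.concat([df.reset_index(drop=True), wl_df], axis=1)
    out.to_csv(path, index=False, float_format="%.12g")
    return path
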