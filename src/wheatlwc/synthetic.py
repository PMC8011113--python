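"""Synthetic winter-wheat canopy reflectance with known leaf water content.

The field campaign this pipeline targets (7 cultivars x 3 irrigation
treatments x 6 sampling dates x 2 seasons = 252 canopy spectra with oven-dry
LWC) is not publicly deposited, so the pipeline is exercised on a generator
that reproduces the *statistical* structure the analysis relies on:

* LWC trajectories rise to a peak shortly after jointing-stage irrigation and
  then fall, with the late-season treatment ordering w2 > w1 > w0 (more
  irrigation, wetter leaves);
* canopy biomass grows through the season, faster under more irrigation, and
  scales the NIR plateau, so NIR reflectance orders w2 > w1 > w0 after grain
  filling;
* Gaussian absorption dips at the canonical water bands (970, 1200, 1450,
  1940 nm) deepen linearly with canopy water (LWC x biomass);
* cultivar-level random intercepts per season, per-sample residuals, and
  additive spectral noise.

This is a phenomenological shape model, not a radiative-transfer model: it
gives the band-selection and regression machinery a controllable, water-driven
signal, not physically calibrated reflectances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, DomainError
from .spectra import (
    MAX_DATE_INDEX,
    TREATMENTS,
    SampleMeta,
    SpectraSet,
    WavelengthGrid,
)

#: Mean LWC (%) per treatment over the six sampling dates.  Unimodal with the
#: peak at date 2 (ten days after jointing irrigation), converging early and
#: separating late with w2 > w1 > w0; anchored to the field range of roughly
#: 56-89 % with an overall mean near 79 %.
DEFAULT_LWC_TABLE: Mapping[str, tuple[float, ...]] = {
    "w0": (82.0, 86.0, 83.0, 78.0, 70.0, 60.0),
    "w1": (82.0, 86.5, 83.5, 79.5, 74.0, 67.0),
    "w2": (82.5, 87.0, 84.0, 81.0, 77.0, 72.0),
}

DEFAULT_BIOMASS_GAIN: Mapping[str, float] = {"w0": 0.15, "w1": 0.30, "w2": 0.45}

# Fixed spectral shape constants (fractions / nm): a low visible baseline with
# a green peak at 550 nm, and a smooth SWIR decline of the vegetation plateau.
_VIS_BASE = 0.04
_GREEN_AMPLITUDE = 0.04
_GREEN_CENTER_NM = 550.0
_GREEN_WIDTH_NM = 30.0
_SWIR_DECLINE_CENTER_NM = 1550.0
_SWIR_DECLINE_WIDTH_NM = 250.0
_SWIR_DECLINE_FRACTION = 0.65


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic canopy experiment.

    The defaults emulate the two-season irrigation trial: 7 cultivars x
    3 treatments x 6 dates x 2 years = 252 samples, 126 per season.
    """

    seed: int = 20180101
    n_cultivars: int = 7
    treatments: tuple[str, ...] = TREATMENTS
    n_dates: int = 6
    n_years: int = 2
    lwc_profile_table: Mapping[str, tuple[float, ...]] | None = None
    cultivar_sd: float = 1.0           # % LWC, random intercept per cultivar x year
    residual_sd: float = 1.0           # % LWC, per sample
    biomass_base: float = 1.0
    biomass_gain: Mapping[str, float] | None = None
    absorption_centers: tuple[int, ...] = (970, 1200, 1450, 1940)
    absorption_widths: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0)
    absorption_rel_depths: tuple[float, ...] = (0.30, 0.40, 1.00, 1.20)
    absorption_depth_coeff: float = 0.18   # reflectance per unit canopy water
    noise_sd: float = 0.005            # reflectance fraction
    red_edge_center: float = 720.0     # nm
    red_edge_width: float = 15.0       # nm
    nir_plateau: float = 0.45          # plateau reflectance at biomass 1.0

    def __post_init__(self) -> None:
        if self.n_cultivars < 1 or self.n_years < 1:
            raise ConfigurationError("n_cultivars and n_years must be >= 1")
        if not 1 <= self.n_dates <= MAX_DATE_INDEX:
            raise ConfigurationError(f"n_dates must be in 1..{MAX_DATE_INDEX}")
        bad = [t for t in self.treatments if t not in TREATMENTS]
        if bad or not self.treatments:
            raise ConfigurationError(f"treatments must be a non-empty subset of {TREATMENTS}")
        for sd in (self.cultivar_sd, self.residual_sd, self.noise_sd):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        if not (
            len(self.absorption_centers)
            == len(self.absorption_widths)
            == len(self.absorption_rel_depths)
        ):
            raise ConfigurationError("absorption centers/widths/depths length mismatch")
        table = self.lwc_profile_table or DEFAULT_LWC_TABLE
        for t in self.treatments:
            if t not in table:
                raise ConfigurationError(f"lwc_profile_table lacks treatment {t!r}")
            if len(table[t]) < self.n_dates:
                raise ConfigurationError(
                    f"lwc_profile_table[{t!r}] has fewer than n_dates entries"
                )
            if any(not (0.0 < v <= 100.0) for v in table[t]):
                raise ConfigurationError("lwc_profile_table values must lie in (0, 100]")
        self.lwc_profile_table = {t: tuple(table[t]) for t in table}
        self.biomass_gain = dict(self.biomass_gain or DEFAULT_BIOMASS_GAIN)
        for t in self.treatments:
            if t not in self.biomass_gain:
                raise ConfigurationError(f"biomass_gain lacks treatment {t!r}")

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * len(self.treatments) * self.n_dates * self.n_years

    def year_label(self, year_idx: int) -> str:
        return f"{2018 + year_idx}-{2019 + year_idx}"


@dataclass
class GroundTruth:
    """Generator-side truth: per-sample LWC (%) and biomass factor."""

    sample_ids: list[str]
    true_lwc: np.ndarray
    biomass: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.true_lwc = np.asarray(self.true_lwc, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if not len(self.sample_ids) == self.true_lwc.size == self.biomass.size:
            raise ConfigurationError("ground-truth arrays must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "true_lwc": self.true_lwc,
                "biomass": self.biomass,
                "seed": self.seed,
            }
        )


def lwc_profile(treatment: str, date_index: int, config: SyntheticConfig) -> float:
    """Mean LWC (%) for a treatment at a sampling date (1-based)."""
    table = config.lwc_profile_table
    if treatment not in table:
        raise DomainError(f"unknown treatment {treatment!r}")
    if not 1 <= date_index <= config.n_dates:
        raise DomainError(f"date_index {date_index} outside 1..{config.n_dates}")
    return float(table[treatment][date_index - 1])


def biomass_factor(treatment: str, date_index: int, config: SyntheticConfig) -> float:
    """Unitless canopy biomass scaler: grows through the season, faster with
    more irrigation."""
    if treatment not in config.biomass_gain:
        raise DomainError(f"unknown treatment {treatment!r}")
    progression = (date_index - 1) / max(config.n_dates - 1, 1)
    return config.biomass_base + config.biomass_gain[treatment] * progression


def baseline_spectrum(
    biomass: float, config: SyntheticConfig, wavelengths: np.ndarray
) -> np.ndarray:
    """Dip-free canopy spectrum: visible base + red-edge rise to a
    biomass-scaled NIR plateau with a smooth SWIR decline."""
    wl = np.asarray(wavelengths, dtype=float)
    vis = _VIS_BASE + _GREEN_AMPLITUDE * np.exp(
        -0.5 * ((wl - _GREEN_CENTER_NM) / _GREEN_WIDTH_NM) ** 2
    )
    red_edge = 1.0 / (1.0 + np.exp(-(wl - config.red_edge_center) / config.red_edge_width))
    swir = 1.0 - _SWIR_DECLINE_FRACTION / (
        1.0 + np.exp(-(wl - _SWIR_DECLINE_CENTER_NM) / _SWIR_DECLINE_WIDTH_NM)
    )
    return vis + config.nir_plateau * biomass * red_edge * swir


def absorption_dips(
    lwc: float, biomass: float, config: SyntheticConfig, wavelengths: np.ndarray
) -> np.ndarray:
    """Summed Gaussian water-absorption dips; depth grows linearly with
    canopy water = (LWC/100) x biomass."""
    wl = np.asarray(wavelengths, dtype=float)
    water = (lwc / 100.0) * biomass
    dips = np.zeros_like(wl)
    for center, width, rel in zip(
        config.absorption_centers, config.absorption_widths, config.absorption_rel_depths
    ):
        dips += (
            config.absorption_depth_coeff
            * water
            * rel
            * np.exp(-0.5 * ((wl - center) / width) ** 2)
        )
    return dips


def simulate_spectrum(
    lwc: float,
    biomass: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """One canopy reflectance vector on the (default) grid.

    Deterministic given (lwc, biomass, config) when ``noise_sd`` is zero.
    """
    if not 0.0 < lwc <= 100.0:
        raise DomainError(f"lwc {lwc} outside (0, 100]")
    if biomass <= 0.0:
        raise DomainError("biomass must be positive")
    wl = (
        WavelengthGrid.default().wavelengths.astype(float)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    r = baseline_spectrum(biomass, config, wl) - absorption_dips(lwc, biomass, config, wl)
    if config.noise_sd > 0:
        r = r + rng.normal(0.0, config.noise_sd, size=wl.size)
    clipped = np.count_nonzero((r < 0.0) | (r > 1.0))
    if clipped > 0.5 * wl.size:
        raise ConfigurationError(
            f"{clipped}/{wl.size} bands clipped to [0, 1]; "
            "the configured shape parameters are not physically plausible"
        )
    return np.clip(r, 0.0, 1.0)


def simulate_dataset(config: SyntheticConfig | None = None) -> tuple[SpectraSet, GroundTruth]:
    """The full synthetic experiment: one sample per cultivar x treatment x
    date x year, with metadata populated and true LWC attached.

    Reruns with the same config (same seed) are bitwise identical.  All
    randomness derives from ``config.seed`` through independent substreams
    for cultivar intercepts, LWC residuals and spectral noise.
    """
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    cultivar_rng, residual_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    grid = WavelengthGrid.default()
    wl = grid.wavelengths.astype(float)

    cultivar_effects = cultivar_rng.normal(
        0.0, config.cultivar_sd, size=(config.n_years, config.n_cultivars)
    )
    rows, meta, truth_lwc, truth_biomass, ids = [], [], [], [], []
    for y in range(config.n_years):
        year = config.year_label(y)
        for c in range(1, config.n_cultivars + 1):
            for trt in config.treatments:
                for d in range(1, config.n_dates + 1):
                    mean = lwc_profile(trt, d, config)
                    lwc = (
                        mean
                        + cultivar_effects[y, c - 1]
                        + residual_rng.normal(0.0, config.residual_sd)
                    )
                    lwc = float(np.clip(lwc, 1e-9, 100.0))
                    biomass = biomass_factor(trt, d, config)
                    rows.append(
                        simulate_spectrum(lwc, biomass, config, noise_rng, wl)
                    )
                    sid = f"{year}_c{c}_{trt}_d{d}"
                    ids.append(sid)
                    meta.append(
                        SampleMeta(
                            sample_id=sid,
                            year=year,
                            cultivar=c,
                            treatment=trt,
                            date_index=d,
                            lwc=lwc,
                        )
                    )
                    truth_lwc.append(lwc)
                    truth_biomass.append(biomass)
    spectra = SpectraSet(grid=grid, reflectance=np.vstack(rows), meta=meta)
    truth = GroundTruth(
        sample_ids=ids,
        true_lwc=np.array(truth_lwc),
        biomass=np.array(truth_biomass),
        seed=config.seed,
    )
    return spectra, truth
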