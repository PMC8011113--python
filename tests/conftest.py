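"""Shared fixtures: toy spectra builders and the default synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from wheatlwc import (
    SampleMeta,
    SpectraSet,
    SyntheticConfig,
    WavelengthGrid,
    apply_atmospheric_mask,
    decimate,
    simulate_dataset,
)


def make_spectra(
    reflectance: np.ndarray,
    wavelengths: np.ndarray | list[int],
    lwc: np.ndarray | list[float] | None = None,
    year: str | list[str] = "2018-2019",
) -> SpectraSet:
    """Build a toy SpectraSet with minimal metadata."""
    reflectance = np.asarray(reflectance, dtype=float)
    n = reflectance.shape[0]
    years = [year] * n if isinstance(year, str) else list(year)
    meta = [
        SampleMeta(
            sample_id=f"s{i}",
            year=years[i],
            cultivar=1,
            treatment="w0",
            date_index=1,
            lwc=None if lwc is None else float(lwc[i]),
        )
        for i in range(n)
    ]
    return SpectraSet(
        grid=WavelengthGrid(np.asarray(wavelengths)), reflectance=reflectance, meta=meta
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The 252-sample default synthetic experiment (fixed seed)."""
    return simulate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def coarse_masked(default_dataset):
    """Default dataset, atmospherically masked and decimated to a 4 nm grid."""
    spectra, truth = default_dataset
    return decimate(apply_atmospheric_mask(spectra), 4), truth
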