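"""Two-band vegetation indices and the literature water-index catalogue.

The three generic two-band forms over reflectances R at wavelengths l1, l2:

    NDVI(l1, l2) = (R_l1 - R_l2) / (R_l1 + R_l2)
    RVI(l1, l2)  = R_l1 / R_l2
    DVI(l1, l2)  = R_l1 - R_l2

plus ten published water-sensitive indices (MSI, NDWI, WI, NDII, ...).  Three
catalogue entries circulate in the literature with typographical defects
(NDWI mixing 820/860 nm, a self-cancelling hNDVI, NDII mixing 1649/1679 nm);
by default this module computes the forms from the original citations
(Gao 1996 NDWI with 860/1240 nm throughout; the Rouse normalized-difference
form with a ``+`` denominator; Hardisky NDII with 1649 nm throughout).  Pass
``as_printed=True`` to reproduce the degenerate printed variants.

Samples where an index denominator vanishes are flagged undefined (NaN) and
counted — never silently dropped — so downstream correlations can exclude
them pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CatalogError, DomainError
from .spectra import SpectraSet, first_derivative

_GENERIC_NAMES = {"normalized": "NDVI", "ratio": "RVI", "difference": "DVI"}

#: Wavelength pair of the best-performing optimised two-band indices found by
#: the exhaustive search on the field data.
OPTIMIZED_PAIR_NM = (1185, 1307)


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral index and the wavelengths (or window) it uses."""

    name: str
    kind: str  # normalized | ratio | difference | derivative_ratio | window_normalized | composite
    wavelengths: tuple[int, ...]
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.window is not None and self.window[0] >= self.window[1]:
            raise DomainError(f"index window bounds must satisfy low < high: {self.window}")


@dataclass
class IndexValues:
    """Per-sample values of one index; NaN marks undefined samples."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_undefined(self) -> int:
        return int(np.count_nonzero(~np.isfinite(self.values)))


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0.0
    out[ok] = num[ok] / den[ok]
    return out


def generic_index(kind: str, lambda1: int, lambda2: int, spectra: SpectraSet) -> IndexValues:
    """One of the three generic two-band forms at an explicit wavelength pair."""
    if kind not in _GENERIC_NAMES:
        raise DomainError(f"unknown generic index kind {kind!r}")
    r1 = spectra.band(lambda1)
    r2 = spectra.band(lambda2)
    if kind == "normalized":
        values = _safe_divide(r1 - r2, r1 + r2)
    elif kind == "ratio":
        values = _safe_divide(r1, r2)
    else:
        values = r1 - r2
    name = f"{_GENERIC_NAMES[kind]}(R{lambda1},R{lambda2})"
    return IndexValues(name=name, values=values)


def _normalized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _safe_divide(a - b, a + b)


def _literature_values(name: str, spectra: SpectraSet, as_printed: bool) -> np.ndarray:
    R = spectra.band
    if name == "RI":
        return _safe_divide(R(1650), R(2220))
    if name == "NDWI":
        if as_printed:
            return _safe_divide(R(860) - R(1240), R(820) + R(1240))
        return _normalized(R(860), R(1240))
    if name == "MSI":
        return _safe_divide(R(1600), R(820))
    if name == "MDWI":
        lo = spectra.grid.index_of(1500)
        hi = spectra.grid.index_of(1750)
        window = spectra.reflectance[:, lo : hi + 1]
        return _normalized(window.max(axis=1), window.min(axis=1))
    if name == "hNDVI":
        if as_printed:
            return _safe_divide(R(900) - R(680), R(900) - R(680))
        return _normalized(R(900), R(680))
    if name == "WI":
        return _safe_divide(R(900), R(970))
    if name == "SRWI":
        return _safe_divide(R(820), R(1200))
    if name == "NDII":
        if as_printed:
            return _safe_divide(R(820) - R(1649), R(820) + R(1679))
        return _normalized(R(820), R(1649))
    if name == "WI/hNDVI":
        return _safe_divide(
            _literature_values("WI", spectra, as_printed),
            _literature_values("hNDVI", spectra, as_printed),
        )
    if name == "FD730-955":
        fd = first_derivative(spectra)
        return _safe_divide(fd.band(730), fd.band(955))
    raise CatalogError(f"unknown index {name!r}")


LITERATURE_INDEX_NAMES = (
    "RI",
    "NDWI",
    "MSI",
    "MDWI",
    "hNDVI",
    "WI",
    "SRWI",
    "NDII",
    "WI/hNDVI",
    "FD730-955",
)

_LITERATURE_DEFINITIONS = {
    "RI": IndexDefinition("RI", "ratio", (1650, 2220)),
    "NDWI": IndexDefinition("NDWI", "normalized", (860, 1240)),
    "MSI": IndexDefinition("MSI", "ratio", (1600, 820)),
    "MDWI": IndexDefinition("MDWI", "window_normalized", (), window=(1500, 1750)),
    "hNDVI": IndexDefinition("hNDVI", "normalized", (900, 680)),
    "WI": IndexDefinition("WI", "ratio", (900, 970)),
    "SRWI": IndexDefinition("SRWI", "ratio", (820, 1200)),
    "NDII": IndexDefinition("NDII", "normalized", (820, 1649)),
    "WI/hNDVI": IndexDefinition("WI/hNDVI", "composite", (900, 970, 680)),
    "FD730-955": IndexDefinition("FD730-955", "derivative_ratio", (730, 955)),
}


def literature_index(name: str, spectra: SpectraSet, as_printed: bool = False) -> IndexValues:
    """One of the ten published water indices by catalogue name."""
    if name not in _LITERATURE_DEFINITIONS:
        raise CatalogError(f"unknown index {name!r}; known: {LITERATURE_INDEX_NAMES}")
    return IndexValues(name=name, values=_literature_values(name, spectra, as_printed))


def index_catalog() -> list[IndexDefinition]:
    """The 13 indices compared against LWC: ten literature water indices plus
    the three optimised two-band forms at (1185, 1307) nm."""
    catalog = [_LITERATURE_DEFINITIONS[n] for n in LITERATURE_INDEX_NAMES]
    l1, l2 = OPTIMIZED_PAIR_NM
    for kind in ("normalized", "ratio", "difference"):
        catalog.append(
            IndexDefinition(
                name=f"{_GENERIC_NAMES[kind]}(R{l1},R{l2})",
                kind=kind,
                wavelengths=(l1, l2),
            )
        )
    return catalog


def compute_index(definition: IndexDefinition, spectra: SpectraSet) -> IndexValues:
    """Evaluate any catalogue entry on a spectra set."""
    if definition.name in _LITERATURE_DEFINITIONS:
        return literature_index(definition.name, spectra)
    if definition.kind in _GENERIC_NAMES:
        l1, l2 = definition.wavelengths
        iv = generic_index(definition.kind, l1, l2, spectra)
        return IndexValues(name=definition.name, values=iv.values)
    raise CatalogError(f"cannot evaluate definition {definition.name!r}")


def evaluate_catalog(spectra: SpectraSet):
    """All 13 catalogue indices as a samples x indices DataFrame."""
    import pandas as pd

    cols = {d.name: compute_index(d, spectra).values for d in index_catalog()}
    return pd.DataFrame(cols, index=[m.sample_id for m in spectra.meta])
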