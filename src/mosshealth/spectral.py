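"""Spectral vegetation indices.

Implements the 21-index panel used for moss/lichen health mapping: the
classic broadband indices (NDVI, DVI, SRI, EVI, TVI, ...), the soil-adjusted
family (MSAVI, OSAVI, GOSAVI), red-edge chlorophyll indices (NDRE, LCI, GCI)
and the visible-band excess-green family (EXG, EXR, EXGR, NGRDI, RGI, GRVI).
All indices use reflectance in the blue/green/red/red-edge/NIR bands only;
the thermal plane never participates.

Ratio indices are undefined where their denominator vanishes; such pixels
are flagged nodata rather than propagating infinities into features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BandStack, BandError

__all__ = [
    "INDEX_NAMES",
    "MODEL8",
    "IndexPlane",
    "compute_index",
    "compute_all_indices",
]

#: The eight-index subset found to yield the stronger stage-1 model,
#: in its canonical order.
MODEL8 = ("GNDVI", "MSAVI", "LCI", "GRVI", "RGI", "NDRE", "EVI", "SIPI")

_EPS_DENOM = 0.0  # exact-zero denominators are masked; no fudge factor


def _safe_div(num, den):
    """Element-wise num/den; returns (values, invalid_mask)."""
    invalid = den == _EPS_DENOM
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(invalid, 0.0, num / np.where(invalid, 1.0, den))
    return out, invalid


# Each formula returns (values, extra_invalid_mask).  B, G, R, RE, N are the
# blue, green, red, red-edge and NIR reflectance planes.

def _ndvi(B, G, R, RE, N):
    return _safe_div(N - R, N + R)

def _gndvi(B, G, R, RE, N):
    return _safe_div(N - G, N + G)

def _msavi(B, G, R, RE, N):
    # standard closed form: (2N + 1 - sqrt((2N+1)^2 - 8(N-R))) / 2
    disc = (2.0 * N + 1.0) ** 2 - 8.0 * (N - R)
    bad = disc < 0
    vals = (2.0 * N + 1.0 - np.sqrt(np.where(bad, 0.0, disc))) / 2.0
    return vals, bad

def _evi(B, G, R, RE, N):
    return _safe_div(2.5 * (N - R), N + 6.0 * R - 7.5 * B + 1.0)

def _sri(B, G, R, RE, N):
    return _safe_div(N, R)

def _arvi(B, G, R, RE, N):
    # conventional ARVI with rb = 2R - B
    rb = 2.0 * R - B
    return _safe_div(N - rb, N + rb)

def _arvi_printed(B, G, R, RE, N):
    # literal reading of the garbled published formula, which collapses to
    # (N + 2B) / (N - 2B)
    return _safe_div(N + 2.0 * B, N - 2.0 * B)

def _sipi(B, G, R, RE, N):
    return _safe_div(N - B, N - R)

def _gci(B, G, R, RE, N):
    vals, bad = _safe_div(N, G)
    return vals - 1.0, bad

def _ndre(B, G, R, RE, N):
    return _safe_div(N - RE, N + RE)

def _lci(B, G, R, RE, N):
    return _safe_div(N - RE, N + R)

def _dvi(B, G, R, RE, N):
    return N - R, np.zeros(N.shape, bool)

def _tvi(B, G, R, RE, N):
    return 60.0 * (N - G) - 100.0 * (R - G), np.zeros(N.shape, bool)

def _ngrdi(B, G, R, RE, N):
    return _safe_div(G - R, G + R)

def _osavi(B, G, R, RE, N):
    return _safe_div(1.16 * (N - R), N + R + 0.16)

def _gosavi(B, G, R, RE, N):
    return _safe_div(N - G, N + G + 0.16)

def _exg(B, G, R, RE, N):
    return _safe_div(2.0 * G - R - B, R + G + B)

def _exr(B, G, R, RE, N):
    return _safe_div(1.4 * R - G, R + G + B)

def _exgr(B, G, R, RE, N):
    g, bad_g = _exg(B, G, R, RE, N)
    r, bad_r = _exr(B, G, R, RE, N)
    return g - r, bad_g | bad_r

def _rgi(B, G, R, RE, N):
    return _safe_div(R, G)

def _grvi(B, G, R, RE, N):
    return _safe_div(R - G, R + G)

def _endvi(B, G, R, RE, N):
    return _safe_div((N + G) - 2.0 * B, N + G + 2.0 * B)


_FORMULAS = {
    "NDVI": _ndvi,
    "GNDVI": _gndvi,
    "MSAVI": _msavi,
    "EVI": _evi,
    "SRI": _sri,
    "ARVI": _arvi,
    "SIPI": _sipi,
    "GCI": _gci,
    "NDRE": _ndre,
    "LCI": _lci,
    "DVI": _dvi,
    "TVI": _tvi,
    "NGRDI": _ngrdi,
    "OSAVI": _osavi,
    "GOSAVI": _gosavi,
    "EXG": _exg,
    "EXR": _exr,
    "EXGR": _exgr,
    "RGI": _rgi,
    "GRVI": _grvi,
    "ENDVI": _endvi,
}

#: All 21 recognised index identifiers.
INDEX_NAMES = tuple(_FORMULAS)

_SPECTRAL_BANDS = ("blue", "green", "red", "red_edge", "nir")


@dataclass
class IndexPlane:
    """One computed spectral-index plane aligned to its source stack."""

    name: str
    values: np.ndarray
    nodata_mask: np.ndarray
    formula_id: str


def compute_index(name: str, stack: BandStack, arvi_as_printed: bool = False) -> IndexPlane:
    """Compute a single spectral index over a band stack.

    Zero-denominator pixels and source nodata pixels are flagged in the
    result's ``nodata_mask`` and hold 0.0 in ``values``.
    """
    if name not in _FORMULAS:
        raise KeyError(
            f"unknown spectral index {name!r}; valid identifiers: {sorted(_FORMULAS)}"
        )
    for b in _SPECTRAL_BANDS:
        if b not in stack.bands:
            raise BandError(f"stack is missing band {b!r} required by {name}")
    planes = [stack.bands[b] for b in _SPECTRAL_BANDS]
    formula_id = name
    fn = _FORMULAS[name]
    if name == "ARVI" and arvi_as_printed:
        fn = _arvi_printed
        formula_id = "ARVI_as_printed"
    vals, invalid = fn(*planes)
    mask = stack.nodata_mask | invalid
    vals = np.where(mask, 0.0, vals)
    assert np.all(np.isfinite(vals[~mask]))
    return IndexPlane(name=name, values=vals, nodata_mask=mask, formula_id=formula_id)


def compute_all_indices(
    stack: BandStack,
    subset: list[str] | None = None,
    arvi_as_printed: bool = False,
) -> list[IndexPlane]:
    """Compute a list of index planes; default is the full 21-index panel.

    ``subset=["model8"]`` expands to the eight-index preset
    ``{GNDVI, MSAVI, LCI, GRVI, RGI, NDRE, EVI, SIPI}`` in that order.
    """
    if subset is None:
        names = list(INDEX_NAMES)
    else:
        if len(subset) == 0:
            raise ValueError("empty index subset; pass None for the full panel")
        names = []
        for s in subset:
            if s == "model8":
                names.extend(MODEL8)
            else:
                names.append(s)
    return [compute_index(n, stack, arvi_as_printed=arvi_as_printed) for n in names]
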