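"""Sensor band resampling and the broadband vegetation-index registry.

Bands use a boxcar spectral response (centre +/- half-width).  The 5-band
sensor layout assigns GREEN to 560 nm and RED to 650 nm (the conventional
assignment for this band set).  The VI registry holds 21 canonical
broadband index formulas; zero denominators propagate NaN, never a silent
zero.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "BandSet",
    "resample_to_bands",
    "compute_vi",
    "compute_all",
    "vi_names",
    "VI_REGISTRY",
    "BAND_NAMES",
]

BAND_NAMES = ("BLUE", "GREEN", "RED", "REDEDGE", "NIR")


@dataclass(frozen=True)
class Band:
    name: str
    center: float  # nm
    half_width: float  # nm

    @property
    def window(self):
        return self.center - self.half_width, self.center + self.half_width


@dataclass(frozen=True)
class BandSet:
    bands: tuple[Band, ...]

    def __post_init__(self):
        centers = [b.center for b in self.bands]
        if sorted(centers) != centers:
            raise ValueError("band centers must be strictly increasing")

    @classmethod
    def uav5(cls) -> "BandSet":
        """The 5-band multispectral sensor: 450/560/650/730/840 nm, +/-16 nm."""
        hw = 16.0
        return cls(
            bands=(
                Band("BLUE", 450.0, hw),
                Band("GREEN", 560.0, hw),
                Band("RED", 650.0, hw),
                Band("REDEDGE", 730.0, hw),
                Band("NIR", 840.0, hw),
            )
        )

    def __len__(self):
        return len(self.bands)


def resample_to_bands(wavelength, spectrum, bandset: BandSet | None = None):
    """Boxcar-average a spectrum into sensor bands.

    ``spectrum`` may have any leading shape with wavelength on the last
    axis; returns an array with the last axis replaced by the bands.
    """
    bandset = bandset or BandSet.uav5()
    wavelength = np.asarray(wavelength, float)
    spectrum = np.asarray(spectrum, float)
    out = np.empty(spectrum.shape[:-1] + (len(bandset),))
    for i, band in enumerate(bandset.bands):
        lo, hi = band.window
        if lo < wavelength[0] or hi > wavelength[-1]:
            raise ValueError(
                f"spectrum ({wavelength[0]}-{wavelength[-1]} nm) does not cover "
                f"band {band.name} ({lo}-{hi} nm)"
            )
        mask = (wavelength >= lo - 1e-9) & (wavelength <= hi + 1e-9)
        out[..., i] = spectrum[..., mask].mean(axis=-1)
    return out


def _div(num, den):
    """Division with zero denominators mapped to NaN."""
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num / np.where(den == 0.0, 1.0, den))
    return out


def _sqrt(x):
    x = np.asarray(x, float)
    with np.errstate(invalid="ignore"):
        return np.where(x < 0.0, np.nan, np.sqrt(np.clip(x, 0.0, None)))


# registry order is the deterministic tie-break order used by the ranking
VI_REGISTRY = OrderedDict(
    [
        ("NDVI-RE", lambda B, G, R, RE, N: _div(N - RE, N + RE)),
        ("CIre", lambda B, G, R, RE, N: _div(N, RE) - 1.0),
        ("TVI", lambda B, G, R, RE, N: 0.5 * (120.0 * (N - G) - 200.0 * (R - G))),
        ("CIgreen", lambda B, G, R, RE, N: _div(N, G) - 1.0),
        ("GNDVI", lambda B, G, R, RE, N: _div(N - G, N + G)),
        ("SR(RE/G)", lambda B, G, R, RE, N: _div(RE, G)),
        ("SR(NIR/R)", lambda B, G, R, RE, N: _div(N, R)),
        (
            "mSR",
            lambda B, G, R, RE, N: _div(_div(N, R) - 1.0, _sqrt(_div(N, R)) + 1.0),
        ),
        (
            "MTVI1",
            lambda B, G, R, RE, N: 1.2 * (1.2 * (N - G) - 2.5 * (R - G)),
        ),
        ("NDVI", lambda B, G, R, RE, N: _div(N - R, N + R)),
        ("NLI", lambda B, G, R, RE, N: _div(N**2 - R, N**2 + R)),
        (
            "TCARI",
            lambda B, G, R, RE, N: 3.0 * ((RE - R) - 0.2 * (RE - G) * _div(RE, R)),
        ),
        (
            "TCARI/OSAVI",
            lambda B, G, R, RE, N: _div(
                3.0 * ((RE - R) - 0.2 * (RE - G) * _div(RE, R)),
                1.16 * _div(N - R, N + R + 0.16),
            ),
        ),
        ("OSAVI", lambda B, G, R, RE, N: 1.16 * _div(N - R, N + R + 0.16)),
        (
            "EVI",
            lambda B, G, R, RE, N: 2.5 * _div(N - R, N + 6.0 * R - 7.5 * B + 1.0),
        ),
        (
            "MSAVI",
            lambda B, G, R, RE, N: 0.5
            * (2.0 * N + 1.0 - _sqrt((2.0 * N + 1.0) ** 2 - 8.0 * (N - R))),
        ),
        ("RDVI", lambda B, G, R, RE, N: _div(N - R, _sqrt(N + R))),
        (
            "TDVI",
            lambda B, G, R, RE, N: 1.5 * _div(N - R, _sqrt(N**2 + R + 0.5)),
        ),
        ("DVI", lambda B, G, R, RE, N: N - R),
        (
            "MCARI",
            lambda B, G, R, RE, N: ((RE - R) - 0.2 * (RE - G)) * _div(RE, R),
        ),
        (
            "MTVI2",
            lambda B, G, R, RE, N: _div(
                1.5 * (1.2 * (N - G) - 2.5 * (R - G)),
                _sqrt((2.0 * N + 1.0) ** 2 - (6.0 * N - 5.0 * _sqrt(R)) - 0.5),
            ),
        ),
    ]
)


def vi_names() -> list[str]:
    return list(VI_REGISTRY)


def _band_arrays(bands):
    """Accept a mapping, Series/DataFrame, or array keyed/ordered by band."""
    if isinstance(bands, pd.DataFrame):
        return tuple(bands[name].to_numpy(float) for name in BAND_NAMES)
    if isinstance(bands, (dict, pd.Series)):
        return tuple(np.asarray(bands[name], float) for name in BAND_NAMES)
    arr = np.asarray(bands, float)
    if arr.shape[-1] != 5:
        raise ValueError("band array must have 5 entries on the last axis")
    return tuple(arr[..., i] for i in range(5))


def compute_vi(bands, name: str):
    """Evaluate one registered index on band reflectances."""
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown VI {name!r}; known: {', '.join(VI_REGISTRY)}")
    b, g, r, re, n = _band_arrays(bands)
    out = VI_REGISTRY[name](b, g, r, re, n)
    return float(out) if np.ndim(out) == 0 else out


def compute_all(bands, names=None):
    """Evaluate the full registry; returns a DataFrame (or Series for 1 sample)."""
    names = list(names) if names is not None else vi_names()
    b, g, r, re, n = _band_arrays(bands)
    values = {name: VI_REGISTRY[name](b, g, r, re, n) for name in names}
    if np.ndim(b) == 0:
        return pd.Series({k: float(v) for k, v in values.items()})
    return pd.DataFrame(values)
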