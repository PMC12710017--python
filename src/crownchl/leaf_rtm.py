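"""Plate-model leaf radiative transfer.

Computes directional-hemispherical leaf reflectance and transmittance on a
1-nm wavelength grid from leaf structure and biochemistry, following the
classic N-layer plate formulation: a single elementary plate bounded by
rough dielectric interfaces, generalised to ``N`` layers through the Stokes
equations for a pile of identical plates.

The per-layer compound absorption coefficient is

    k(lambda) = sum_i C_i * k_i(lambda) / N

and the isotropic transmission through one elementary layer uses the
exponential-integral expression ``(1 - k) exp(-k) + k^2 E1(k)``.

Calibration tables (refractive index and specific absorption coefficients)
are packaged as CSV under :mod:`crownchl.data`; see
``scripts/build_calibration.py`` for their provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import exp1

__all__ = [
    "LeafBiochem",
    "AbsorptionCoefficients",
    "LeafOptics",
    "tav",
    "prospect5",
    "load_coefficients",
]

#: default incidence half-angle (degrees) of the top leaf surface
DEFAULT_ALPHA = 40.0

#: conventional carotenoid-to-chlorophyll ratio used when cxc is tied to cab
DEFAULT_CXC_RATIO = 0.25


class ParameterError(ValueError):
    """Raised when a physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class LeafBiochem:
    """Leaf structure parameter and constituent contents.

    Parameters
    ----------
    n_struct : float
        Number of elementary layers (>= 1, unitless).
    cab : float
        Chlorophyll a+b content, ug/cm^2.
    cxc : float
        Carotenoid content, ug/cm^2.
    cbrown : float
        Brown pigment content, arbitrary units.
    cw : float
        Equivalent water thickness, cm.
    cm : float
        Dry matter content, g/cm^2.
    """

    n_struct: float = 1.5
    cab: float = 40.0
    cxc: float = 10.0
    cbrown: float = 0.0
    cw: float = 0.01
    cm: float = 0.009

    def __post_init__(self):
        if self.n_struct < 1.0:
            raise ParameterError(f"n_struct must be >= 1, got {self.n_struct}")
        for name in ("cab", "cxc", "cbrown", "cw", "cm"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def with_cab(cls, cab, *, cxc_ratio=DEFAULT_CXC_RATIO, **kwargs):
        """Build a biochem with carotenoids tied to chlorophyll (cxc = ratio*cab)."""
        return cls(cab=cab, cxc=cxc_ratio * cab, **kwargs)


@dataclass(frozen=True)
class AbsorptionCoefficients:
    """Refractive index and specific absorption coefficients on a nm grid."""

    wavelength: np.ndarray
    refractive_index: np.ndarray
    k_cab: np.ndarray
    k_cxc: np.ndarray
    k_cbrown: np.ndarray
    k_cw: np.ndarray
    k_cm: np.ndarray

    def __post_init__(self):
        nwl = self.wavelength.shape[0]
        for name in ("refractive_index", "k_cab", "k_cxc", "k_cbrown", "k_cw", "k_cm"):
            arr = getattr(self, name)
            if arr.shape != (nwl,):
                raise ParameterError(f"{name} grid mismatch: {arr.shape} vs ({nwl},)")
        if np.any(self.refractive_index <= 1.0):
            raise ParameterError("refractive_index must be > 1 everywhere")
        for name in ("k_cab", "k_cxc", "k_cbrown", "k_cw", "k_cm"):
            if np.any(getattr(self, name) < 0.0):
                raise ParameterError(f"{name} must be >= 0 everywhere")

    def compound_k(self, biochem: LeafBiochem) -> np.ndarray:
        """Per-layer absorption k = sum_i C_i k_i / N."""
        total = (
            biochem.cab * self.k_cab
            + biochem.cxc * self.k_cxc
            + biochem.cbrown * self.k_cbrown
            + biochem.cw * self.k_cw
            + biochem.cm * self.k_cm
        )
        return total / biochem.n_struct


@dataclass(frozen=True)
class LeafOptics:
    """Directional-hemispherical leaf reflectance/transmittance spectra."""

    wavelength: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self):
        if not (self.wavelength.shape == self.reflectance.shape == self.transmittance.shape):
            raise ParameterError("wavelength/R/T shape mismatch")

    @property
    def absorptance(self) -> np.ndarray:
        return 1.0 - self.reflectance - self.transmittance

    @property
    def albedo(self) -> np.ndarray:
        """Single-scattering albedo omega = R + T."""
        return self.reflectance + self.transmittance

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelength,
                "reflectance": self.reflectance,
                "transmittance": self.transmittance,
            }
        ).to_csv(path, index=False)


def load_coefficients(source: str | Path = "default") -> AbsorptionCoefficients:
    """Load a packaged ("default" or "test") or external CSV coefficient table."""
    if source in ("default", "test"):
        fname = "leaf_coefficients.csv" if source == "default" else "leaf_coefficients_test.csv"
        ref = resources.files("crownchl.data").joinpath(fname)
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    return AbsorptionCoefficients(
        wavelength=df["wavelength_nm"].to_numpy(float),
        refractive_index=df["refractive_index"].to_numpy(float),
        k_cab=df["k_cab"].to_numpy(float),
        k_cxc=df["k_cxc"].to_numpy(float),
        k_cbrown=df["k_cbrown"].to_numpy(float),
        k_cw=df["k_cw"].to_numpy(float),
        k_cm=df["k_cm"].to_numpy(float),
    )


def tav(alpha: float, n):
    """Average transmissivity of a dielectric interface.

    Transmission of isotropic radiation confined to a cone of half-angle
    ``alpha`` (degrees) across a plane interface of relative refractive
    index ``n``, per the Stern/Allen closed form.

    Parameters
    ----------
    alpha : float
        Incidence half-angle in degrees, in (0, 90].
    n : float or ndarray
        Relative refractive index, >= 1.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    n = np.asarray(n, dtype=float)
    if alpha <= 0.0 or alpha > 90.0:
        raise ParameterError(f"alpha must be in (0, 90], got {alpha}")
    if np.any(n < 1.0):
        raise ParameterError("refractive index must be >= 1")

    scalar = n.ndim == 0
    n = np.atleast_1d(n)
    result = np.ones_like(n)
    m = n > 1.0 + 1e-12  # n == 1: no interface
    if np.any(m):
        result[m] = _tav_stern(np.radians(alpha), n[m])
    return float(result[0]) if scalar else result


def _tav_stern(alpha_rad, n):
    """Closed-form Stern average transmissivity (vectorised over n)."""
    n2 = n**2
    np_ = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    sa = np.sin(alpha_rad)

    if np.isclose(alpha_rad, np.pi / 2.0):
        b1 = np.zeros_like(n)
    else:
        b1 = np.sqrt((sa**2 - np_ / 2.0) ** 2 + k)
    b2 = sa**2 - np_ / 2.0
    b = b1 - b2
    b3 = b**3
    a3 = a**3
    ts = (k**2 / (6.0 * b3) + k / b - b / 2.0) - (
        k**2 / (6.0 * a3) + k / a - a / 2.0
    )

    tp1 = -2.0 * n2 * (b - a) / (np_**2)
    tp2 = -2.0 * n2 * np_ * np.log(b / a) / (nm**2)
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0
        * n2**2
        * (n2**2 + 1.0)
        * np.log((2.0 * np_ * b - nm**2) / (2.0 * np_ * a - nm**2))
        / (np_**3 * nm**2)
    )
    tp5 = (
        16.0
        * n2**3
        * (1.0 / (2.0 * np_ * b - nm**2) - 1.0 / (2.0 * np_ * a - nm**2))
        / (np_**3)
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sa**2)


def _layer_transmission(k):
    """Isotropic transmission through one elementary absorbing layer."""
    k = np.asarray(k, dtype=float)
    trans = np.ones_like(k)
    pos = k > 0.0
    kp = k[pos]
    trans[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(trans, 0.0, 1.0)


def prospect5(
    biochem: LeafBiochem,
    coeffs: AbsorptionCoefficients | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> LeafOptics:
    """Run the N-layer plate model for one leaf.

    Parameters
    ----------
    biochem : LeafBiochem
        Leaf structure parameter and constituent contents.
    coeffs : AbsorptionCoefficients, optional
        Calibration table; the packaged default is used when omitted.
    alpha : float
        Incidence half-angle of the top interface, degrees.

    Returns
    -------
    LeafOptics on the coefficient wavelength grid.
    """
    if coeffs is None:
        coeffs = load_coefficients()
    n = coeffs.refractive_index
    k = coeffs.compound_k(biochem)
    tau = _layer_transmission(k)

    # top surface at `alpha`, interior interfaces at 90 degrees
    talf = tav(alpha, n)
    ralf = 1.0 - talf
    t12 = tav(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21

    denom = 1.0 - r21**2 * tau**2
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t

    Rsub, Tsub = _stokes_pile(r, t, biochem.n_struct)

    denom = 1.0 - Rsub * r
    T = Ta * Tsub / denom
    R = Ra + Ta * Rsub * t / denom

    R = np.clip(R, 0.0, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return LeafOptics(wavelength=coeffs.wavelength, reflectance=R, transmittance=T)


def _stokes_pile(r, t, n_struct):
    """Reflectance/transmittance of N-1 additional identical layers (Stokes)."""
    Rsub = np.zeros_like(r)
    Tsub = np.ones_like(t)
    if n_struct == 1.0:
        return Rsub, Tsub

    # near-conservative layers (r + t -> 1) take the analytic limit
    conservative = (r + t) >= 1.0 - 1e-12
    dissipative = ~conservative

    if np.any(conservative):
        tc = t[conservative]
        Tsub_c = tc / (tc + (1.0 - tc) * (n_struct - 1.0))
        Tsub[conservative] = Tsub_c
        Rsub[conservative] = 1.0 - Tsub_c

    if np.any(dissipative):
        rd = r[dissipative]
        td = t[dissipative]
        D = np.sqrt(
            (1.0 + rd + td) * (1.0 + rd - td) * (1.0 - rd + td) * (1.0 - rd - td)
        )
        r2 = rd**2
        t2 = td**2
        va = (1.0 + r2 - t2 + D) / (2.0 * rd)
        vb = (1.0 - r2 + t2 + D) / (2.0 * td)
        vbNN = vb ** (n_struct - 1.0)
        vbNN2 = vbNN**2
        va2 = va**2
        denomx = va2 * vbNN2 - 1.0
        Rsub[dissipative] = va * (vbNN2 - 1.0) / denomx
        Tsub[dissipative] = vbNN * (va2 - 1.0) / denomx

    return Rsub, Tsub
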