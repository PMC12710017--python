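"""Regenerate the packaged optical calibration tables.

Writes, under src/crownchl/data/:

* ``leaf_coefficients.csv``   -- refractive index and specific absorption
  coefficients of the leaf constituents on the 400-2500 nm / 1 nm grid.
  The curves are analytic (sums of Gaussian absorption bands plus smooth
  baselines) with band positions and magnitudes chosen to reproduce the
  well-known features of green-leaf optics: chlorophyll absorption in the
  blue and red, carotenoid absorption in the blue, liquid-water bands at
  970/1200/1450/1940/2500 nm, and a dry-matter continuum rising into the
  SWIR.  They are a self-contained surrogate calibration, not a copy of
  any published coefficient set.
* ``leaf_coefficients_test.csv`` -- a tiny synthetic table (400-700 nm,
  10 nm step, single Gaussian bands) used by unit tests that must not
  depend on the full calibration.
* ``soil_reflectance.csv`` and ``bark_reflectance.csv`` -- smooth bright
  background / bark spectra with shallow moisture dips.

Deterministic; run from the repository root:

    python scripts/build_calibration.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "crownchl" / "data"


def gauss(wl, center, sigma, amp):
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def build_leaf_coefficients(wl):
    n = 1.40 + 0.12 * np.exp(-(wl - 400.0) / 700.0)

    # chlorophyll a+b, cm^2/ug: blue + red bands, shallow green valley,
    # truncated above 760 nm so NIR is pigment-free
    k_cab = (
        gauss(wl, 435, 30, 0.100)
        + gauss(wl, 470, 25, 0.055)
        + gauss(wl, 615, 30, 0.030)
        + gauss(wl, 662, 25, 0.125)
        + 0.012 * np.exp(-0.5 * ((wl - 550) / 90.0) ** 2)
    )
    k_cab = np.where(wl > 760, 0.0, k_cab)

    # carotenoids, cm^2/ug: blue only
    k_cxc = gauss(wl, 448, 30, 0.110) + gauss(wl, 478, 20, 0.075)
    k_cxc = np.where(wl > 560, 0.0, k_cxc)

    # brown pigments, per arbitrary unit: broad decay through the visible
    k_cbrown = 0.8 * np.exp(-(wl - 400.0) / 220.0)
    k_cbrown = np.where(wl > 1400, 0.0, k_cbrown)

    # liquid water, cm^-1
    ramp = np.clip(wl - 1300.0, 0.0, None) / 1200.0 * 6.0
    k_cw = (
        gauss(wl, 970, 40, 0.55)
        + gauss(wl, 1200, 55, 1.8)
        + gauss(wl, 1450, 55, 34.0)
        + gauss(wl, 1790, 45, 6.0)
        + gauss(wl, 1940, 70, 115.0)
        + gauss(wl, 2500, 180, 95.0)
        + ramp
    )

    # dry matter, cm^2/g: continuum rising into the SWIR + cellulose/lignin bands
    sig = 1.0 / (1.0 + np.exp(-(wl - 950.0) / 180.0))
    k_cm = (
        6.0 * sig
        + gauss(wl, 1720, 55, 9.0)
        + gauss(wl, 2100, 75, 16.0)
        + gauss(wl, 2300, 90, 22.0)
    )

    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "refractive_index": n,
            "k_cab": k_cab,
            "k_cxc": k_cxc,
            "k_cbrown": k_cbrown,
            "k_cw": k_cw,
            "k_cm": k_cm,
        }
    )


def build_test_coefficients():
    wl = np.arange(400.0, 701.0, 10.0)
    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "refractive_index": np.full_like(wl, 1.45),
            "k_cab": gauss(wl, 550, 40, 0.1),
            "k_cxc": gauss(wl, 460, 30, 0.1),
            "k_cbrown": np.full_like(wl, 0.02),
            "k_cw": gauss(wl, 650, 30, 2.0),
            "k_cm": np.full_like(wl, 5.0),
        }
    )


def build_soil(wl):
    rho = 0.06 + 0.22 * (1.0 - np.exp(-(wl - 400.0) / 1100.0))
    rho -= gauss(wl, 1450, 60, 0.04) + gauss(wl, 1940, 80, 0.06)
    return pd.DataFrame({"wavelength_nm": wl, "reflectance": np.clip(rho, 0.0, 1.0)})


def build_bark(wl):
    rho = 0.07 + 0.28 / (1.0 + np.exp(-(wl - 850.0) / 260.0))
    rho -= gauss(wl, 1450, 60, 0.03) + gauss(wl, 1940, 80, 0.05)
    return pd.DataFrame({"wavelength_nm": wl, "reflectance": np.clip(rho, 0.0, 1.0)})


def main():
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    wl = np.arange(400.0, 2501.0, 1.0)
    build_leaf_coefficients(wl).to_csv(
        DATA_DIR / "leaf_coefficients.csv", index=False, float_format="%.6g"
    )
    build_test_coefficients().to_csv(
        DATA_DIR / "leaf_coefficients_test.csv", index=False, float_format="%.6g"
    )
    build_soil(wl).to_csv(
        DATA_DIR / "soil_reflectance.csv", index=False, float_format="%.6g"
    )
    build_bark(wl).to_csv(
        DATA_DIR / "bark_reflectance.csv", index=False, float_format="%.6g"
    )
    print(f"wrote calibration tables to {DATA_DIR}")


if __name__ == "__main__":
    main()
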