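"""Synthetic orchard surveys with known per-tree ground truth.

Stands in for the UAV campaign: builds row-structured layouts, samples
per-tree trait truth from truncated normals, renders 5-band nadir
reflectance rasters (with a crown-ID map) through the scene renderer and
spectral mixing, and extracts per-tree crown-mean reflectances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.stats import truncnorm

from .canopy_scene import (
    SHADED_LEAF,
    SITE_LATITUDE,
    SITE_LONGITUDE,
    SUNLIT_LEAF,
    CrownShape,
    FourComponentImage,
    MixingParams,
    OrchardScene,
    SceneError,
    crown_shadow_fraction,
    load_background_spectrum,
    render_four_component,
    site_time,
    sun_position,
)
from .leaf_rtm import DEFAULT_CXC_RATIO, LeafBiochem, load_coefficients, prospect5
from .spectral_indices import BAND_NAMES, BandSet, resample_to_bands

__all__ = [
    "OrchardLayout",
    "SyntheticSurvey",
    "generate_orchard",
    "sample_truth",
    "render_survey",
    "extract_crown_reflectance",
    "ORCHARD_PRESETS",
]

# rows x trees_per_row chosen to match the reported per-orchard tree counts
ORCHARD_PRESETS = {
    "orchard1": {"rows": 13, "trees_per_row": 33},
    "orchard2": {"rows": 5, "trees_per_row": 43},
    "mini": {"rows": 4, "trees_per_row": 6},
}


@dataclass(frozen=True)
class OrchardLayout:
    """Row-structured tree positions (m); rows run along x."""

    positions: np.ndarray  # (n, 2)
    rows: int
    trees_per_row: int
    row_spacing: float
    tree_spacing: float

    @property
    def n_trees(self) -> int:
        return self.positions.shape[0]


def generate_orchard(
    rows: int,
    trees_per_row: int,
    row_spacing: float = 4.0,
    tree_spacing: float = 2.5,
    jitter: float = 0.0,
    seed: int = 0,
    crown_diameter: float | None = None,
) -> OrchardLayout:
    """Deterministic row lattice with optional positional jitter.

    ``jitter`` is the standard deviation (m) of Gaussian offsets, truncated
    to 40% of the smaller spacing so trees keep their grid order.
    """
    if rows < 1 or trees_per_row < 1 or row_spacing <= 0 or tree_spacing <= 0:
        raise SceneError("orchard dimensions must be positive")
    min_spacing = min(row_spacing, tree_spacing)
    if crown_diameter is not None and min_spacing < 0.5 * crown_diameter:
        raise SceneError(
            f"spacing {min_spacing} m too small for crown diameter {crown_diameter} m"
        )
    xs = np.arange(trees_per_row) * tree_spacing
    ys = np.arange(rows) * row_spacing
    pos = np.array([(x, y) for y in ys for x in xs], float)
    pos -= pos.mean(axis=0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        cap = 0.4 * min_spacing
        pos = pos + np.clip(rng.normal(0.0, jitter, pos.shape), -cap, cap)
    return OrchardLayout(
        positions=pos,
        rows=rows,
        trees_per_row=trees_per_row,
        row_spacing=row_spacing,
        tree_spacing=tree_spacing,
    )


def _truncated_normal(mean, sd, lo, hi, size, rng):
    if hi <= lo:
        raise ValueError(f"inverted truncation bounds [{lo}, {hi}]")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_truth(
    n_trees: int,
    lcc_dist=(60.0, 10.0, 40.0, 85.0),
    lai_dist=(3.5, 0.8, 1.0, 6.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tree trait truth: truncated-normal LCC and LAI, CCC = LCC*LAI.

    Distribution tuples are (mean, sd, lower, upper).
    """
    rng = np.random.default_rng(seed)
    lcc = _truncated_normal(*lcc_dist, n_trees, rng)
    lai = _truncated_normal(*lai_dist, n_trees, rng)
    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n_trees + 1),
            "lcc": lcc,
            "lai": lai,
            "ccc": lcc * lai,
        }
    )


@dataclass
class SyntheticSurvey:
    """Rendered orchard raster pack with its generating truth."""

    bands: np.ndarray  # (5, ny, nx) reflectance in [0,1], BLUE..NIR order
    crown_id: np.ndarray  # (ny, nx) uint32, 0 = background
    four_component: FourComponentImage
    truth: pd.DataFrame
    time: float
    resolution: float
    noise_std: float
    shadow_fraction: pd.Series  # per tree_id

    def write(self, outdir) -> dict:
        """Write GeoTIFF pair + truth CSV; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "bands": outdir / "survey_bands.tif",
            "crown_id": outdir / "crown_id.tif",
            "truth": outdir / "truth.csv",
        }
        res = self.resolution
        tifffile.imwrite(
            paths["bands"],
            self.bands.astype(np.float32),
            photometric="minisblack",
            resolution=(1.0 / res, 1.0 / res),
        )
        tifffile.imwrite(paths["crown_id"], self.crown_id.astype(np.uint32))
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def render_survey(
    layout: OrchardLayout,
    truth: pd.DataFrame,
    time: float = 12.0,
    resolution: float = 0.03,
    noise_std: float = 0.01,
    seed: int = 0,
    crown: CrownShape | None = None,
    supersample: int = 2,
    mixing: MixingParams | None = None,
    coeffs=None,
    bandset: BandSet | None = None,
    min_crown_pixels: int = 20,
) -> SyntheticSurvey:
    """Render a 5-band nadir survey of the orchard.

    Per-pixel reflectance mixes each pixel's own sunlit/shaded component
    fractions with its tree's leaf optics (driven by that tree's true LCC)
    and the packaged soil spectrum, then adds clipped Gaussian sensor
    noise.  No shadow masking is applied anywhere.
    """
    if resolution > 0.1:
        raise SceneError("survey resolution must be <= 0.1 m/pixel")
    crown = crown or CrownShape()
    mixing = mixing or MixingParams()
    coeffs = coeffs if coeffs is not None else load_coefficients()
    bandset = bandset or BandSet.uav5()
    if len(truth) != layout.n_trees:
        raise SceneError("truth table and layout tree counts differ")

    margin = max(crown.ax, crown.ay) + 0.5
    pos = layout.positions
    extent = (
        pos[:, 0].min() - margin,
        pos[:, 1].min() - margin,
        pos[:, 0].max() + margin,
        pos[:, 1].max() + margin,
    )
    density = crown.density_for_lai(truth["lai"].to_numpy(float))
    scene = OrchardScene(
        positions=pos,
        crown=crown,
        leaf_area_density=density,
        extent=extent,
    )

    sun = sun_position(SITE_LATITUDE, SITE_LONGITUDE, site_time(time))
    img = render_four_component(
        scene, sun, resolution=resolution, supersample=supersample, seed=seed
    )

    counts = np.bincount(img.crown_id.ravel(), minlength=layout.n_trees + 1)
    small = np.flatnonzero(counts[1:] < min_crown_pixels) + 1
    if small.size:
        raise SceneError(
            f"trees {small.tolist()} resolve to < {min_crown_pixels} crown pixels; "
            "use a finer resolution"
        )

    # per-tree band leaf optics and recollision gain
    n_trees = layout.n_trees
    rho_t = np.zeros((n_trees + 1, len(bandset)))
    omega_t = np.zeros_like(rho_t)
    for i, lcc in enumerate(truth["lcc"].to_numpy(float), start=1):
        lo = prospect5(LeafBiochem.with_cab(lcc), coeffs)
        rho_t[i] = resample_to_bands(lo.wavelength, lo.reflectance, bandset)
        omega_t[i] = rho_t[i] + resample_to_bands(
            lo.wavelength, lo.transmittance, bandset
        )

    sf = np.zeros(n_trees + 1)
    for t in range(1, n_trees + 1):
        sf[t] = crown_shadow_fraction(img, t)
    p_t = np.clip(mixing.p0 + mixing.p1 * sf, 0.0, mixing.p_max)

    wl_soil, soil_full = load_background_spectrum("soil")
    soil_b = resample_to_bands(wl_soil, soil_full, bandset)

    cid = img.crown_id
    frac = img.pixel_component_fractions()  # (ny, nx, 4)
    rho_pix = rho_t[cid]  # (ny, nx, 5)
    omega_pix = omega_t[cid]
    p_pix = p_t[cid][..., None]
    m_pix = p_pix * omega_pix / (1.0 - p_pix * omega_pix)
    brf = (
        frac[..., 0, None] * rho_pix * (1.0 + m_pix)
        + frac[..., 1, None] * rho_pix * (mixing.skyl + m_pix)
        + frac[..., 2, None] * soil_b[None, None, :]
        + frac[..., 3, None] * mixing.skyl * soil_b[None, None, :]
    )

    if noise_std > 0:
        rng = np.random.default_rng(seed + 1)
        brf = brf + rng.normal(0.0, noise_std, size=brf.shape)
    brf = np.clip(brf, 0.0, 1.0)

    truth = truth.copy()
    truth["x"] = pos[:, 0]
    truth["y"] = pos[:, 1]
    return SyntheticSurvey(
        bands=np.moveaxis(brf, -1, 0),
        crown_id=cid.astype(np.uint32),
        four_component=img,
        truth=truth,
        time=time,
        resolution=resolution,
        noise_std=noise_std,
        shadow_fraction=pd.Series(sf[1:], index=truth["tree_id"].to_numpy()),
    )


def extract_crown_reflectance(
    survey: SyntheticSurvey, masked: bool = False
) -> pd.DataFrame:
    """Per-tree mean band reflectance over crown pixels.

    ``masked=True`` keeps only sunlit-leaf pixels (shadow-masking
    comparison mode); the default averages every crown pixel, sunlit and
    shaded alike.  Trees whose mask is empty get NaN rows and an ``error``
    note instead of aborting the extraction.
    """
    cid = survey.crown_id
    labels = survey.four_component.labels
    n_trees = int(survey.truth["tree_id"].max())
    rows = []
    for t in range(1, n_trees + 1):
        mask = cid == t
        if masked:
            mask = mask & (labels == SUNLIT_LEAF)
        note = ""
        if not np.any(mask):
            vals = [np.nan] * len(BAND_NAMES)
            note = "empty crown mask"
        else:
            vals = [float(survey.bands[i][mask].mean()) for i in range(len(BAND_NAMES))]
        rows.append([t, *vals, note])
    return pd.DataFrame(rows, columns=["tree_id", *BAND_NAMES, "error"])
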