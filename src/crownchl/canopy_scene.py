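"""Row-structured orchard scene: four-component rendering and canopy spectra.

The scene holds ellipsoidal crowns with homogeneous leaf area density on a
flat soil plane.  Foliage attenuates rays by Beer's law with a spherical
leaf-angle distribution (G = 0.5).  A nadir orthographic camera casts
supersampled view rays; each subray is classified leaf/ground by stochastic
interception along its path, then sunlit/shaded by the gap transmission of a
second ray toward the sun (transmission >= 0.5 marks sunlit).  Pixel labels
follow the majority rule with sunlit-leaf pixels requiring a sunlit-leaf
proportion factor >= 50%.

Crown-level reflectance spectra are synthesised from the four component
area fractions with a spectral-invariant multiple-scattering gain driven by
a recollision probability that grows with the crown shadow fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from importlib import resources

import numpy as np
import pandas as pd

from .leaf_rtm import (
    DEFAULT_CXC_RATIO,
    AbsorptionCoefficients,
    LeafBiochem,
    LeafOptics,
    ParameterError,
    load_coefficients,
    prospect5,
)
from .solar import SolarGeometry, sun_position

__all__ = [
    "CrownShape",
    "OrchardScene",
    "FourComponentImage",
    "CanopySample",
    "MixingParams",
    "ParameterGrid",
    "FescEstimate",
    "sun_position",
    "SolarGeometry",
    "render_four_component",
    "crown_shadow_fraction",
    "estimate_fesc",
    "synthesize_canopy_brf",
    "build_lut",
    "load_background_spectrum",
    "SITE_LATITUDE",
    "SITE_LONGITUDE",
    "SITE_TIMEZONE_HOURS",
    "ACQUISITION_DATE",
]

# default site and acquisition date for all simulations
SITE_LATITUDE = 40.154
SITE_LONGITUDE = 116.133
SITE_TIMEZONE_HOURS = 8
ACQUISITION_DATE = (2021, 8, 31)

# pixel label codes
SUNLIT_LEAF = 1
SHADED_LEAF = 2
SUNLIT_GROUND = 3
SHADED_GROUND = 4

_LN2 = float(np.log(2.0))


class SceneError(ValueError):
    pass


def site_time(hour: float, date=ACQUISITION_DATE) -> datetime:
    """Local timestamp (UTC+8) for a decimal hour on the acquisition date."""
    tz = timezone(timedelta(hours=SITE_TIMEZONE_HOURS))
    h = int(hour)
    m = int(round((hour - h) * 60))
    return datetime(*date, h, m, tzinfo=tz)


def load_background_spectrum(which: str = "soil") -> tuple[np.ndarray, np.ndarray]:
    """Packaged soil or bark reflectance on the 400-2500 nm grid."""
    fname = {"soil": "soil_reflectance.csv", "bark": "bark_reflectance.csv"}[which]
    ref = resources.files("crownchl.data").joinpath(fname)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df["wavelength_nm"].to_numpy(float), df["reflectance"].to_numpy(float)


@dataclass(frozen=True)
class CrownShape:
    """Ellipsoid crown: semi-axes (m) and height of the crown base (m)."""

    ax: float = 1.5
    ay: float = 1.5
    az: float = 1.2
    base_height: float = 0.8

    def __post_init__(self):
        for name in ("ax", "ay", "az"):
            if getattr(self, name) <= 0:
                raise SceneError(f"crown semi-axis {name} must be > 0")
        if self.base_height < 0:
            raise SceneError("crown base height must be >= 0")

    @property
    def center_z(self) -> float:
        return self.base_height + self.az

    @property
    def top(self) -> float:
        return self.base_height + 2.0 * self.az

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.ax * self.ay * self.az

    @property
    def projected_area(self) -> float:
        return np.pi * self.ax * self.ay

    def density_for_lai(self, lai: float) -> float:
        """Leaf area density (m^2/m^3) giving tree LAI over the crown footprint."""
        return lai * self.projected_area / self.volume


@dataclass
class OrchardScene:
    """Tree positions, shared crown shape, foliage density and optics."""

    positions: np.ndarray  # (n_trees, 2) crown centres, m
    crown: CrownShape
    leaf_area_density: np.ndarray  # (n_trees,) m^2/m^3
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    g_function: float = 0.5
    component_optics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.leaf_area_density = np.broadcast_to(
            np.asarray(self.leaf_area_density, float), (self.n_trees,)
        ).copy()
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise SceneError("scene extent must have positive area")
        if np.any(self.leaf_area_density < 0):
            raise SceneError("leaf area density must be >= 0")
        c = self.crown
        inx = (self.positions[:, 0] >= xmin + 0) & (self.positions[:, 0] <= xmax)
        iny = (self.positions[:, 1] >= ymin) & (self.positions[:, 1] <= ymax)
        if not np.all(inx & iny):
            raise SceneError("all crown centres must lie within the extent")

    @property
    def n_trees(self) -> int:
        return self.positions.shape[0]

    @property
    def ground_area(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)

    @property
    def lai_scene(self) -> float:
        """Scene LAI = total leaf area / ground area."""
        leaf_area = float(np.sum(self.leaf_area_density) * self.crown.volume)
        return leaf_area / self.ground_area

    @classmethod
    def grid(
        cls,
        rows: int = 3,
        trees_per_row: int = 3,
        row_spacing: float = 4.0,
        tree_spacing: float = 2.5,
        crown: CrownShape | None = None,
        lai: float = 3.0,
        margin: float | None = None,
        **kwargs,
    ) -> "OrchardScene":
        """Regular row-structured orchard (rows run west-east along x)."""
        if rows < 1 or trees_per_row < 1:
            raise SceneError("rows and trees_per_row must be >= 1")
        crown = crown or CrownShape()
        if margin is None:
            margin = max(crown.ax, crown.ay)
        xs = np.arange(trees_per_row) * tree_spacing
        ys = np.arange(rows) * row_spacing
        pos = np.array([(x, y) for y in ys for x in xs], float)
        pos -= pos.mean(axis=0)
        extent = (
            pos[:, 0].min() - margin,
            pos[:, 1].min() - margin,
            pos[:, 0].max() + margin,
            pos[:, 1].max() + margin,
        )
        density = crown.density_for_lai(lai)
        return cls(
            positions=pos,
            crown=crown,
            leaf_area_density=np.full(len(pos), density),
            extent=extent,
            **kwargs,
        )

    def with_lai(self, lai: float | np.ndarray) -> "OrchardScene":
        density = self.crown.density_for_lai(np.asarray(lai, float))
        density = np.broadcast_to(density, (self.n_trees,))
        return replace(self, leaf_area_density=density.copy())

    def central_tree(self) -> int:
        """Index of the tree closest to the scene centroid."""
        centroid = self.positions.mean(axis=0)
        return int(np.argmin(np.hypot(*(self.positions - centroid).T)))


@dataclass
class FourComponentImage:
    """Nadir component classification raster with per-pixel proportion factors."""

    resolution: float
    labels: np.ndarray  # (ny, nx) uint8 codes
    sunlit_leaf_fraction: np.ndarray  # (ny, nx) in [0,1]; 0 on pure-ground pixels
    crown_id: np.ndarray  # (ny, nx) int32, 0 = background
    leaf_fraction: np.ndarray  # (ny, nx) subray share that hit foliage
    ground_sunlit_fraction: np.ndarray  # share of ground subrays that are sunlit
    extent: tuple[float, float, float, float]

    @property
    def shape(self):
        return self.labels.shape

    def component_fractions(self, mask: np.ndarray | None = None):
        """Mean (f_sunlit_leaf, f_shaded_leaf, f_sunlit_ground, f_shaded_ground).

        Averaged over the selected pixels (all pixels when mask is None);
        the four values sum to 1 by construction.
        """
        if mask is None:
            mask = np.ones(self.labels.shape, bool)
        lf = self.leaf_fraction[mask]
        slf = self.sunlit_leaf_fraction[mask]
        gsf = self.ground_sunlit_fraction[mask]
        f_sl = float(np.mean(lf * slf))
        f_sh = float(np.mean(lf * (1.0 - slf)))
        f_sg = float(np.mean((1.0 - lf) * gsf))
        f_shg = float(np.mean((1.0 - lf) * (1.0 - gsf)))
        return f_sl, f_sh, f_sg, f_shg

    def pixel_component_fractions(self):
        """Per-pixel component fraction stack with axis -1 = (sl, sh, sg, shg)."""
        lf = self.leaf_fraction
        slf = self.sunlit_leaf_fraction
        gsf = self.ground_sunlit_fraction
        return np.stack(
            [lf * slf, lf * (1.0 - slf), (1.0 - lf) * gsf, (1.0 - lf) * (1.0 - gsf)],
            axis=-1,
        )


def _sun_vector(sun: SolarGeometry) -> np.ndarray:
    """Unit vector pointing from the surface toward the sun (x=east, y=north)."""
    zen = np.radians(sun.zenith)
    az = np.radians(sun.azimuth)
    return np.array(
        [np.sin(zen) * np.sin(az), np.sin(zen) * np.cos(az), np.cos(zen)]
    )


def _ellipsoid_chord(px, py, pz, direction, center, axes):
    """Forward chord length of rays p + t*dir (t>=0) through one ellipsoid.

    Vectorised over points; direction is a single unit 3-vector.
    """
    ax, ay, az = axes
    qx = (px - center[0]) / ax
    qy = (py - center[1]) / ay
    qz = (pz - center[2]) / az
    vx, vy, vz = direction[0] / ax, direction[1] / ay, direction[2] / az
    a = vx * vx + vy * vy + vz * vz
    b = 2.0 * (qx * vx + qy * vy + qz * vz)
    c = qx * qx + qy * qy + qz * qz - 1.0
    disc = b * b - 4.0 * a * c
    hit = disc > 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    t1 = np.maximum(t1, 0.0)
    length = np.where(hit, np.maximum(t2 - t1, 0.0), 0.0)
    return length


def _sun_optical_depth(scene: OrchardScene, px, py, pz, sun_vec, self_tree=None):
    """Beer's-law optical depth from points toward the sun through all crowns.

    When ``self_tree`` (per-point crown index, -1 for none) is given, the
    contribution of each point's own crown is returned separately so the
    caller can apply a hotspot (sun/view path correlation) discount.
    """
    tau = np.zeros_like(px)
    tau_self = np.zeros_like(px) if self_tree is not None else None
    c = scene.crown
    axes = (c.ax, c.ay, c.az)
    sz = sun_vec[2]
    t_max = c.top / max(sz, 1e-9)  # beyond this height no crown can intersect
    for t, (cx, cy) in enumerate(scene.positions):
        u = scene.leaf_area_density[t]
        if u <= 0:
            continue
        # cheap candidate window: points whose ray can pass near this crown
        lo_x = min(cx - c.ax, cx - c.ax - t_max * sun_vec[0])
        hi_x = max(cx + c.ax, cx + c.ax - t_max * sun_vec[0])
        lo_y = min(cy - c.ay, cy - c.ay - t_max * sun_vec[1])
        hi_y = max(cy + c.ay, cy + c.ay - t_max * sun_vec[1])
        cand = (px >= lo_x) & (px <= hi_x) & (py >= lo_y) & (py <= hi_y)
        if not np.any(cand):
            continue
        length = _ellipsoid_chord(
            px[cand], py[cand], pz[cand], sun_vec, (cx, cy, c.center_z), axes
        )
        contrib = scene.g_function * u * length
        if self_tree is None:
            tau[cand] += contrib
        else:
            own = self_tree[cand] == t
            tau[cand] += np.where(own, 0.0, contrib)
            tau_self[cand] += np.where(own, contrib, 0.0)
    if self_tree is None:
        return tau
    return tau, tau_self


def render_four_component(
    scene: OrchardScene,
    sun: SolarGeometry,
    resolution: float = 0.05,
    supersample: int = 2,
    seed: int = 0,
    hotspot_degrees: float = 10.0,
) -> FourComponentImage:
    """Render the nadir four-component image of a scene.

    Each pixel is sampled with ``supersample**2`` subrays on a regular
    subgrid.  A subray intercepts foliage with the Beer's-law probability of
    its vertical path; intercepted rays scatter at a depth drawn from the
    truncated exponential free-path distribution.  The hit point (foliage or
    ground) is sunlit when the gap transmission toward the sun is >= 0.5.

    The sun path through a foliage point's own crown is discounted by the
    hotspot factor ``1 - exp(-phase/hotspot_degrees)`` (phase = sun zenith
    for a nadir view): with sun and view aligned, photons exit through the
    gaps they entered, so first hits stay sunlit.
    """
    if resolution <= 0:
        raise SceneError("resolution must be > 0")
    if supersample < 1:
        raise SceneError("supersample must be >= 1")
    sun.require_daytime()
    if sun.zenith >= 89.0:
        raise SceneError("sun too close to the horizon for a meaningful render")

    xmin, ymin, xmax, ymax = scene.extent
    nx = max(1, int(round((xmax - xmin) / resolution)))
    ny = max(1, int(round((ymax - ymin) / resolution)))
    ss = supersample

    # subray coordinates: regular subgrid inside each pixel (north-up rows)
    off = (np.arange(ss) + 0.5) / ss
    px_edges = xmin + np.arange(nx)[:, None] * resolution + off[None, :] * resolution
    py_edges = ymax - (np.arange(ny)[:, None] * resolution + off[None, :] * resolution)
    sx = px_edges.reshape(-1)  # nx*ss
    sy = py_edges.reshape(-1)  # ny*ss
    PX, PY = np.meshgrid(sx, sy)  # (ny*ss, nx*ss)
    px = PX.ravel()
    py = PY.ravel()
    npts = px.size

    crown = scene.crown
    rng = np.random.default_rng(seed)

    # vertical interception through all crowns
    tau_view = np.zeros(npts)
    top_z = np.full(npts, -np.inf)  # entry height of topmost crown hit
    top_u = np.zeros(npts)
    top_tree = np.full(npts, -1, dtype=np.int64)
    for t, (cx, cy) in enumerate(scene.positions):
        u = scene.leaf_area_density[t]
        if u <= 0:
            continue
        cand = (np.abs(px - cx) <= crown.ax) & (np.abs(py - cy) <= crown.ay)
        if not np.any(cand):
            continue
        d2 = 1.0 - ((px[cand] - cx) / crown.ax) ** 2 - ((py[cand] - cy) / crown.ay) ** 2
        inside = d2 > 0.0
        if not np.any(inside):
            continue
        idx = np.flatnonzero(cand)[inside]
        half = crown.az * np.sqrt(d2[inside])
        tau_view[idx] += scene.g_function * u * 2.0 * half
        ztop = crown.center_z + half
        better = ztop > top_z[idx]
        sel = idx[better]
        top_z[sel] = ztop[better]
        top_u[sel] = u
        top_tree[sel] = t

    p_int = 1.0 - np.exp(-tau_view)
    udraw = rng.random(npts)
    leaf_hit = udraw < p_int

    # scatter depth: truncated exponential along the in-crown path
    hz = np.zeros(npts)
    if np.any(leaf_hit):
        v = udraw[leaf_hit] / p_int[leaf_hit]
        tau_star = -np.log1p(-v * p_int[leaf_hit])
        depth = tau_star / (scene.g_function * np.maximum(top_u[leaf_hit], 1e-12))
        hz[leaf_hit] = np.maximum(top_z[leaf_hit] - depth, crown.base_height)

    # sunlit test at hit points (leaves) and at the ground for the rest
    sun_vec = _sun_vector(sun)
    pz = np.where(leaf_hit, hz, 0.0)
    self_tree = np.where(leaf_hit, top_tree, -1)
    tau_other, tau_self = _sun_optical_depth(
        scene, px, py, pz, sun_vec, self_tree=self_tree
    )
    hotspot = 1.0 - np.exp(-sun.zenith / max(hotspot_degrees, 1e-9))
    tau_sun = tau_other + hotspot * tau_self
    sunlit = tau_sun <= _LN2  # transmission >= 0.5

    # aggregate subrays per pixel
    def tally(values):
        return (
            values.reshape(ny, ss, nx, ss).sum(axis=(1, 3)).astype(float) / (ss * ss)
        )

    leaf_fraction = tally(leaf_hit)
    sl_fraction_abs = tally(leaf_hit & sunlit)
    ground_frac = 1.0 - leaf_fraction
    sg_fraction_abs = tally(~leaf_hit & sunlit)

    with np.errstate(invalid="ignore", divide="ignore"):
        sunlit_leaf_fraction = np.where(
            leaf_fraction > 0, sl_fraction_abs / np.maximum(leaf_fraction, 1e-12), 0.0
        )
        ground_sunlit_fraction = np.where(
            ground_frac > 0, sg_fraction_abs / np.maximum(ground_frac, 1e-12), 0.0
        )

    is_leaf_pixel = leaf_fraction >= 0.5
    labels = np.where(
        is_leaf_pixel,
        np.where(sunlit_leaf_fraction >= 0.5, SUNLIT_LEAF, SHADED_LEAF),
        np.where(ground_sunlit_fraction >= 0.5, SUNLIT_GROUND, SHADED_GROUND),
    ).astype(np.uint8)

    # crown membership by footprint ellipse at crown-equator height
    cx_pix = xmin + (np.arange(nx) + 0.5) * resolution
    cy_pix = ymax - (np.arange(ny) + 0.5) * resolution
    CXP, CYP = np.meshgrid(cx_pix, cy_pix)
    crown_id = np.zeros((ny, nx), np.int32)
    best_d = np.full((ny, nx), np.inf)
    for t, (cx, cy) in enumerate(scene.positions):
        d2 = ((CXP - cx) / crown.ax) ** 2 + ((CYP - cy) / crown.ay) ** 2
        inside = d2 < 1.0
        closer = inside & (d2 < best_d)
        crown_id[closer] = t + 1
        best_d[closer] = d2[closer]

    return FourComponentImage(
        resolution=resolution,
        labels=labels,
        sunlit_leaf_fraction=sunlit_leaf_fraction,
        crown_id=crown_id,
        leaf_fraction=leaf_fraction,
        ground_sunlit_fraction=ground_sunlit_fraction,
        extent=scene.extent,
    )


def crown_shadow_fraction(img: FourComponentImage, tree: int) -> float:
    """Shaded-leaf share of a crown's leaf pixels (tree ids start at 1)."""
    mask = img.crown_id == tree
    lab = img.labels[mask]
    n_sl = int(np.sum(lab == SUNLIT_LEAF))
    n_sh = int(np.sum(lab == SHADED_LEAF))
    if n_sl + n_sh == 0:
        raise SceneError(f"tree {tree} has no leaf pixels")
    return n_sh / (n_sl + n_sh)


@dataclass(frozen=True)
class FescEstimate:
    value: float
    stderr: float
    n_photons: int


def estimate_fesc(
    scene: OrchardScene,
    sun: SolarGeometry,
    omega_nir: float = 0.9,
    n_photons: int = 20000,
    seed: int = 0,
) -> FescEstimate:
    """Monte-Carlo first-order photon escape probability toward nadir.

    Photons enter along the solar beam, are intercepted inside a crown at a
    depth drawn from the free-path distribution, and escape toward the nadir
    sensor with the gap probability of the upward path.  ``omega_nir`` is
    validated as the NIR single-scattering albedo of the foliage but does
    not enter the first-order escape estimate (escape is conditioned on a
    scattering event having occurred).
    """
    if not 0.0 < omega_nir < 1.0:
        raise ParameterError("omega_nir must be in (0, 1)")
    if n_photons < 1000:
        raise ParameterError("n_photons must be >= 1e3")
    sun.require_daytime()

    rng = np.random.default_rng(seed)
    crown = scene.crown
    axes = np.array([crown.ax, crown.ay, crown.az])
    sun_vec = _sun_vector(sun)
    w = -sun_vec  # photon travel direction

    # choose target crowns uniformly (identical projected areas)
    tree_idx = rng.integers(0, scene.n_trees, n_photons)
    u_tree = scene.leaf_area_density[tree_idx]

    # impact parameter on the projected unit disk (sphere space)
    vsph = w / axes
    vnorm = np.linalg.norm(vsph)
    vs = vsph / vnorm
    # orthonormal basis perpendicular to vs
    helper = np.array([1.0, 0.0, 0.0])
    if abs(vs[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    b1 = np.cross(vs, helper)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(vs, b1)

    r = np.sqrt(rng.random(n_photons))
    phi = rng.random(n_photons) * 2.0 * np.pi
    q0 = (
        r[:, None] * np.cos(phi)[:, None] * b1[None, :]
        + r[:, None] * np.sin(phi)[:, None] * b2[None, :]
    )
    half = np.sqrt(np.maximum(1.0 - r**2, 0.0))
    q_in = q0 - half[:, None] * vs[None, :]
    chord = 2.0 * half / vnorm  # real-space chord length

    centers = np.column_stack(
        [
            scene.positions[tree_idx, 0],
            scene.positions[tree_idx, 1],
            np.full(n_photons, crown.center_z),
        ]
    )
    p_entry = centers + q_in * axes[None, :]

    tau_chord = scene.g_function * u_tree * chord
    p_int = 1.0 - np.exp(-tau_chord)

    # scattering point conditional on interception
    v = rng.random(n_photons)
    tau_star = -np.log1p(-v * p_int)
    dist = np.where(
        tau_chord > 0, tau_star / np.maximum(scene.g_function * u_tree, 1e-12), 0.0
    )
    p_scat = p_entry + dist[:, None] * w[None, :]

    # upward escape through all crowns
    up = np.array([0.0, 0.0, 1.0])
    tau_up = _sun_optical_depth(
        scene, p_scat[:, 0], p_scat[:, 1], p_scat[:, 2], up
    )
    esc = np.exp(-tau_up)

    weights = p_int
    wsum = float(np.sum(weights))
    if wsum <= 0:
        return FescEstimate(value=1.0, stderr=0.0, n_photons=n_photons)
    value = float(np.sum(weights * esc) / wsum)
    var = float(np.sum(weights * (esc - value) ** 2) / wsum)
    neff = wsum**2 / float(np.sum(weights**2))
    stderr = float(np.sqrt(var / max(neff, 1.0)))
    return FescEstimate(value=value, stderr=stderr, n_photons=n_photons)


@dataclass(frozen=True)
class MixingParams:
    """Spectral mixing defaults (diffuse skylight share, recollision law)."""

    skyl: float = 0.35
    p0: float = 0.45
    p1: float = 0.30
    p_max: float = 0.95

    def recollision(self, shadow_fraction: float) -> float:
        return float(np.clip(self.p0 + self.p1 * shadow_fraction, 0.0, self.p_max))


def synthesize_canopy_brf(
    fractions,
    leaf,
    soil,
    sun: SolarGeometry | None = None,
    shadow_fraction: float = 0.0,
    mixing: MixingParams | None = None,
):
    """Mix four-component spectra into a crown reflectance factor.

    BRF = f_sl*rho_leaf*(1+M) + f_sh*rho_leaf*(skyl+M)
        + f_sg*rho_soil + f_shg*skyl*rho_soil

    with multiple-scattering gain M = p*omega/(1 - p*omega),
    omega = rho_leaf + tau_leaf, and recollision probability
    p = clip(p0 + p1*shadow_fraction, 0, p_max).

    Parameters
    ----------
    fractions : sequence of 4 floats summing to 1
        (sunlit leaf, shaded leaf, sunlit ground, shaded ground).
    leaf : LeafOptics or (rho, omega) arrays
    soil : ndarray
        Soil reflectance on the same spectral grid.
    """
    f = np.asarray(fractions, float)
    if f.shape[-1] != 4:
        raise SceneError("fractions must have 4 components")
    if not np.allclose(f.sum(axis=-1), 1.0, atol=1e-9):
        raise SceneError("component fractions must sum to 1")
    mixing = mixing or MixingParams()

    if isinstance(leaf, LeafOptics):
        rho = leaf.reflectance
        omega = leaf.albedo
    else:
        rho, omega = leaf
        rho = np.asarray(rho, float)
        omega = np.asarray(omega, float)
    soil = np.asarray(soil, float)

    p = mixing.recollision(shadow_fraction)
    m = p * omega / (1.0 - p * omega)
    brf = (
        f[..., 0, None] * rho * (1.0 + m)
        + f[..., 1, None] * rho * (mixing.skyl + m)
        + f[..., 2, None] * soil
        + f[..., 3, None] * mixing.skyl * soil
    )
    return np.clip(np.squeeze(brf), 0.0, 1.0)


@dataclass(frozen=True)
class ParameterGrid:
    """Full-factorial leaf/canopy parameter ladders for LUT generation."""

    n_struct: np.ndarray
    cab: np.ndarray
    cw: np.ndarray
    lai: np.ndarray
    cm: float = 0.01
    cbrown: float = 0.0
    cxc_ratio: float = DEFAULT_CXC_RATIO

    def __post_init__(self):
        for name in ("n_struct", "cab", "cw", "lai"):
            arr = np.asarray(getattr(self, name), float)
            if arr.size == 0:
                raise SceneError(f"parameter ladder {name} is empty")
            object.__setattr__(self, name, arr)

    @classmethod
    def from_counts(cls, counts=(8, 70, 4, 9), **kwargs) -> "ParameterGrid":
        """Uniformly spaced ladders over the standard ranges.

        counts = (levels of N in [1,3], Cab in [20,70] ug/cm^2,
                  Cw in [0.01,0.03] cm, LAI in [0.5,7]).
        """
        cn, ccab, ccw, clai = counts

        def ladder(lo, hi, k):
            return np.array([0.5 * (lo + hi)]) if k == 1 else np.linspace(lo, hi, k)

        return cls(
            n_struct=ladder(1.0, 3.0, cn),
            cab=ladder(20.0, 70.0, ccab),
            cw=ladder(0.01, 0.03, ccw),
            lai=ladder(0.5, 7.0, clai),
            **kwargs,
        )

    @property
    def per_time_count(self) -> int:
        return self.n_struct.size * self.cab.size * self.cw.size * self.lai.size

    def biochem_rows(self):
        """Cartesian product over the leaf ladders (N, cab, cw)."""
        for n, cab, cw in itertools.product(self.n_struct, self.cab, self.cw):
            yield LeafBiochem(
                n_struct=float(n),
                cab=float(cab),
                cxc=self.cxc_ratio * float(cab),
                cbrown=self.cbrown,
                cw=float(cw),
                cm=self.cm,
            )


@dataclass(frozen=True)
class CanopySample:
    """One simulated crown observation (used for single-sample workflows)."""

    time: float
    sza: float
    saa: float
    shadow_fraction: float
    fesc: float
    brf: np.ndarray
    truth: LeafBiochem
    lai: float


DEFAULT_TIMES = tuple(range(9, 17))  # 9:00 .. 16:00 local


def build_lut(
    grid: ParameterGrid | None = None,
    times=DEFAULT_TIMES,
    scene: OrchardScene | None = None,
    seed: int = 0,
    coeffs: AbsorptionCoefficients | None = None,
    mixing: MixingParams | None = None,
    bandset=None,
    resolution: float = 0.06,
    supersample: int = 2,
    fesc_photons: int = 5000,
    noise_std: float = 0.01,
    date=ACQUISITION_DATE,
) -> pd.DataFrame:
    """Simulate the canopy-spectra lookup table.

    For each acquisition time, the full Cartesian product of the parameter
    ladders is simulated: the crown shadow fraction, component fractions and
    fesc are rendered once per (time, LAI) and shared across the leaf
    biochemistries; leaf spectra come from the plate model and are mixed
    into crown reflectance, reported in the 5 sensor bands.  Additive
    Gaussian sensor noise (``noise_std``, seeded) emulates the radiometric
    noise of the emulated sensor; pass 0 for noiseless spectra.

    Returns a DataFrame with one row per sample.
    """
    from .spectral_indices import BandSet, resample_to_bands  # lazy: avoid cycle

    grid = grid or ParameterGrid.from_counts()
    scene = scene or OrchardScene.grid()
    coeffs = coeffs or load_coefficients()
    mixing = mixing or MixingParams()
    bandset = bandset or BandSet.uav5()

    wl_soil, soil_full = load_background_spectrum("soil")
    if wl_soil.shape != coeffs.wavelength.shape or not np.allclose(
        wl_soil, coeffs.wavelength
    ):
        soil_full = np.interp(coeffs.wavelength, wl_soil, soil_full)
    soil_b = resample_to_bands(coeffs.wavelength, soil_full, bandset)

    # leaf optics for every biochemistry, resampled to sensor bands
    biochems = list(grid.biochem_rows())
    rho_b = np.empty((len(biochems), len(bandset.bands)))
    omega_b = np.empty_like(rho_b)
    for i, bc in enumerate(biochems):
        lo = prospect5(bc, coeffs)
        rho_b[i] = resample_to_bands(lo.wavelength, lo.reflectance, bandset)
        omega_b[i] = rho_b[i] + resample_to_bands(
            lo.wavelength, lo.transmittance, bandset
        )

    nb = len(biochems)
    nl = grid.lai.size
    band_names = [b.name for b in bandset.bands]
    blocks = []
    rng = np.random.default_rng(seed)
    # common random numbers: one render seed per LAI level, shared across
    # times, so diurnal contrasts are not blurred by interception noise
    lai_seeds = {float(lai): int(rng.integers(0, 2**31 - 1)) for lai in grid.lai}
    for time in times:
        sun = sun_position(SITE_LATITUDE, SITE_LONGITUDE, site_time(time, date))
        sun.require_daytime()
        for lai in grid.lai:
            sub_seed = lai_seeds[float(lai)]
            sc = scene.with_lai(float(lai))
            img = render_four_component(
                sc, sun, resolution=resolution, supersample=supersample, seed=sub_seed
            )
            tree = sc.central_tree() + 1
            sf = crown_shadow_fraction(img, tree)
            fr = img.component_fractions(img.crown_id == tree)
            fesc = estimate_fesc(
                sc, sun, n_photons=fesc_photons, seed=sub_seed
            ).value

            p = mixing.recollision(sf)
            m = p * omega_b / (1.0 - p * omega_b)  # (nb, nbands)
            brf = (
                fr[0] * rho_b * (1.0 + m)
                + fr[1] * rho_b * (mixing.skyl + m)
                + fr[2] * soil_b[None, :]
                + fr[3] * mixing.skyl * soil_b[None, :]
            )
            if noise_std > 0:
                brf = brf + rng.normal(0.0, noise_std, size=brf.shape)
            brf = np.clip(brf, 0.0, 1.0)

            block = pd.DataFrame(brf, columns=band_names)
            block.insert(0, "time", float(time))
            block.insert(1, "sza", sun.zenith)
            block.insert(2, "saa", sun.azimuth)
            block.insert(3, "shadow_fraction", sf)
            block.insert(4, "fesc", fesc)
            block.insert(5, "n_struct", [bc.n_struct for bc in biochems])
            block.insert(6, "cab", [bc.cab for bc in biochems])
            block.insert(7, "cxc", [bc.cxc for bc in biochems])
            block.insert(8, "cw", [bc.cw for bc in biochems])
            block.insert(9, "cm", [bc.cm for bc in biochems])
            block.insert(10, "lai", float(lai))
            blocks.append(block)

    lut = pd.concat(blocks, ignore_index=True)
    expected = grid.per_time_count * len(times)
    assert len(lut) == expected, (len(lut), expected)
    return lut
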