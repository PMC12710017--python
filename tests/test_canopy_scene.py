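"""Scene geometry, four-component rendering, fesc and mixing tests."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from crownchl.canopy_scene import (
    SHADED_GROUND,
    SHADED_LEAF,
    SUNLIT_GROUND,
    SUNLIT_LEAF,
    CrownShape,
    FourComponentImage,
    MixingParams,
    OrchardScene,
    ParameterGrid,
    SceneError,
    SITE_LATITUDE,
    SITE_LONGITUDE,
    SolarGeometry,
    build_lut,
    crown_shadow_fraction,
    estimate_fesc,
    load_background_spectrum,
    render_four_component,
    site_time,
    sun_position,
    synthesize_canopy_brf,
)
from crownchl.leaf_rtm import LeafBiochem, prospect5
from crownchl.spectral_indices import BandSet, resample_to_bands

TZ8 = timezone(timedelta(hours=8))


def fake_sun(zenith, azimuth=180.0):
    return SolarGeometry(
        local_datetime=datetime(2021, 8, 31, 12, 0, tzinfo=TZ8),
        latitude=SITE_LATITUDE,
        longitude=SITE_LONGITUDE,
        zenith=zenith,
        azimuth=azimuth,
    )


def single_crown_scene(lai=50.0, crown=None, extent_half=6.0):
    crown = crown or CrownShape()
    return OrchardScene(
        positions=np.array([[0.0, 0.0]]),
        crown=crown,
        leaf_area_density=crown.density_for_lai(lai),
        extent=(-extent_half, -extent_half, extent_half, extent_half),
    )


# ------------------------------------------------------------------- scene


def test_scene_lai_consistency():
    scene = OrchardScene.grid(rows=2, trees_per_row=3, lai=3.0)
    expected = (
        scene.leaf_area_density.sum() * scene.crown.volume / scene.ground_area
    )
    assert scene.lai_scene == pytest.approx(expected, abs=1e-6)


def test_density_for_lai_roundtrip():
    crown = CrownShape(ax=1.2, ay=1.0, az=0.9, base_height=0.5)
    u = crown.density_for_lai(4.0)
    # tree leaf area / footprint area returns the LAI
    assert u * crown.volume / crown.projected_area == pytest.approx(4.0)


def test_scene_rejects_bad_geometry():
    with pytest.raises(SceneError):
        CrownShape(ax=-1.0)
    with pytest.raises(SceneError):
        OrchardScene(
            positions=[[0.0, 0.0]],
            crown=CrownShape(),
            leaf_area_density=1.0,
            extent=(0.0, 0.0, 0.0, 1.0),
        )
    with pytest.raises(SceneError):
        OrchardScene.grid(rows=0)


# ---------------------------------------------------------------- rendering


def test_nadir_sun_gives_no_shaded_leaf():
    scene = single_crown_scene(lai=60.0)  # effectively opaque
    img = render_four_component(scene, fake_sun(0.5), resolution=0.05, seed=1)
    crown_labels = img.labels[img.crown_id == 1]
    assert np.sum(crown_labels == SHADED_LEAF) == 0
    assert np.sum(crown_labels == SUNLIT_LEAF) > 0


def test_sphere_shadow_matches_projected_ellipse():
    r = 0.8
    crown = CrownShape(ax=r, ay=r, az=r, base_height=2.0)
    scene = single_crown_scene(lai=200.0, crown=crown, extent_half=7.0)
    img = render_four_component(scene, fake_sun(45.0), resolution=0.01, seed=0)
    shadow_px = int(np.sum(img.labels == SHADED_GROUND))
    shadow_area = shadow_px * img.resolution**2
    expected = np.pi * r**2 / np.cos(np.radians(45.0))
    assert shadow_area == pytest.approx(expected, rel=0.05)


def test_component_fractions_sum_to_one():
    scene = OrchardScene.grid(rows=2, trees_per_row=2, lai=2.0)
    img = render_four_component(scene, fake_sun(40.0), resolution=0.05, seed=3)
    assert sum(img.component_fractions()) == pytest.approx(1.0, abs=1e-12)
    window = np.zeros(img.shape, bool)
    window[: img.shape[0] // 2, : img.shape[1] // 3] = True
    assert sum(img.component_fractions(window)) == pytest.approx(1.0, abs=1e-12)
    pix = img.pixel_component_fractions()
    np.testing.assert_allclose(pix.sum(axis=-1), 1.0, atol=1e-12)


def test_sunlit_leaf_label_consistent_with_fraction():
    scene = OrchardScene.grid(rows=2, trees_per_row=2, lai=3.0)
    img = render_four_component(scene, fake_sun(50.0), resolution=0.05, seed=4)
    leaf_px = img.leaf_fraction >= 0.5
    sl = img.labels == SUNLIT_LEAF
    assert np.all(img.sunlit_leaf_fraction[sl] >= 0.5)
    assert np.all(img.sunlit_leaf_fraction[leaf_px & ~sl] < 0.5)


def test_render_rejects_bad_inputs(small_scene):
    with pytest.raises(SceneError):
        render_four_component(small_scene, fake_sun(30.0), resolution=-1.0)
    with pytest.raises(SceneError):
        render_four_component(small_scene, fake_sun(89.5), resolution=0.1)
    with pytest.raises(SceneError):
        render_four_component(small_scene, fake_sun(30.0), resolution=0.1, supersample=0)


# -------------------------------------------------------- shadow fraction


def synthetic_image(labels, crown_id):
    labels = np.asarray(labels, np.uint8)
    shape = labels.shape
    return FourComponentImage(
        resolution=0.05,
        labels=labels,
        sunlit_leaf_fraction=(labels == SUNLIT_LEAF).astype(float),
        crown_id=np.asarray(crown_id, np.int32),
        leaf_fraction=((labels == SUNLIT_LEAF) | (labels == SHADED_LEAF)).astype(float),
        ground_sunlit_fraction=np.zeros(shape),
        extent=(0, 0, shape[1] * 0.05, shape[0] * 0.05),
    )


def test_shadow_fraction_trivial_cases():
    all_sun = synthetic_image([[SUNLIT_LEAF] * 3] * 3, np.ones((3, 3)))
    assert crown_shadow_fraction(all_sun, 1) == 0.0
    all_shade = synthetic_image([[SHADED_LEAF] * 3] * 3, np.ones((3, 3)))
    assert crown_shadow_fraction(all_shade, 1) == 1.0
    no_leaf = synthetic_image([[SUNLIT_GROUND] * 3] * 3, np.ones((3, 3)))
    with pytest.raises(SceneError):
        crown_shadow_fraction(no_leaf, 1)


@pytest.fixture(scope="module")
def diurnal_series(small_scene):
    sf, fe = {}, {}
    for h in range(9, 17):
        sun = sun_position(SITE_LATITUDE, SITE_LONGITUDE, site_time(h))
        img = render_four_component(small_scene, sun, resolution=0.05, seed=1)
        tree = small_scene.central_tree() + 1
        sf[h] = crown_shadow_fraction(img, tree)
        fe[h] = estimate_fesc(small_scene, sun, n_photons=20000, seed=1).value
    return pd.Series(sf), pd.Series(fe)


def test_shadow_fraction_parabolic_minimum_at_noon(diurnal_series):
    sf, _ = diurnal_series
    assert sf.idxmin() == 12
    assert sf[9] > sf[12]
    # unimodal: decreasing to noon, increasing after
    assert np.all(np.diff(sf[sf.index <= 12]) < 0)
    assert np.all(np.diff(sf[sf.index >= 12]) > 0)


def test_fesc_unimodal_maximum_at_noon(diurnal_series):
    _, fe = diurnal_series
    assert fe.idxmax() == 12
    assert np.all(np.diff(fe[fe.index <= 12]) > 0)
    assert np.all(np.diff(fe[fe.index >= 12]) < 0)


# ----------------------------------------------------------------- fesc MC


def test_fesc_limit_without_foliage():
    crown = CrownShape()
    scene = OrchardScene(
        positions=[[0.0, 0.0]],
        crown=crown,
        leaf_area_density=1e-6,
        extent=(-4, -4, 4, 4),
    )
    est = estimate_fesc(scene, fake_sun(35.0), n_photons=5000, seed=2)
    assert est.value == pytest.approx(1.0, abs=3 * est.stderr + 1e-4)


def test_fesc_decreasing_in_density():
    vals = []
    for lai in (1.0, 3.0, 6.0):
        scene = single_crown_scene(lai=lai)
        vals.append(estimate_fesc(scene, fake_sun(35.0), n_photons=20000, seed=5).value)
    assert vals[0] > vals[1] > vals[2]


def test_fesc_convergence_across_budgets(small_scene):
    sun = fake_sun(35.0)
    lo = estimate_fesc(small_scene, sun, n_photons=20000, seed=1)
    hi = estimate_fesc(small_scene, sun, n_photons=100000, seed=2)
    combined = np.hypot(lo.stderr, hi.stderr)
    assert abs(lo.value - hi.value) <= 3 * combined


def test_fesc_rejects_bad_parameters(small_scene):
    with pytest.raises(Exception):
        estimate_fesc(small_scene, fake_sun(35.0), omega_nir=1.5)
    with pytest.raises(Exception):
        estimate_fesc(small_scene, fake_sun(35.0), n_photons=10)


# ----------------------------------------------------------------- mixing


def test_pure_sunlit_leaf_returns_leaf_reflectance(coeffs):
    lo = prospect5(LeafBiochem(), coeffs)
    soil = np.full_like(lo.reflectance, 0.2)
    mix = MixingParams(p0=0.0, p1=0.0)
    brf = synthesize_canopy_brf([1, 0, 0, 0], lo, soil, shadow_fraction=0.3, mixing=mix)
    np.testing.assert_allclose(brf, lo.reflectance, atol=1e-12)


def test_zero_albedo_kills_multiple_scattering():
    rho = np.full(10, 0.3)
    omega = np.zeros(10)
    soil = np.full(10, 0.15)
    mix = MixingParams(skyl=0.2, p0=0.6, p1=0.3)
    brf = synthesize_canopy_brf(
        [0.5, 0.5, 0.0, 0.0], (rho, omega), soil, shadow_fraction=0.5, mixing=mix
    )
    expected = 0.5 * rho + 0.5 * rho * mix.skyl
    np.testing.assert_allclose(brf, expected, atol=1e-12)


def test_fraction_sum_enforced():
    with pytest.raises(SceneError):
        synthesize_canopy_brf([0.5, 0.2, 0.2, 0.2], (np.ones(3) * 0.3, np.ones(3) * 0.6), np.ones(3) * 0.1)


def test_red_decreases_nir_increases_with_shadow(coeffs):
    lo = prospect5(LeafBiochem.with_cab(45.0), coeffs)
    bs = BandSet.uav5()
    rho = resample_to_bands(lo.wavelength, lo.reflectance, bs)
    omega = rho + resample_to_bands(lo.wavelength, lo.transmittance, bs)
    wl_s, soil = load_background_spectrum("soil")
    soil_b = resample_to_bands(wl_s, soil, bs)
    red, nir = [], []
    for sf in np.linspace(0.0, 0.6, 13):
        brf = synthesize_canopy_brf(
            [1 - sf, sf, 0, 0], (rho, omega), soil_b, shadow_fraction=sf
        )
        red.append(brf[2])
        nir.append(brf[4])
    assert np.all(np.diff(red) < 0)
    assert np.all(np.diff(nir) > 0)


def test_recollision_probability_clamped():
    mix = MixingParams(p0=0.9, p1=0.5)
    assert mix.recollision(0.9) == mix.p_max


# -------------------------------------------------------------------- LUT


def test_lut_trivial_grid_counts(small_scene):
    grid = ParameterGrid.from_counts((1, 1, 1, 1))
    lut = build_lut(grid, times=(11, 12), scene=small_scene, seed=0, fesc_photons=1000)
    assert len(lut) == 2
    grid2 = ParameterGrid.from_counts((2, 3, 1, 2))
    lut2 = build_lut(grid2, times=(12,), scene=small_scene, seed=0, fesc_photons=1000)
    assert len(lut2) == 12


def test_lut_shadow_shared_across_biochemistry(small_scene):
    grid = ParameterGrid.from_counts((2, 2, 1, 2))
    lut = build_lut(grid, times=(12,), scene=small_scene, seed=0, fesc_photons=1000)
    for (_, _), sub in lut.groupby(["time", "lai"]):
        assert sub["shadow_fraction"].nunique() == 1
        assert sub["fesc"].nunique() == 1


def test_lut_reflectance_bounded(reduced_lut):
    bands = reduced_lut[["BLUE", "GREEN", "RED", "REDEDGE", "NIR"]].to_numpy()
    assert np.all(bands >= 0.0) and np.all(bands <= 1.0)


def test_lut_truth_within_grid_ranges(reduced_lut):
    assert reduced_lut["cab"].between(20, 70).all()
    assert reduced_lut["lai"].between(0.5, 7).all()
    assert reduced_lut["n_struct"].between(1, 3).all()
    np.testing.assert_allclose(
        reduced_lut["cxc"], reduced_lut["cab"] * 0.25, rtol=1e-12
    )


def test_lut_empty_grid_rejected():
    with pytest.raises(SceneError):
        ParameterGrid(n_struct=np.array([]), cab=np.array([40.0]), cw=np.array([0.01]), lai=np.array([3.0]))


def test_visible_max_and_nir_min_at_noon(diurnal_series, coeffs):
    """Fixed biochemistry: crown visible BRF peaks and NIR dips at 12:00.

    Evaluated over the crown's leaf components (the four-component analysis
    assumes no soil inside the canopy): f_sunlit + f_shaded = 1.
    """
    sf, _ = diurnal_series
    lo = prospect5(LeafBiochem.with_cab(50.0), coeffs)
    bs = BandSet.uav5()
    rho = resample_to_bands(lo.wavelength, lo.reflectance, bs)
    omega = rho + resample_to_bands(lo.wavelength, lo.transmittance, bs)
    wl_s, soil = load_background_spectrum("soil")
    soil_b = resample_to_bands(wl_s, soil, bs)
    brf = pd.DataFrame(
        {
            h: synthesize_canopy_brf(
                [1 - s, s, 0, 0], (rho, omega), soil_b, shadow_fraction=s
            )
            for h, s in sf.items()
        },
        index=["BLUE", "GREEN", "RED", "REDEDGE", "NIR"],
    ).T
    for band in ("BLUE", "GREEN", "RED"):
        assert brf[band].idxmax() == 12
        assert (brf.loc[12, band] >= brf[band]).all()
    assert brf["NIR"].idxmin() == 12
    assert (brf.loc[12, "NIR"] <= brf["NIR"]).all()
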