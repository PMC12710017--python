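"""Shared fixtures: coefficient tables, scenes, a reduced LUT, and a survey.

Session-scoped simulation fixtures keep the suite inside its time budget;
the reduced parameter grid (4 x 12 x 2 x 6 levels) preserves the structure
of the full 8 x 70 x 4 x 9 grid at desk scale.
"""

import warnings

import numpy as np
import pytest

from crownchl.canopy_scene import (
    OrchardScene,
    ParameterGrid,
    build_lut,
)
from crownchl.leaf_rtm import load_coefficients
from crownchl.synthetic_orchard import generate_orchard, render_survey, sample_truth

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")

REDUCED_COUNTS = (4, 12, 2, 6)


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture(scope="session")
def coeffs_test():
    return load_coefficients("test")


@pytest.fixture(scope="session")
def small_scene():
    return OrchardScene.grid(rows=3, trees_per_row=3)


@pytest.fixture(scope="session")
def reduced_lut(small_scene):
    """Noisy band-level LUT on the reduced grid over all 8 times."""
    grid = ParameterGrid.from_counts(REDUCED_COUNTS)
    return build_lut(
        grid, scene=small_scene, seed=7, resolution=0.06, fesc_photons=3000
    )


@pytest.fixture(scope="session")
def ranking(reduced_lut):
    from crownchl.shadow_resistance import ranking_from_lut

    return ranking_from_lut(reduced_lut)


@pytest.fixture(scope="session")
def selection(reduced_lut, ranking):
    """Rank-ordered forward VI selection on the reduced LUT (seeded)."""
    from crownchl.hybrid_inversion import iterative_vi_selection
    from crownchl.spectral_indices import BAND_NAMES, compute_all

    vis = compute_all(reduced_lut[list(BAND_NAMES)])
    return iterative_vi_selection(
        list(ranking.index),
        vis,
        reduced_lut["cab"].to_numpy(),
        seed=11,
        max_train=500,
        n_restarts=1,
    )


@pytest.fixture(scope="session")
def survey12():
    """Mini synthetic survey at 12:00 with default sensor noise."""
    layout = generate_orchard(4, 6, jitter=0.2, seed=5)
    truth = sample_truth(layout.n_trees, seed=6)
    return render_survey(
        layout, truth, time=12.0, resolution=0.04, noise_std=0.01, seed=7
    )


@pytest.fixture(scope="session")
def lcc_model(reduced_lut):
    """GPR LCC model on the 4 top-ranked VI features of the reduced LUT."""
    from crownchl.hybrid_inversion import train_gpr
    from crownchl.shadow_resistance import ranking_from_lut
    from crownchl.spectral_indices import BAND_NAMES, compute_all

    ranking = ranking_from_lut(reduced_lut)
    chosen = list(ranking.index[:4])
    vis = compute_all(reduced_lut[list(BAND_NAMES)])
    ok = np.isfinite(vis[chosen].to_numpy()).all(axis=1)
    model = train_gpr(
        vis.loc[ok, chosen],
        reduced_lut.loc[ok, "cab"].to_numpy(),
        seed=1,
        max_train=800,
        n_restarts=1,
    )
    return model
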