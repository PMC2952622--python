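"""Shared fixtures: canonical synthetic scenarios generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cret import physics, synthetic_data
from cret.physics import _substream_int

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def f18():
    return physics.get_nuclide("F-18")


@pytest.fixture(scope="session")
def cu64():
    return physics.get_nuclide("Cu-64")


@pytest.fixture(scope="session")
def tc99m():
    return physics.get_nuclide("Tc-99m")


@pytest.fixture(scope="session")
def water_medium():
    return physics.water()


@pytest.fixture(scope="session")
def f18_per_decay(f18, water_medium):
    """Per-decay Cerenkov spectrum of F-18 in water (shared, seeded)."""
    return physics.cherenkov_photons_per_decay(
        f18, water_medium, n_samples=20000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def concentration_plate(tmp_path_factory):
    """Concentration-ladder plate: 0-200 nM acceptor at 5.6 MBq F-18."""
    scenario = synthetic_data.PlateScenario(
        name="concentration_plate", seed=_substream_int(FIXTURE_SEED, "conc_ladder"))
    path, manifest = synthetic_data.generate_plate(
        scenario, tmp_path_factory.mktemp("conc_ladder") / "plate")
    return path, manifest


@pytest.fixture(scope="session")
def titration_plate(tmp_path_factory):
    """Activity-titration plate: 0-37 MBq F-18 at 0/40 nM acceptor."""
    scenario = synthetic_data.PlateScenario(
        name="titration_plate",
        fluorophore_concentration_nm=[0.0, 40.0],
        activity_per_well_mbq=[0.0, 0.037, 0.37, 3.7, 37.0],
        exposure_s=30.0, seed=_substream_int(FIXTURE_SEED, "act_titration"))
    path, manifest = synthetic_data.generate_plate(
        scenario, tmp_path_factory.mktemp("act_titration") / "plate")
    return path, manifest


@pytest.fixture(scope="session")
def tc99m_plate(tmp_path_factory):
    """Gamma-only null plate: Tc-99m with and without acceptor."""
    scenario = synthetic_data.PlateScenario(
        name="tc99m_plate", nuclide="Tc-99m",
        fluorophore_concentration_nm=[0.0, 400.0],
        hot_pixel_rate=0.0, seed=_substream_int(FIXTURE_SEED, "tc99m"))
    path, manifest = synthetic_data.generate_plate(
        scenario, tmp_path_factory.mktemp("tc") / "plate")
    return path, manifest


@pytest.fixture(scope="session")
def mouse_500(tmp_path_factory):
    scenario = synthetic_data.MouseScenario(
        name="mouse_500nM", pseudotumor_concentrations_nm=(500.0, 0.0),
        seed=_substream_int(FIXTURE_SEED, "mouse_500nM"))
    path, manifest = synthetic_data.generate_mouse(
        scenario, tmp_path_factory.mktemp("mouse500") / "mouse")
    return path, manifest


@pytest.fixture(scope="session")
def mouse_200(tmp_path_factory):
    scenario = synthetic_data.MouseScenario(
        name="mouse_200nM", pseudotumor_concentrations_nm=(200.0, 0.0),
        seed=_substream_int(FIXTURE_SEED, "mouse_200nM"))
    path, manifest = synthetic_data.generate_mouse(
        scenario, tmp_path_factory.mktemp("mouse200") / "mouse")
    return path, manifest


@pytest.fixture(scope="session")
def hot_pixel_fixture():
    """Clean noise-free image, corrupted twin, injected coordinates."""
    return synthetic_data.hot_pixel_pair(
        seed=_substream_int(FIXTURE_SEED, "hotpix"))
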