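"""Shared fixtures: published parameter sets and small synthetic plates."""

import numpy as np
import pytest
from hypothesis import settings

from nrfr import ExperimentDesign, GeneratingModel, simulate_experiment

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Fitted numerical-response parameters (mu_max d^-1, P' mg C/L, k2 mg C/L)
# and the published initial slope alpha, per species and temperature.
NR_PARAMS = {
    ("H. bodamicum", 5): ((0.23, 0.14, 0.30), 0.78),
    ("V. natans", 5): ((0.33, 0.16, 0.16), 2.0),
    ("H. bodamicum", 10): ((0.36, 0.46, 0.61), 0.59),
    ("V. natans", 10): ((0.45, 0.28, 0.55), 0.81),
    ("H. bodamicum", 15): ((0.38, 0.46, 0.93), 0.41),
    ("V. natans", 15): ((0.45, 0.10, 0.18), 2.44),
    ("H. bodamicum", 18): ((0.44, 0.20, 0.40), 1.11),
    ("V. natans", 20): ((0.83, 0.11, 0.27), 3.13),
}

# Holling-II functional-response parameters (I_max ng C/cell/d, k mg C/L)
# for the temperature/species combinations where the fit converged.
FR_PARAMS = {
    ("H. bodamicum", 5): (67.35, 6.22),
    ("V. natans", 5): (4.94, 0.52),
    ("H. bodamicum", 10): (17.81, 0.87),
    ("V. natans", 10): (27.68, 3.31),
    ("H. bodamicum", 15): (17.37, 2.07),
    ("V. natans", 15): (28.54, 4.09),
}

# Published cell volume (µm^3) -> cell biomass; ciliates in ng C, algae pg C
CILIATE_BIOMASS_TABLE = [
    (40941, 4.6),
    (20539, 2.4),
    (34628, 3.9),
    (22068, 2.6),
    (26749, 3.1),
    (29455, 3.4),
    (32557, 3.7),
    (17848, 2.1),
]
ALGA_BIOMASS_TABLE = [(337, 39), (304, 36), (313, 37), (262, 31), (247, 30), (293, 34)]

#: V. natans 15 °C ground truth used throughout the recovery tests
VNATANS_15C = GeneratingModel(nr=(0.45, 0.10, 0.18), fr_holling=(28.54, 4.09))


@pytest.fixture(scope="session")
def vnatans_model():
    return VNATANS_15C


@pytest.fixture(scope="session")
def noiseless_plate(vnatans_model):
    return simulate_experiment(vnatans_model, ExperimentDesign(), seed=11, noiseless=True)


@pytest.fixture(scope="session")
def noisy_plate(vnatans_model):
    return simulate_experiment(vnatans_model, ExperimentDesign(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
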