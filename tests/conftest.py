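"""Shared fixtures: small noise-free and noisy synthetic configurations."""

import numpy as np
import pytest
from hypothesis import settings

from placscreen.synthetic_data import SimulationConfig, StudyDesign

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_genes():
    return [f"G{i}" for i in range(1, 7)]


@pytest.fixture
def noisefree_config(small_genes):
    """Tiny noise-free cohort: one gene per planted class plus two nulls."""
    return SimulationConfig(
        genes=small_genes,
        effect_class={"G1": "iugr_only", "G2": "pe_only", "G3": "equal",
                      "G4": "equal_reversed"},
        effect_size=1.0,
        noise_sd=0.0,
        sample_offset_sd=0.0,
        study_designs=(StudyDesign("A", 4, 4, 4), StudyDesign("B", 3, 3, 0)),
        group_sizes={"term": 4, "preterm": 2, "IUGR": 3, "PE": 3,
                     "PE+IUGR": 2},
        seed=11,
    )


@pytest.fixture
def noisy_config(small_genes):
    return SimulationConfig(
        genes=small_genes,
        effect_class={"G1": "iugr_only", "G2": "pe_only", "G3": "equal",
                      "G4": "equal_reversed"},
        effect_size=1.5,
        noise_sd=0.25,
        study_designs=(StudyDesign("A", 5, 5, 5),),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
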