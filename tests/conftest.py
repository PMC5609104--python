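"""Shared fixtures: synthetic truths, phantoms, simple ligand constants."""

import warnings

import numpy as np
import pytest

import autoradq as aq
from autoradq import panel


@pytest.fixture(autouse=True)
def _quiet_calibration_warnings():
    # out-of-range background pixels are masked with a warning by design;
    # tests assert on the masking, not the warning text
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the calibrated range.*")
        yield


@pytest.fixture(scope="session")
def simple_ligand() -> aq.LigandParams:
    return aq.LigandParams(E=0.5, B=2.0, Wb=0.05, Sa=80.0, KD=1.4, L=0.7)


@pytest.fixture(scope="session")
def demo_truth() -> aq.GroundTruthTable:
    return aq.generate_ground_truth(aq.demo_config(replicate_cv=0.05), seed=7)


@pytest.fixture(scope="session")
def demo_strata(demo_truth):
    return aq.strata_table_from_truth(demo_truth)


@pytest.fixture(scope="session")
def demo_mean_strata(demo_strata):
    return (demo_strata.groupby(["area", "receptor"], sort=False, as_index=False)
            [["mean_sg", "mean_g", "mean_ig", "mean_all"]].mean())


@pytest.fixture(scope="session")
def flat_phantom(demo_truth):
    """Noiseless flat-ribbon phantom of the first receptor, brain 1."""
    receptor = "AMPA"
    ligand = aq.default_ligands([receptor])[receptor]
    spec = aq.auto_spec(demo_truth, ligand, receptor, noise_sd=0.0, seed=3)
    return aq.render_phantom(spec, demo_truth, ligand, receptor=receptor, brain=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def constant_receptor(name="flat", value=100.0):
    """Receptor with identical density in all strata (constant-field phantoms)."""
    return panel.ReceptorSpec(name, panel.CUSTOM,
                              {"sg": value, "g": value, "ig": value})
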