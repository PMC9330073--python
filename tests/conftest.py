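import numpy as np
import pytest

from complexqa.model_io import ComplexSpec
from complexqa.synthetic_data import (
    ENSEMBLE_PRESETS,
    EnsembleNoiseSpec,
    ToyComplexSpec,
    default_complex_spec,
    fabricate_confidence,
    make_toy_complex,
    perturb_model_ensemble,
)


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec()


@pytest.fixture(scope="session")
def toy(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def cspec(toy_spec):
    return default_complex_spec(toy_spec)


@pytest.fixture(scope="session")
def ensemble_vac17(toy, cspec):
    """Full-consensus 5-model ensemble with fabricated confidence."""
    noise = EnsembleNoiseSpec(**{**ENSEMBLE_PRESETS["vac17-like"].__dict__, "seed": 11})
    mset = perturb_model_ensemble(toy, noise, cspec)
    return fabricate_confidence(mset, toy, cspec, jitter_sd=0.25, seed=11)


@pytest.fixture(scope="session")
def long_ligand_truth():
    """Toy complex with a long disordered-adaptor-like ligand, planted MIS 460-512."""
    spec = ToyComplexSpec(ligand_n_res=71, ligand_seq_start=450, planted_mis=(460, 512))
    return make_toy_complex(spec), default_complex_spec(spec)
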