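import numpy as np
import pytest

from ryrgate import (
    CoiParameters,
    NoiseModel,
    generate_dataset,
    paper_design,
    paper_truth,
    reference_parameters,
    table8_fitspec,
)

#: Published best-fit free-parameter values keyed by free-slot name.
TABLE8_FREE_TRUTH = {
    "K_Ca": 0.59,
    "K_Mg": 36.3,
    "f_Ca[RyR2+ATP]": 0.029,
    "f_Ca[RyR2-ATP]": 0.10,
    "f_Ca[RyR1-ATP]": 0.15,
    "h_CaM[RyR2+ATP]": 0.016,
    "h_CaM_noATP": 0.11,
    "h_M[RyR1-ATP]": 0.28,
}

#: Published standard errors of the same slots.
TABLE8_FREE_SE = {
    "K_Ca": 0.15,
    "K_Mg": 4.3,
    "f_Ca[RyR2+ATP]": 0.005,
    "f_Ca[RyR2-ATP]": 0.003,
    "f_Ca[RyR1-ATP]": 0.01,
    "h_CaM[RyR2+ATP]": 0.003,
    "h_CaM_noATP": 0.04,
    "h_M[RyR1-ATP]": 0.10,
}


@pytest.fixture(scope="session")
def truth():
    return paper_truth()


@pytest.fixture(scope="session")
def design():
    return paper_design()


@pytest.fixture(scope="session")
def seeded_datasets(truth, design):
    """One realistic-noise realization of the study design (seed 1)."""
    return generate_dataset(truth, design, NoiseModel(), seed=1)


def random_reduced_parameters(rng) -> CoiParameters:
    """A random but physically plausible reduced parameter set."""
    return CoiParameters.reduced(
        K_O0=float(rng.uniform(1e3, 1e5)),
        K_I0=float(rng.uniform(1e3, 1e5)),
        K_Ca=float(10 ** rng.uniform(-1, 1)),
        K_Mg=float(10 ** rng.uniform(0.5, 2.5)),
        K_M=float(10 ** rng.uniform(2, 3.5)),
        f_Ca=float(10 ** rng.uniform(-2, 0.5)),
        f_Mg=float(10 ** rng.uniform(-0.5, 1)),
        h_M=float(10 ** rng.uniform(-1, 0.3)),
        h_CaM=float(10 ** rng.uniform(-2, 0.3)),
        h_MgM=float(10 ** rng.uniform(-1, 0.3)),
    )


def random_full_parameters(rng) -> CoiParameters:
    base = random_reduced_parameters(rng).to_dict()
    for name in ("f_M", "h_Ca", "h_Mg", "f_CaM", "f_MgM", "g_CaM", "g_MgM"):
        base[name] = float(10 ** rng.uniform(-1, 1))
    return CoiParameters(**base)


def random_condition(rng):
    from ryrgate import IonCondition

    return IonCondition.from_uM(
        float(10 ** rng.uniform(-2, 3.5)), float(10 ** rng.uniform(-1, 3.2))
    )
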