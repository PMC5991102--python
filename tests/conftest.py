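import numpy as np
import pytest

from allokit import AllosterySpec, StrainSpec


@pytest.fixture(scope="session")
def fitted_allostery() -> AllosterySpec:
    """The headline fitted MWC parameters (K_A=139 uM, K_I=0.53 uM, 4.5 kBT)."""
    return AllosterySpec(ka=139e-6, ki=0.53e-6, d_eps_ai=4.5, n_sites=2)


@pytest.fixture(scope="session")
def o2_strain() -> StrainSpec:
    return StrainSpec(repressors=260, d_eps_ra=-13.9)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)


def random_parameter_sets(rng: np.random.Generator, n: int):
    """Random valid inducible parameter sets (K_I < K_A) for property tests."""
    out = []
    for _ in range(n):
        ka = 10.0 ** rng.uniform(-6, -3)
        ki = ka / 10.0 ** rng.uniform(0.3, 3)
        a = AllosterySpec(
            ka=ka,
            ki=ki,
            d_eps_ai=float(rng.uniform(0.0, 6.0)),
            n_sites=int(rng.choice([1, 2, 4])),
        )
        s = StrainSpec(
            repressors=float(10.0 ** rng.uniform(0.5, 3.5)),
            d_eps_ra=float(rng.uniform(-17.0, -9.0)),
        )
        out.append((a, s))
    return out
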