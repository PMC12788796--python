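import numpy as np
import pytest

from oligosep.thermo import InteractionClass, MixtureSpec


@pytest.fixture
def fh_spec():
    """Plain Flory-Huggins monomer-solvent mixture (no assemblies)."""
    return MixtureSpec(M=1, chi=1.0, T=0.4, e_int=0.0, omega_inf=0.0)


@pytest.fixture
def linear_spec():
    """Linear assemblies, class 1, moderate bond strength."""
    return MixtureSpec(M=50, d=1, chi=1.0, e_int=-3.0, T=0.8)


@pytest.fixture
def class2_spec():
    """Linear assemblies with screened (size-dependent) solvent interaction."""
    return MixtureSpec(
        M=50, d=1, interaction_class=InteractionClass.CLASS2,
        chi=1.2, chi_prime=0.4, e_int=-2.0, s_int=0.3, T=0.8,
    )


@pytest.fixture
def gel_spec():
    """Three-dimensional assemblies capable of gelation."""
    return MixtureSpec(M=600, d=3, chi=1.0, e_int=-0.5, T=0.47)


def random_state(rng, M, scale=0.15):
    """A strictly interior random composition with phi_s > 0."""
    phi = rng.uniform(0.005, scale, M)
    if phi.sum() > 0.9:
        phi *= 0.9 / phi.sum()
    return phi
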