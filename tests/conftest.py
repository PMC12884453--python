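import numpy as np
import pytest

from lcnpkit import raman
from lcnpkit.synthetic import (
    SyntheticRamanSpec,
    SyntheticSAXSSpec,
    generate_raman_population,
    generate_saxs_profile,
)


@pytest.fixture(scope="session")
def pn3m_profile():
    """Noise-free Pn3m profile with d = 10.1 nm on the instrument q-range."""
    return generate_saxs_profile(SyntheticSAXSSpec("Pn3m", 10.1))


@pytest.fixture(scope="session")
def im3m_profile():
    return generate_saxs_profile(SyntheticSAXSSpec("Im3m", 14.2))


@pytest.fixture(scope="session")
def l3_profile():
    """Sponge-phase profile whose correlation peak sits at q = 0.6 nm^-1."""
    return generate_saxs_profile(SyntheticSAXSSpec("L3", 14.8))


@pytest.fixture(scope="session")
def small_population():
    """A 60-particle population, half hybrid, with a 15% interfering
    subpopulation, preprocessed once for reuse."""
    spec = SyntheticRamanSpec(
        n_particles=60, hybrid_fraction=0.5, subpop_fraction=0.15, seed=3
    )
    batch, blank = generate_raman_population(spec)
    processed = raman.preprocess_batch(batch, blank)
    return batch, processed


@pytest.fixture(scope="session")
def pure_reference_areas():
    """Protein-peak areas of a preprocessed pure (non-hybrid) population."""
    spec = SyntheticRamanSpec(n_particles=100, hybrid_fraction=0.0, seed=42)
    batch, blank = generate_raman_population(spec)
    processed = raman.preprocess_batch(batch, blank)
    return np.array([raman.integrate_protein_peak(s) for s in processed])
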