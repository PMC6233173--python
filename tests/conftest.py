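import numpy as np
import pytest

import spectralsar as ss


@pytest.fixture(scope="session")
def bundled_db():
    return ss.bundled_indices()


@pytest.fixture(scope="session")
def hydropathy(bundled_db):
    return ss.get_index(bundled_db, "KYTJ820101")


@pytest.fixture(scope="session")
def fixture_index():
    """Deterministic synthetic encoding index with distinct values."""
    return ss.make_fixture_index(seed=11)


@pytest.fixture(scope="session")
def toy_index():
    """Tiny handmade index mapping A..V to 1..20 in AAindex residue order."""
    return ss.EncodingIndex(
        accession="TOY0000001",
        description="identity-style toy index",
        values={aa: float(i + 1) for i, aa in enumerate(ss.AA_ORDER)},
    )


@pytest.fixture(scope="session")
def additive_landscape():
    """Noiseless, epistasis-free 9-mutation landscape (all 512 genotypes)."""
    cfg = ss.LandscapeConfig(n_mutations=9, gamma_density=0.0, sigma=0.0, seed=42)
    return ss.simulate_landscape(cfg)


@pytest.fixture(scope="session")
def epistatic_landscape():
    """Noiseless 9-mutation landscape with sparse pairwise epistasis."""
    cfg = ss.LandscapeConfig(n_mutations=9, gamma_density=0.25, sigma=0.0, seed=7)
    return ss.simulate_landscape(cfg)


def singles_subtable(landscape):
    """Rows of the landscape's variant table with at most one mutation."""
    mask = [len(ss.parse_genotype(m)) <= 1 for m in landscape.variants["mutations"]]
    return landscape.variants[mask].reset_index(drop=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
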