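import numpy as np
import pytest

from gwlpheno import synth
from gwlpheno.doseresp import FourPL


@pytest.fixture(scope="session")
def untreated_population():
    """10k-cell untreated population with arbitrary-unit gain."""
    spec = synth.PopulationSpec(n_cells=10_000, dose=0.0, intensity_gain=1000.0,
                                peak_cv=0.10, seed=101)
    return synth.gen_cell_population(spec)


@pytest.fixture(scope="session")
def treated_population():
    """10k-cell population at 0.5 µM with a ploidy-shift midpoint of 0.3 µM."""
    spec = synth.PopulationSpec(
        n_cells=10_000, dose=0.5,
        effect_curve=FourPL(slope=-2.0, lower=0.0, upper=1.0, midpoint=0.3),
        p21_fraction=0.3, multinucleation_fraction=0.15,
        intensity_gain=1000.0, peak_cv=0.10, seed=202,
    )
    return synth.gen_cell_population(spec)


@pytest.fixture(scope="session")
def phospho_dataset():
    """1,500-site matrix, 3v3, spiked down/up effects, default motif bias."""
    return synth.gen_phospho_dataset(
        n_sites=1500, replicates=3, frac_down=0.1, frac_up=0.05,
        effect_log2=3.0, seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
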