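import numpy as np
import pytest

from dipkit.core import GenotypeMatrix, LocusDef
from dipkit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """Two Balding-Nichols populations, 20 loci, 60+40 individuals."""
    rng = np.random.default_rng(42)
    anc = rng.uniform(0.2, 0.8, 20)
    freqs = sd.balding_nichols_freqs(anc, 0.10, 2, rng)
    a = sd.sample_hwe_genotypes(freqs[0], 60, rng, population="A")
    b = sd.sample_hwe_genotypes(freqs[1], 40, rng, population="B")
    return stack_populations(a, b)


@pytest.fixture(scope="session")
def preset_panel():
    """The 25-population synthetic reference panel (seeded once per session)."""
    return sd.generate_kyrgyz_like(7)


def stack_populations(*gms: GenotypeMatrix) -> GenotypeMatrix:
    samples, pops = [], []
    for g in gms:
        samples += g.samples
        pops += g.populations
    return GenotypeMatrix(samples, pops, gms[0].loci,
                          np.vstack([g.dosage for g in gms]))
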