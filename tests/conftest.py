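import numpy as np
import pytest

from admixscan import synthpop as sp


@pytest.fixture(scope="session")
def toy_cohort():
    """Small admixed cohort shared across module tests (no background LD)."""
    chrom, pos = sp.snp_grid(2, 300, 25_000_000, seed=71)
    freqs = sp.sample_ancestral_freqs(len(pos), seed=72)
    founders = sp.simulate_founder_haplotypes(freqs, chrom, pos, 40, seed=73)
    panel, ancestry, truth = sp.simulate_admixture(
        founders, 60, generations=(2, 12), seed=74
    )
    return {
        "panel": panel,
        "ancestry": ancestry,
        "truth": truth,
        "founders": founders,
        "freqs": freqs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
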