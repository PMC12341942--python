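import numpy as np
import pytest

from phasebench import (
    PhasedAncestryCalls,
    concat_genotypes,
    make_uniform_map,
    oracle_lai,
    simulate_markov_tracts,
    simulate_panels,
    synthesize,
)


@pytest.fixture(scope="session")
def small_map():
    """Three 50-cM chromosomes, 0.5-cM marker grid (1.5 Morgans total)."""
    return make_uniform_map(3, 50.0, 0.5)


@pytest.fixture(scope="session")
def small_panels(small_map):
    return simulate_panels(small_map, n_hap_per_pop=20, fst=0.15, seed=10)


@pytest.fixture(scope="session")
def cohort(small_map, small_panels):
    """Six admixed individuals (T=6, p=0.5): truth tract pairs, phased
    genotypes, and perfect marker-level calls."""
    rng = np.random.default_rng(42)
    pairs = []
    parts = []
    for i in range(6):
        name = f"sim_0_{i}"
        a = simulate_markov_tracts(small_map, 6, 0.5, rng, individual=name, haplotype=0)
        b = simulate_markov_tracts(small_map, 6, 0.5, rng, individual=name, haplotype=1)
        pairs.append((a, b))
        parts.append(synthesize(a, b, small_panels, small_map, rng, sample=name))
    genotypes = concat_genotypes(parts)
    truth_calls = oracle_lai(pairs, small_map, small_panels[0].markers, mode="perfect")
    return {"pairs": pairs, "genotypes": genotypes, "truth_calls": truth_calls}
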