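import numpy as np
import pytest

import gblupset as gs


@pytest.fixture(scope="session")
def small_geno():
    """60 lines x 1,500 markers, block LD, inbred."""
    return gs.simulate_genotypes(60, 1500, seed=11)


@pytest.fixture(scope="session")
def small_grm(small_geno):
    return gs.build_grm(small_geno)


@pytest.fixture(scope="session")
def sim_dataset(small_geno, small_grm):
    """One simulated data set with a fitted GBLUP model and effects."""
    causal = gs.select_causal_sets(
        small_geno, "random", seed=21, n_c1=50, n_c2=200,
        null_set_sizes=(50,), n_null_per_size=4,
    )
    sc = gs.SimulationScenario(h2=0.5, hf2=0.5, n_rep=8, seed=22)
    ph = gs.simulate_phenotypes(small_geno, causal, sc)
    y = ph["value"].to_numpy()
    lines = ph["line_index"].to_numpy()
    fit = gs.GBLUP().fit(small_grm, y, lines=lines)
    effects = gs.backsolve_effects(fit, small_geno)
    return dict(geno=small_geno, grm=small_grm, causal=causal, pheno=ph,
                y=y, lines=lines, fit=fit, effects=effects)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
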