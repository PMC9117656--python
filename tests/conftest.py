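import numpy as np
import pytest

from plastcomp.plastome_io import AnnotatedGenome, Feature
from plastcomp.simulate import SimulationConfig, mini_config, simulate


def random_seq(rng, n, p=(0.317, 0.183, 0.183, 0.317)):
    """Random DNA with plastome-like AT richness."""
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))


@pytest.fixture(scope="session")
def mini_sim():
    """Small evolved data set (8 taxa, ~11.5 kb reduced genome) at the default
    per-class rates; shared by variant/phylo/integration tests."""
    return simulate(mini_config(seed=7))


@pytest.fixture(scope="session")
def static_sim():
    """Full-architecture genome with every planted element but zero mutation:
    the leaves equal the ancestor, so planted coordinates are exact."""
    cfg = SimulationConfig(
        seed=13,
        taxa={"Acnida": 1, "Amaranthus": 1, "Albersia": 1},
        n_outgroup=1,
        subst_rates={k: 0.0 for k in ("CDS", "tRNA", "rRNA", "intron", "IGS")},
        indel_freqs={k: 0.0 for k in ("CDS", "tRNA", "rRNA", "intron", "IGS")},
        planted_indels=[],
    )
    return simulate(cfg)


@pytest.fixture()
def toy_genome():
    """400 bp circular genome with two genes, for interval arithmetic tests."""
    rng = np.random.default_rng(0)
    seq = random_seq(rng, 400)
    feats = [
        Feature("gene", "g1", ((0, 100),)),
        Feature("gene", "g2", ((200, 300),)),
    ]
    return AnnotatedGenome("toy", seq, circular=True, features=feats)
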