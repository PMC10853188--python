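import numpy as np
import pytest

from mrshape.harmonize import HarmonizedPair, align_pair
from mrshape.summary_io import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def harmonize_sim(sim, sex="women"):
    """Align every simulated outcome record against its exposure record."""
    exposure = {rec.rsid: rec for rec in sim.exposure}
    return [align_pair(exposure[rec.rsid], rec) for rec in sim.outcomes[sex]]


def random_pairs(rng, n_snps, *, theta=0.05):
    """A random harmonized panel with heterogeneous weights."""
    bx = rng.uniform(0.03, 0.12, n_snps) * rng.choice([-1.0, 1.0], n_snps)
    sx = rng.uniform(0.005, 0.02, n_snps)
    sy = rng.uniform(0.002, 0.01, n_snps)
    by = rng.normal(theta * bx, sy)
    return [
        HarmonizedPair(
            rsid=f"rs{j}", effect_allele="A", other_allele="G",
            beta_x=float(bx[j]), se_x=float(sx[j]),
            beta_y=float(by[j]), se_y=float(sy[j]),
        )
        for j in range(n_snps)
    ]


@pytest.fixture
def pairs_of():
    return harmonize_sim


@pytest.fixture
def make_pairs():
    return random_pairs
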