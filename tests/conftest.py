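import numpy as np
import pytest

from hapgene.refine import RefinementInputs, run_refinement
from hapgene.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_haplotype_pair,
)

SMALL_SV_EVENTS = [
    ("DEL", 1000), ("INS", 800), ("INV", 4000), ("DUP", 1200), ("TRANS", 1500),
]


def small_config(seed: int = 3, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed, n_chrom=2, chrom_len=400_000, n_genes=60,
        sv_events=list(SMALL_SV_EVENTS), n_notal=1, notal_len=2000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-gene, 2x400 kb fixture shared by read-only tests."""
    return simulate_haplotype_pair(small_config())


@pytest.fixture(scope="session")
def small_expr(small_sim):
    cfg = small_sim.config
    return simulate_expression(small_sim.truth, list(cfg.tissues), cfg)


@pytest.fixture(scope="session")
def battery():
    """The default fixture battery: 500 genes on 2x2.5 Mb chromosomes with
    5% dropped, 3% split, 2% merged and 5% spurious models."""
    return simulate_haplotype_pair(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def battery_refined(battery):
    cfg = battery.config
    e1, e2 = simulate_expression(battery.truth, list(cfg.tissues), cfg)
    inputs = RefinementInputs(
        hap1=battery.hap1, hap2=battery.hap2,
        genes_h1=battery.genes_h1, genes_h2=battery.genes_h2,
        variants=battery.variants, blocks=battery.blocks,
        te_h1=battery.te, junctions_h2=battery.junctions,
        expr_h1=e1, expr_h2=e2, domains=battery.domains,
    )
    return run_refinement(inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
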