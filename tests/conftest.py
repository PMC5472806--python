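import numpy as np
import pytest

from chronolgt.phylo_core import parse_dated_newick
from chronolgt.synthetic_data import SimConfig, simulate_dated_tree, simulate_gene_content


@pytest.fixture(scope="session")
def example_tree():
    """Three-leaf dated tree used in hand-derived examples."""
    return parse_dated_newick("((A:1,B:1):2,C:3);")


@pytest.fixture(scope="session")
def two_clade_tree():
    """Four-leaf tree with two labelled clades."""
    t = parse_dated_newick("((A:1,B:1):2,(C:2,D:2):1);")
    t.clade_map = {"A": "I", "B": "I", "C": "II", "D": "II"}
    return t


@pytest.fixture(scope="session")
def sim_tree20():
    return simulate_dated_tree(20, 100.0, seed=1, clade_split_depth=10)


@pytest.fixture(scope="session")
def sim_content20(sim_tree20):
    cfg = SimConfig(
        seed=2,
        n_taxa=20,
        root_age=100,
        transfer_rate=0.05,
        loss_rate=0.005,
        within_clade_bias=0.5,
        post_transfer_loss_multiplier=1.0,
        n_families=200,
        root_family_fraction=0.8,
        clade_split_depth=10,
    )
    matrix, log, gene_trees = simulate_gene_content(sim_tree20, cfg)
    return cfg, matrix, log, gene_trees


def random_ultrametric_newick(rng, labels):
    """Random coalescence with random waiting times; ultrametric by design."""
    nodes = [(str(l), 0.0) for l in labels]
    t = 0.0
    while len(nodes) > 1:
        t += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (a, ta), (b, tb) = nodes[i], nodes[j]
        merged = (f"({a}:{t - ta:.12g},{b}:{t - tb:.12g})", t)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0][0] + ";"


def random_gene_topology(rng, tips):
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [f"({a},{b})"]
    return nodes[0] + ";"
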