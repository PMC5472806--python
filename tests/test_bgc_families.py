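import io

import numpy as np
import pytest
from scipy import stats

from chronolgt.phylo_core import TreeError
from chronolgt.synthetic_data import simulate_dated_tree
from chronolgt.lgt_rates import TransferEvent
from chronolgt.bgc_families import (
    BGCluster,
    bgc_gene_sources,
    build_similarity_graph,
    cluster_families,
    lin_similarity,
    mcl_cluster,
    read_bgc_tsv,
    restriction_fraction,
    restriction_test,
    write_bgc_tsv,
)


def bgc(cid, *domains, genome="G"):
    return BGCluster(cid, genome, tuple(domains))


class TestLinSimilarity:
    def test_identical_clusters(self):
        a = bgc("a", "d1", "d2", "d3")
        assert lin_similarity(a, a) == 1.0

    def test_disjoint_domain_sets(self):
        a = bgc("a", "d1", "d2", "d3")
        b = bgc("b", "d4", "d5", "d6")
        assert lin_similarity(a, b) == 0.0

    def test_reversed_order_keeps_only_jaccard_weight(self):
        a = bgc("a", "d1", "d2", "d3")
        b = bgc("b", "d3", "d2", "d1")
        # Jaccard 1, gamma -1 -> 0.36 * 1 + 0.64 * 0
        assert lin_similarity(a, b) == pytest.approx(0.36)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        doms = [f"d{i}" for i in range(12)]
        for _ in range(100):
            a = bgc("a", *rng.choice(doms, size=rng.integers(3, 8)))
            b = bgc("b", *rng.choice(doms, size=rng.integers(3, 8)))
            s = lin_similarity(a, b)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(lin_similarity(b, a))

    def test_too_few_domains_rejected(self):
        with pytest.raises(ValueError, match="3 domains"):
            bgc("a", "d1", "d2")


class TestMcl:
    def _clique_edges(self, members, offset):
        return [
            (i + offset, j + offset, 0.9)
            for i in range(members)
            for j in range(i + 1, members)
        ]

    def test_two_cliques_two_families(self):
        ids = [f"c{i}" for i in range(8)]
        edges = self._clique_edges(4, 0) + self._clique_edges(4, 4)
        assign = mcl_cluster(ids, edges)
        groups = {}
        for cid, f in assign.items():
            groups.setdefault(f, set()).add(cid)
        assert sorted(map(sorted, groups.values())) == [
            [f"c{i}" for i in range(4)],
            [f"c{i}" for i in range(4, 8)],
        ]

    def test_singleton_is_its_own_family(self):
        assign = mcl_cluster(["only"], [])
        assert assign == {"only": 0}

    def test_partition_invariant_to_relabelling(self):
        rng = np.random.default_rng(1)
        n = 12
        edges = [
            (i, j, float(w))
            for i in range(n)
            for j in range(i + 1, n)
            if (w := rng.random()) > 0.6
        ]
        ids = [f"c{i}" for i in range(n)]
        base = mcl_cluster(ids, edges)
        perm = list(rng.permutation(n))
        ids2 = [ids[perm[i]] for i in range(n)]
        inv = {perm[i]: i for i in range(n)}
        edges2 = [(inv[i], inv[j], w) for i, j, w in edges]
        relab = mcl_cluster(ids2, edges2)
        part1 = {}
        part2 = {}
        for cid in ids:
            part1.setdefault(base[cid], set()).add(cid)
            part2.setdefault(relab[cid], set()).add(cid)
        assert sorted(map(sorted, part1.values())) == sorted(
            map(sorted, part2.values())
        )

    def test_raising_threshold_only_refines(self):
        rng = np.random.default_rng(2)
        doms = [f"d{i}" for i in range(15)]
        clusters = [
            bgc(f"c{i}", *rng.choice(doms, size=6)) for i in range(20)
        ]
        lo = cluster_families(clusters, threshold=0.5)
        hi = cluster_families(clusters, threshold=0.8)
        # families at the higher threshold nest inside those at the lower
        for fam in set(hi.values()):
            members = {c for c, f in hi.items() if f == fam}
            lo_fams = {lo[c] for c in members}
            assert len(lo_fams) == 1


@pytest.fixture(scope="module")
def tree50():
    return simulate_dated_tree(50, 380.0, seed=42, clade_split_depth=30)


class TestRestriction:

    def test_family_on_all_taxa_never_restricted(self, tree50):
        r = restriction_test(tree50, tree50.leaf_labels, seed=0)
        assert not r.restricted
        assert r.p_value == 1.0

    def test_tip_cherry_is_restricted(self, tree50):
        cherries = [
            v
            for v in range(tree50.n_nodes)
            if not tree50.is_leaf(v) and len(tree50.leaf_set(v)) == 2
        ]
        r = restriction_test(tree50, tree50.leaf_set(cherries[0]),
                             alpha=1e-5, seed=7)
        assert r.restricted
        assert r.observed_my < r.null_mean

    def test_single_taxon_rejected(self, tree50):
        with pytest.raises(TreeError, match=">= 2"):
            restriction_test(tree50, [tree50.leaf_labels[0]])

    def test_seeded_reproducibility(self, tree50):
        taxa = tree50.leaf_labels[:6]
        a = restriction_test(tree50, taxa, seed=5)
        b = restriction_test(tree50, taxa, seed=5)
        assert a == b

    def test_fraction_all_or_none(self, tree50):
        r_all = restriction_test(tree50, tree50.leaf_labels[:4], seed=1)
        fake_true = [r_all]
        out = restriction_fraction(fake_true)
        assert out["overall"] in (0.0, 1.0)
        with pytest.raises(ValueError):
            restriction_fraction([])


class TestGeneSources:
    def _setup(self, tree):
        leaf = tree.leaf_labels[0]
        b = tree.leaf_id(leaf)
        return leaf, b

    def test_no_events_vertical_single_source(self, sim_tree20):
        leaf, _ = self._setup(sim_tree20)
        genes = {"bgc1": {"g1": ("famA", leaf), "g2": ("famB", leaf)}}
        df = bgc_gene_sources([], genes, sim_tree20, window_my=50)
        row = df.iloc[0]
        assert row.n_acquired_in_window == 0
        assert row.n_sources == 1
        assert not row.single_source

    def test_batch_transfer_single_source(self, sim_tree20):
        leaf, b = self._setup(sim_tree20)
        evs = [
            TransferEvent("famA", recipient=b, donor=None, time_my=3.0,
                          donor_category="within_clade"),
            TransferEvent("famB", recipient=b, donor=None, time_my=3.0,
                          donor_category="within_clade"),
        ]
        genes = {"bgc1": {"g1": ("famA", leaf), "g2": ("famB", leaf)}}
        df = bgc_gene_sources(evs, genes, sim_tree20, window_my=50)
        row = df.iloc[0]
        assert row.single_source
        assert row.fraction_acquired == 1.0

    def test_old_events_outside_window_ignored(self, sim_tree20):
        leaf, b = self._setup(sim_tree20)
        evs = [TransferEvent("famA", recipient=b, donor=None, time_my=80.0,
                             donor_category="within_clade")]
        genes = {"bgc1": {"g1": ("famA", leaf)}}
        df = bgc_gene_sources(evs, genes, sim_tree20, window_my=50)
        assert df.iloc[0].n_acquired_in_window == 0

    def test_ancestral_branch_events_count(self, sim_tree20):
        leaf = sim_tree20.leaf_labels[0]
        anc = sim_tree20.parent[sim_tree20.leaf_id(leaf)]
        if sim_tree20.parent[anc] is None:
            pytest.skip("leaf hangs off the root")
        t = float(sum(sim_tree20.branch_interval(anc)) / 2)
        evs = [TransferEvent("famA", recipient=anc, donor=None,
                             time_my=min(t, 49.0),
                             donor_category="cross_clade")]
        genes = {"bgc1": {"g1": ("famA", leaf)}}
        df = bgc_gene_sources(evs, genes, sim_tree20, window_my=50)
        assert df.iloc[0].n_acquired_in_window == 1


def test_bgc_tsv_roundtrip():
    clusters = [
        BGCluster("c1", "G1", ("d1", "d2", "d3")),
        BGCluster("c2", "G2", ("d3", "d2", "d1", "d4")),
    ]
    buf = io.StringIO()
    write_bgc_tsv(clusters, buf)
    buf.seek(0)
    assert read_bgc_tsv(buf) == clusters
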