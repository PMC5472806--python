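import io

import numpy as np
import pytest

from chronolgt.phylo_core import contemporaneous, parse_dated_newick
from chronolgt.synthetic_data import (
    SimConfig,
    simulate_bgc_families,
    simulate_codon_pair,
    simulate_dated_tree,
    simulate_gene_content,
)
from chronolgt.bgc_families import lin_similarity
from chronolgt.mutation_rates import alignment_counts, clock_rates


class TestDatedTreeSimulation:
    def test_two_taxa_is_a_full_depth_cherry(self):
        t = simulate_dated_tree(2, 100.0, seed=0)
        assert len(t.leaves) == 2
        for b in t.branches():
            assert t.branch_length(b) == pytest.approx(100.0)

    def test_deterministic_under_seed(self):
        a = simulate_dated_tree(20, 380.0, seed=1).to_newick()
        b = simulate_dated_tree(20, 380.0, seed=1).to_newick()
        assert a == b

    def test_output_passes_dated_tree_validation(self):
        t = simulate_dated_tree(20, 380.0, seed=1)
        reparsed = parse_dated_newick(t.to_newick())
        assert reparsed.root_age == pytest.approx(380.0, rel=1e-9)

    def test_clades_from_root_split(self):
        t = simulate_dated_tree(20, 380.0, seed=1)
        assert set(t.clade_map.values()) == {"I", "II"}
        for side, label in zip(t.children[t.root], ("I", "II")):
            assert {t.clade_map[g] for g in t.leaf_set(side)} == {label}

    def test_clade_split_depth_enforced(self):
        t = simulate_dated_tree(30, 380.0, seed=3, clade_split_depth=50)
        for side in t.children[t.root]:
            if not t.is_leaf(side):
                assert t.ages[side] <= 380.0 - 50 + 1e-6

    def test_min_taxa(self):
        with pytest.raises(ValueError):
            simulate_dated_tree(1, 100.0, seed=0)


class TestGeneContent:
    def test_no_transfer_process_no_transfer_records(self, sim_tree20):
        cfg = SimConfig(seed=3, n_taxa=20, root_age=100, transfer_rate=0.0,
                        n_families=50, clade_split_depth=10)
        _, log, _ = simulate_gene_content(sim_tree20, cfg)
        assert log.of_kind("transfer") == []

    def test_no_loss_root_family_fixes_everywhere(self, sim_tree20):
        cfg = SimConfig(seed=4, n_taxa=20, root_age=100, transfer_rate=0.0,
                        loss_rate=0.0, n_families=1, root_family_fraction=1.0,
                        clade_split_depth=10)
        matrix, _, _ = simulate_gene_content(sim_tree20, cfg)
        assert matrix.data.shape == (20, 1)
        assert (matrix.data == 1).all().all()

    def test_byte_identical_under_seed(self, sim_tree20):
        cfg = SimConfig(seed=5, n_taxa=20, root_age=100, n_families=100,
                        clade_split_depth=10)
        outs = []
        for _ in range(2):
            matrix, log, gts = simulate_gene_content(sim_tree20, cfg)
            m = io.StringIO()
            matrix.to_tsv(m)
            l = io.StringIO()
            log.to_tsv(l)
            outs.append((m.getvalue(), l.getvalue(), tuple(sorted(
                (k, v) for k, v in gts.items() if v))))
        assert outs[0] == outs[1]

    def test_transfers_connect_contemporaneous_branches(self, sim_content20,
                                                        sim_tree20):
        _, _, log, _ = sim_content20
        for r in log.of_kind("transfer"):
            assert contemporaneous(sim_tree20, r.donor, r.branch)
            hi, lo = sim_tree20.branch_interval(r.branch)
            assert lo < r.time_my < hi

    def test_transfer_count_within_poisson_bounds(self, sim_tree20):
        # expected arrivals = rate x total branch time; a few attempts fail
        # while a clade has a single lineage, so the observed count sits
        # between that and the full expectation
        rate = 0.05
        counts = []
        lam = rate * sum(sim_tree20.branch_length(b)
                         for b in sim_tree20.branches())
        for seed in range(5):
            cfg = SimConfig(seed=20 + seed, n_taxa=20, root_age=100,
                            transfer_rate=rate, loss_rate=0.005,
                            n_families=500, root_family_fraction=0.8,
                            clade_split_depth=10)
            _, log, _ = simulate_gene_content(sim_tree20, cfg)
            counts.append(len(log.of_kind("transfer"))
                          + log.n_skipped_transfers)
        total, lam_total = sum(counts), 5 * lam
        assert abs(total - lam_total) <= 3 * np.sqrt(lam_total)

    def test_gene_trees_match_matrix_presence(self, sim_content20):
        _, matrix, _, gts = sim_content20
        for fam in matrix.families:
            nwk = gts[fam]
            assert nwk is not None
            present = {g for g in matrix.genomes if matrix.data.loc[g, fam]}
            in_tree = {tok.split("|")[0] for tok in
                       nwk.replace("(", "").replace(")", "").rstrip(";").split(",")}
            assert in_tree == present

    def test_elevated_post_transfer_loss_erodes_old_transfers(self, sim_tree20):
        cfg = SimConfig(seed=6, n_taxa=20, root_age=100, transfer_rate=1.0,
                        loss_rate=0.02, post_transfer_loss_multiplier=10.0,
                        n_families=400, root_family_fraction=0.9,
                        clade_split_depth=10)
        _, log, _ = simulate_gene_content(sim_tree20, cfg)
        recs = log.of_kind("transfer")
        old = [r.detectable for r in recs if r.time_my > 20]
        young = [r.detectable for r in recs if r.time_my <= 5]
        assert np.mean(young) > np.mean(old) + 0.3

    def test_neutral_multiplier_keeps_retention_flat(self, sim_tree20):
        cfg = SimConfig(seed=7, n_taxa=20, root_age=100, transfer_rate=1.0,
                        loss_rate=0.005, post_transfer_loss_multiplier=1.0,
                        n_families=400, root_family_fraction=0.9,
                        clade_split_depth=10)
        _, log, _ = simulate_gene_content(sim_tree20, cfg)
        recs = log.of_kind("transfer")
        old = [r.detectable for r in recs if r.time_my > 20]
        young = [r.detectable for r in recs if r.time_my <= 5]
        assert abs(np.mean(young) - np.mean(old)) < 0.1


class TestCodonPair:
    def test_zero_time_identical(self):
        aln = simulate_codon_pair(100, 0.0, 1e-8, 1e-9, seed=0)
        assert aln.seqs[0] == aln.seqs[1]

    def test_no_stop_codons_produced(self):
        with pytest.warns(UserWarning, match="saturation"):
            aln = simulate_codon_pair(2000, 50.0, 5e-8, 5e-9, seed=1)
        from chronolgt.mutation_rates import STOP_CODONS

        for s in aln.seqs:
            codons = {s[i : i + 3] for i in range(0, len(s), 3)}
            assert not (codons & STOP_CODONS)

    def test_pure_nonsynonymous_process(self):
        # with the synonymous channel off, essentially all path-classified
        # differences are nonsynonymous (multi-hit codons can produce
        # fractional synonymous steps on inferred paths)
        aln = simulate_codon_pair(10000, 10.0, 0.0, 1e-8, seed=2)
        c = alignment_counts(aln, correction=False)
        assert c.Nd > 0
        assert c.Sd / (c.Sd + c.Nd) < 0.05

    def test_saturation_warning(self):
        with pytest.warns(UserWarning, match="saturation"):
            simulate_codon_pair(10, 100.0, 1e-7, 1e-8, seed=3)

    def test_rate_recovery_within_ten_percent(self):
        aln = simulate_codon_pair(20000, 10.0, 1.6e-8, 1.8e-9, seed=4)
        r = clock_rates(alignment_counts(aln, correction=True), 10.0)
        assert r.syn_rate == pytest.approx(1.6e-8, rel=0.10)
        assert r.nonsyn_rate == pytest.approx(1.8e-9, rel=0.10)


class TestBgcSimulation:
    def test_zero_mutation_members_identical(self, sim_tree20):
        cfg = SimConfig(seed=8, n_taxa=20, root_age=100, n_bgc_families=5,
                        domain_mutation_prob=0.0, clade_split_depth=10)
        clusters, fam_of, _ = simulate_bgc_families(sim_tree20, cfg)
        by_fam = {}
        for c in clusters:
            by_fam.setdefault(fam_of[c.cluster_id], []).append(c)
        for members in by_fam.values():
            for m in members[1:]:
                assert m.domains == members[0].domains
                assert lin_similarity(members[0], m) == 1.0

    def test_fully_restricted_families_form_clades(self, sim_tree20):
        cfg = SimConfig(seed=9, n_taxa=20, root_age=100, n_bgc_families=10,
                        restricted_fraction=1.0, clade_split_depth=10)
        clusters, fam_of, flags = simulate_bgc_families(sim_tree20, cfg)
        assert all(flags.values())
        clades = {
            frozenset(sim_tree20.leaf_set(v))
            for v in range(sim_tree20.n_nodes)
            if not sim_tree20.is_leaf(v)
        }
        fam_taxa = {}
        for c in clusters:
            fam_taxa.setdefault(fam_of[c.cluster_id], set()).add(c.genome_id)
        for taxa in fam_taxa.values():
            assert frozenset(taxa) in clades

    def test_short_archetype_rejected(self, sim_tree20):
        cfg = SimConfig(seed=10, archetype_length=2)
        with pytest.raises(ValueError, match="archetype_length"):
            simulate_bgc_families(sim_tree20, cfg)

    def test_deterministic(self, sim_tree20):
        cfg = SimConfig(seed=11, n_taxa=20, root_age=100, n_bgc_families=8,
                        clade_split_depth=10)
        a = simulate_bgc_families(sim_tree20, cfg)
        b = simulate_bgc_families(sim_tree20, cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]
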