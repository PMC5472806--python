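import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronolgt.phylo_core import TreeError, lca, parse_dated_newick
from chronolgt.lgt_rates import (
    TransferEvent,
    branch_rates,
    clade_rate,
    classify_events,
    donor_bias_table,
    fit_power_law,
    rate_table,
    read_events_tsv,
    write_events_tsv,
)


@pytest.fixture
def mixed_clade_tree():
    # C is labelled clade II although it nests with A, B: the branch above
    # (A,B,C)'s ancestor spans both clades and is therefore "mixed".
    t = parse_dated_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
    t.clade_map = {"A": "I", "B": "I", "C": "II", "D": "II", "E": "II"}
    return t


class TestClassification:
    def test_within_cross_and_ancestral_donors(self, mixed_clade_tree):
        t = mixed_clade_tree
        a, b, c = t.leaf_id("A"), t.leaf_id("B"), t.leaf_id("C")
        abc = lca(t, {"A", "B", "C"})
        evs = classify_events(
            [
                TransferEvent("f", recipient=a, donor=b, time_my=0.5),
                TransferEvent("f", recipient=a, donor=c, time_my=0.5),
                TransferEvent("f", recipient=a, donor=abc, time_my=2.2),
                TransferEvent("f", recipient=a, donor=None, time_my=0.5),
            ],
            t,
        )
        assert [e.donor_category for e in evs] == [
            "within_clade",
            "cross_clade",
            "other_lineage",
            "outgroup",
        ]

    def test_unknown_branch_rejected(self, mixed_clade_tree):
        with pytest.raises(TreeError, match="unknown"):
            classify_events(
                [TransferEvent("f", recipient=999, donor=None)], mixed_clade_tree
            )

    def test_category_counts_conserve_total(self, two_clade_tree):
        t = two_clade_tree
        rng = np.random.default_rng(0)
        branches = t.branches()
        evs = [
            TransferEvent(
                f"f{i}",
                recipient=int(rng.choice(branches)),
                donor=int(rng.choice(branches)),
                time_my=0.5,
            )
            for i in range(50)
        ]
        tab = rate_table(evs, t)
        for clade in ("I", "II"):
            sub = tab[tab.recipient_clade == clade]
            total = sub[sub.source == "total"]["n_events"].iloc[0]
            assert sub[sub.source != "total"]["n_events"].sum() == total


class TestCladeRate:
    def test_normalizations_consistent(self, two_clade_tree):
        t = two_clade_tree
        a, b = t.leaf_id("A"), t.leaf_id("B")
        evs = [TransferEvent("f", recipient=a, time_my=0.5)] * 3 + [
            TransferEvent("f", recipient=b, time_my=0.5)
        ]
        r = clade_rate(evs, t, "I")
        # clade I: branches A, B plus the stem of their ancestor
        assert r["n_branches"] == 3
        assert r["lca_age_my"] == pytest.approx(1.0)
        assert r["n_events"] == 4
        assert r["clade_total_rate_per_my"] == pytest.approx(4.0)
        assert r["per_node_rate_per_my"] == pytest.approx(4.0 / 3.0)
        # lineage time: two 1-my leaf branches + 2-my stem
        assert r["per_lineage_rate_per_my"] == pytest.approx(1.0)

    def test_stem_acquisitions_count_into_clade(self, two_clade_tree):
        t = two_clade_tree
        stem = lca(t, {"A", "B"})
        r = clade_rate([TransferEvent("f", recipient=stem, time_my=2.5)], t, "I")
        assert r["n_events"] == 1

    def test_zero_events_zero_rate(self, two_clade_tree):
        r = clade_rate([], two_clade_tree, "I")
        assert r["n_events"] == 0 and r["clade_total_rate_per_my"] == 0.0

    def test_singleton_clade_rejected(self, two_clade_tree):
        t = two_clade_tree
        t2 = parse_dated_newick(t.to_newick())
        t2.clade_map = {"A": "I", "B": "II", "C": "II", "D": "II"}
        with pytest.raises(TreeError, match="single genome"):
            clade_rate([], t2, "I")


class TestDonorBias:
    def test_perfectly_assorted_table(self, two_clade_tree):
        t = two_clade_tree
        a, b = t.leaf_id("A"), t.leaf_id("B")
        c, d = t.leaf_id("C"), t.leaf_id("D")
        evs = [TransferEvent("f", recipient=a, donor=b, time_my=0.5)] * 10 + [
            TransferEvent("f", recipient=c, donor=d, time_my=0.5)
        ] * 10
        tab, p = donor_bias_table(evs, t)
        assert tab.to_numpy().tolist() == [[10, 0], [0, 10]]
        # exact hypergeometric point mass: 2 / C(20, 10)
        assert p == pytest.approx(2.0 / 184756.0, rel=1e-9)

    def test_balanced_table_uninformative(self, two_clade_tree):
        t = two_clade_tree
        a, b = t.leaf_id("A"), t.leaf_id("B")
        c, d = t.leaf_id("C"), t.leaf_id("D")
        evs = (
            [TransferEvent("f", recipient=a, donor=b, time_my=0.5)] * 5
            + [TransferEvent("f", recipient=a, donor=c, time_my=0.5)] * 5
            + [TransferEvent("f", recipient=c, donor=b, time_my=0.5)] * 5
            + [TransferEvent("f", recipient=c, donor=d, time_my=0.5)] * 5
        )
        _, p = donor_bias_table(evs, t)
        assert p == pytest.approx(1.0)

    def test_empty_table_rejected(self, two_clade_tree):
        with pytest.raises(TreeError, match="no events"):
            donor_bias_table([], two_clade_tree)


class TestBranchRates:
    def test_rate_arithmetic(self, two_clade_tree):
        t = two_clade_tree
        c = t.leaf_id("C")  # 2-my branch
        evs = [TransferEvent("f", recipient=c, time_my=0.5)] * 5
        tab = branch_rates(evs, t).set_index("branch")
        assert tab.loc[c, "rate_per_my"] == pytest.approx(2.5)
        assert (tab.drop(index=c)["rate_per_my"] == 0).all()


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        lengths = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        rates = 2.0 * lengths**-0.5
        tab = pd.DataFrame(
            {"branch": range(6), "length_my": lengths,
             "n_events": rates * lengths, "rate_per_my": rates}
        )
        fit = fit_power_law(tab)
        assert fit.alpha == pytest.approx(-0.5, abs=1e-9)
        assert fit.c == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_rate_is_flat(self):
        tab = pd.DataFrame(
            {"branch": range(4), "length_my": [1.0, 2.0, 4.0, 8.0],
             "n_events": [1, 2, 4, 8], "rate_per_my": [1.0, 1.0, 1.0, 1.0]}
        )
        assert fit_power_law(tab).alpha == pytest.approx(0.0, abs=1e-12)

    def test_alpha_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(1)
        lengths = rng.uniform(0.5, 20, 30)
        rates = 3.0 * lengths**-0.7 * np.exp(rng.normal(0, 0.1, 30))
        tab = pd.DataFrame(
            {"branch": range(30), "length_my": lengths,
             "n_events": rates * lengths, "rate_per_my": rates}
        )
        f1 = fit_power_law(tab)
        tab2 = tab.copy()
        tab2["length_my"] *= 10.0
        tab2["rate_per_my"] /= 10.0
        f2 = fit_power_law(tab2)
        assert f2.alpha == pytest.approx(f1.alpha, abs=1e-9)

    def test_too_few_points_rejected(self):
        tab = pd.DataFrame(
            {"branch": [0, 1], "length_my": [1.0, 2.0],
             "n_events": [1, 1], "rate_per_my": [1.0, 0.5]}
        )
        with pytest.raises(ValueError, match=">=3"):
            fit_power_law(tab)


def test_events_tsv_roundtrip(two_clade_tree):
    t = two_clade_tree
    evs = [
        TransferEvent("f1", recipient=t.leaf_id("A"), donor=t.leaf_id("B"),
                      time_my=0.25, kind="simulated", detectable=True),
        TransferEvent("f2", recipient=t.leaf_id("C"), donor=None, time_my=1.5),
    ]
    buf = io.StringIO()
    write_events_tsv(evs, buf)
    buf.seek(0)
    back = read_events_tsv(buf)
    assert back[0].family == "f1" and back[0].donor == t.leaf_id("B")
    assert back[0].detectable is True
    assert back[1].donor is None and back[1].time_my == 1.5
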