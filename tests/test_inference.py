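"""Mann-Whitney U, Dollo loss counting, qPCR statistics, verdict classifier."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phagehgt import inference as inf


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def mwu_exact_oracle(g1, g2):
    """Two-tailed exact p by enumerating all C(n1+n2, n1) group labelings."""
    pooled = list(g1) + list(g2)
    n1 = len(g1)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(g1, g2)
    n2 = len(g2)
    mu = n1 * n2 / 2
    count = total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def dollo_brute_force(ptree: inf.PresenceTree) -> int:
    """Minimum loss count by enumerating all loss placements below the MRCA."""
    carriers = ptree.carriers
    mrca = (
        ptree.tree.mrca(taxon_labels=list(carriers))
        if len(carriers) > 1
        else [lf for lf in ptree.tree.leaf_node_iter() if lf.taxon.label in carriers][0]
    )
    nodes = list(mrca.preorder_iter())
    nodes = [n for n in nodes if n is not mrca]
    leaves = [lf for lf in mrca.leaf_iter()]
    best = math.inf
    for r in range(len(nodes) + 1):
        if r >= best:
            break
        for subset in itertools.combinations(nodes, r):
            lost = set()
            for n in subset:
                lost.update(lf.taxon.label for lf in n.leaf_iter())
            ok = all(
                (lf.taxon.label not in lost) == (lf.taxon.label in carriers)
                for lf in leaves
            )
            if ok:
                best = min(best, r)
                break
    return 0 if best is math.inf else best


def random_newick(labels, rng):
    labels = list(labels)
    rng.shuffle(labels)

    def build(ls):
        if len(ls) == 1:
            return ls[0]
        k = int(rng.integers(1, len(ls)))
        return f"({build(ls[:k])},{build(ls[k:])})"

    return build(labels) + ";"


class TestMannWhitney:
    def test_small_sample_exact_value(self):
        g = inf.mann_whitney_u([1, 2], [3, 4])
        assert g.u == 0
        assert g.p_two_tailed == pytest.approx(1 / 3)
        assert g.method == "exact"

    def test_identical_tied_groups(self):
        g = inf.mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert g.p_two_tailed == pytest.approx(1.0)
        assert g.method == "normal_approx"  # ties force the approximation
        assert g.tie_correction

    def test_exact_matches_enumeration_small_sizes(self):
        rng = np.random.default_rng(2)
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                vals = rng.permutation(100)[: n1 + n2].astype(float)
                g1, g2 = vals[:n1].tolist(), vals[n1:].tolist()
                got = inf.mann_whitney_u(g1, g2, mode="exact")
                assert got.p_two_tailed == pytest.approx(mwu_exact_oracle(g1, g2))

    def test_u_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g1 = rng.normal(size=8)
            g2 = rng.normal(size=11)
            g = inf.mann_whitney_u(g1, g2)
            assert 0 <= g.u <= len(g1) * len(g2)
            assert 0 < g.p_two_tailed <= 1

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError):
            inf.mann_whitney_u([1, 1], [2, 3], mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            inf.mann_whitney_u([], [1.0])

    def test_one_sided_alternative(self):
        g = inf.mann_whitney_u([1, 2, 3], [7, 8, 9], alternative="less")
        assert g.p_two_tailed < 0.1


class TestDollo:
    def make(self, newick, carriers):
        return inf.PresenceTree.from_newick(newick, carriers)

    def test_toy_tree_three_losses(self):
        pt = self.make("((A,B),(C,(D,E)));", ["A", "E"])
        assert inf.dollo_losses(pt) == 3

    def test_all_leaves_carriers(self):
        pt = self.make("((A,B),(C,D));", ["A", "B", "C", "D"])
        assert inf.dollo_losses(pt) == 0

    def test_single_carrier(self):
        pt = self.make("((A,B),(C,D));", ["B"])
        assert inf.dollo_losses(pt) == 0

    def test_zero_carriers_rejected(self):
        pt = self.make("((A,B),(C,D));", ["A"])
        pt.carriers = frozenset()
        with pytest.raises(ValueError):
            inf.dollo_losses(pt)

    def test_unknown_carrier_rejected(self):
        with pytest.raises(ValueError):
            self.make("((A,B),(C,D));", ["Z"])

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(8)]
        for trial in range(15):
            n_leaves = int(rng.integers(3, 9))
            nwk = random_newick(labels[:n_leaves], rng)
            k = int(rng.integers(1, n_leaves + 1))
            carriers = rng.choice(labels[:n_leaves], size=k, replace=False).tolist()
            pt = self.make(nwk, carriers)
            assert inf.dollo_losses(pt) == dollo_brute_force(pt)


class TestStandardCurve:
    def test_perfect_doubling_slope(self):
        c = inf.fit_standard_curve([(l, 38.0 - 3.3219 * l) for l in range(3, 8)])
        assert c.efficiency == pytest.approx(1.0, abs=1e-4)
        assert c.r_squared == pytest.approx(1.0)

    def test_noiseless_recovery(self):
        pts = [(l, 40.0 - 3.5 * l) for l in (3, 5, 7)]
        c = inf.fit_standard_curve(pts)
        assert c.slope == pytest.approx(-3.5)
        assert c.intercept == pytest.approx(40.0)
        assert c.copies(40.0 - 3.5 * 4) == pytest.approx(1e4)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            inf.fit_standard_curve([(3, 10), (4, 11), (5, 12)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            inf.fit_standard_curve([(3, 30), (4, 27)])

    def test_efficiency_band_under_noise(self):
        # triplicate standards, Ct noise sd 0.2: estimates stay in the
        # 96.6-104.4% amplification-efficiency band in nearly all runs
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = [
                (l, 38.0 - 3.3219 * l + rng.normal(0, 0.2))
                for l in range(3, 8)
                for _ in range(3)
            ]
            c = inf.fit_standard_curve(pts)
            hits += 0.966 <= c.efficiency <= 1.044
        assert hits >= 45


class TestCopyRatio:
    def test_exact_expected_ratio(self):
        r = inf.copy_ratio_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.t_statistic == 0.0 and r.p_two_tailed == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            inf.copy_ratio_test([1.0], [1.0])

    def test_zero_denominator_dropped(self, caplog):
        with caplog.at_level("WARNING", logger="phagehgt.inference"):
            r = inf.copy_ratio_test([2.0, 3.0, 4.0], [1.0, 0.0, 2.0])
        assert r.n == 2
        assert "dropped" in caplog.text

    def test_threefold_ratio_detected(self):
        found = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            den = 1e5 * np.exp(rng.normal(0, 0.07, size=9))
            num = 3.0 * 1e5 * np.exp(rng.normal(0, 0.07, size=9))
            r = inf.copy_ratio_test(num, den)
            if 2.7 <= r.ratio_mean <= 3.3 and r.p_two_tailed < 0.01:
                found += 1
        assert found >= 19


class TestPlateNormalization:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["plate", "gene", "replicate", "copies"])

    def test_single_plate_identity(self):
        df = self.frame([("p1", "cal", 1, 10.0), ("p1", "x", 1, 20.0)])
        out = inf.normalize_plate_effects(df, "cal")
        assert np.allclose(out["copies"], df["copies"])

    def test_twofold_offset_removed(self):
        df = self.frame(
            [("p1", "cal", 1, 10.0), ("p1", "x", 1, 30.0),
             ("p2", "cal", 1, 20.0), ("p2", "x", 1, 60.0)]
        )
        out = inf.normalize_plate_effects(df, "cal")
        cal_means = out[out["gene"] == "cal"].groupby("plate")["copies"].mean()
        assert np.allclose(cal_means, cal_means.iloc[0])
        x = out[out["gene"] == "x"].set_index("plate")["copies"]
        assert x["p1"] == pytest.approx(x["p2"])

    def test_missing_calibrator_rejected(self):
        df = self.frame([("p1", "cal", 1, 10.0), ("p2", "x", 1, 60.0)])
        with pytest.raises(ValueError, match="absent"):
            inf.normalize_plate_effects(df, "cal")


class TestClassifier:
    def evidence(self, cand_id=98.5, res_id=85.0, host_id=96.0,
                 cand_ds=0.07, res_ds=0.27, host_ds=0.10, n=8, tree=None, spread=1.0):
        rng = np.random.default_rng(1)
        mk = lambda m, s: rng.normal(m, s, size=n)  # noqa: E731
        return inf.TransferEvidence(
            candidate_identity=mk(cand_id, spread),
            resident_identity=mk(res_id, spread),
            host_identity=mk(host_id, spread),
            candidate_ds=mk(cand_ds, 0.01),
            resident_ds=mk(res_ds, 0.02),
            host_ds=mk(host_ds, 0.01),
            tree=tree,
        )

    def test_study_regime_is_recent_transfer(self):
        v = inf.classify_transfer(self.evidence())
        assert v.label == "recent_transfer"

    def test_missing_group_indeterminate(self):
        ev = self.evidence()
        ev.host_identity = np.array([])
        v = inf.classify_transfer(ev)
        assert v.label == "indeterminate"
        assert "host" in v.reason

    def test_no_separation_is_vertical(self):
        v = inf.classify_transfer(self.evidence(cand_id=90.0, res_id=90.0))
        assert v.label == "vertical_or_ancient"

    def test_loss_count_gate(self):
        # single-loss tree: carriers are sisters, zero losses below their MRCA
        pt = inf.PresenceTree.from_newick("((A,B),(C,D));", ["A", "B"])
        v = inf.classify_transfer(self.evidence(tree=pt))
        assert v.label == "indeterminate"
        assert "loss count" in v.reason

    def test_monotone_in_candidate_ds(self):
        base = self.evidence()
        v1 = inf.classify_transfer(base)
        assert v1.label == "recent_transfer"
        lower = self.evidence(cand_ds=0.01)
        v2 = inf.classify_transfer(lower)
        assert v2.label == "recent_transfer"  # decreasing dS never flips away

    def test_verdict_records_statistics(self):
        v = inf.classify_transfer(self.evidence())
        assert set(v.statistics["mean_identity"]) == {"candidate", "resident", "host"}
        assert v.statistics["n"]["candidate"] == 8
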