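"""Alignment, identity, trimming, homology screen, orthologs and synteny."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagehgt import seqcompare as sc
from phagehgt.simulate import simulate_gene_pair

PARAMS = sc.DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# exhaustive alignment oracle (independent of the aligner under test)
# ---------------------------------------------------------------------------


def brute_force_best_score(a: str, b: str, p: sc.AlignParams) -> float:
    """Enumerate every global alignment as an op string and score it."""

    def gap_cost(run: int) -> float:
        return p.gap_open + (run - 1) * p.gap_extend

    best = [-np.inf]

    def rec(i, j, score, gap_state, gap_run):
        if gap_state is not None:
            score_here = score + gap_cost(gap_run)
        else:
            score_here = score
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_here)
            return
        if i < len(a) and j < len(b):
            rec(
                i + 1,
                j + 1,
                score_here + (p.match if a[i] == b[j] else p.mismatch),
                None,
                0,
            )
        if i < len(a):  # gap in b
            if gap_state == "b":
                rec(i + 1, j, score, "b", gap_run + 1)
            else:
                rec(i + 1, j, score_here, "b", 1)
        if j < len(b):  # gap in a
            if gap_state == "a":
                rec(i, j + 1, score, "a", gap_run + 1)
            else:
                rec(i, j + 1, score_here, "a", 1)

    rec(0, 0, 0.0, None, 0)
    return best[0]


class TestGlobalAlign:
    def test_identity_case(self):
        aln = sc.global_align("ACGT", "ACGT")
        assert aln.score == 4 * PARAMS.match
        assert sc.percent_identity(aln) == 100.0

    def test_single_substitution(self):
        aln = sc.global_align("ACGT", "ACGA")
        assert sc.percent_identity(aln) == 75.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sc.global_align("", "ACGT")

    def test_gap_free_round_trip(self):
        aln = sc.global_align("ACGTACGT", "ACGTTACGT")
        assert aln.ungapped_a == "ACGTACGT"
        assert aln.ungapped_b == "ACGTTACGT"
        assert not any(
            x == "-" and y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
        )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="AC", min_size=1, max_size=6),
        b=st.text(alphabet="AC", min_size=1, max_size=6),
    )
    def test_score_matches_exhaustive_enumeration(self, a, b):
        aln = sc.global_align(a, b)
        assert aln.score == pytest.approx(brute_force_best_score(a, b, PARAMS))


class TestPercentIdentity:
    def test_gap_excluded_by_default(self):
        aln = sc.PairwiseAlignment("a", "b", "AC-GT", "ACTGT", 0)
        assert sc.percent_identity(aln) == 100.0

    def test_all_columns_mode(self):
        aln = sc.PairwiseAlignment("a", "b", "AC-GT", "ACTGT", 0)
        assert sc.percent_identity(aln, mode="all_columns") == 80.0

    def test_known_substitution_count(self, rng):
        L, k = 300, 17
        a = "".join(rng.choice(list("ACGT"), size=L))
        pos = rng.choice(L, size=k, replace=False)
        b = list(a)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        aln = sc.PairwiseAlignment("a", "b", a, "".join(b), 0)
        assert sc.percent_identity(aln) == pytest.approx(100.0 * (L - k) / L)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=120))
        b = "".join(rng.choice(list("ACGT"), size=110))
        f = sc.global_align(a, b)
        r = sc.global_align(b, a)
        assert sc.percent_identity(f) == pytest.approx(sc.percent_identity(r))

    def test_zero_columns_is_error(self):
        aln = sc.PairwiseAlignment("a", "b", "A-", "-A", 0)
        with pytest.raises(ValueError):
            sc.percent_identity(aln)


class TestTrimConservedBlocks:
    def test_gapless_identical_unchanged(self):
        s = "ACGTACGTACGTACG"
        aln = sc.PairwiseAlignment("a", "b", s, s, 0)
        trimmed = sc.trim_conserved_blocks(aln)
        assert trimmed.aligned_a == s and trimmed.aligned_b == s

    def test_gappy_island_removed(self):
        # 12 conserved + 5 gap columns + 12 conserved
        left, right = "ACGTACGTACGT", "TTTTGGGGCCCC"
        a = left + "-----" + right
        b = left + "AAAAA" + right
        trimmed = sc.trim_conserved_blocks(aln := sc.PairwiseAlignment("a", "b", a, b, 0))
        assert trimmed.aligned_a == left + right
        assert trimmed.aligned_b == left + right
        assert len(trimmed) < len(aln)

    def test_min_block_len_larger_than_alignment(self, caplog):
        aln = sc.PairwiseAlignment("a", "b", "ACGT", "ACGT", 0)
        with caplog.at_level("WARNING", logger="phagehgt.seqcompare"):
            trimmed = sc.trim_conserved_blocks(aln, min_block_len=10)
        assert len(trimmed) == 0
        assert "removed" in caplog.text

    def test_unconserved_block_removed(self):
        a = "ACGTACGTACGT" + "AAAAAAAAAAAA"
        b = "ACGTACGTACGT" + "CCCCCCCCCCCC"
        # second block is gap-free but 0% conserved: only when split by a gap
        a += "-" + "ACGTACGTACGT"
        b += "T" + "ACGTACGTACGT"
        trimmed = sc.trim_conserved_blocks(
            sc.PairwiseAlignment("a", "b", a, b, 0), min_block_len=10
        )
        # the first 24 columns form one block at 50% conservation (kept);
        # the trailing 12 identical columns form their own block (kept)
        assert len(trimmed) == 36


class TestHomologySearch:
    def test_self_hit_far_below_cutoff(self, rng):
        db = {f"g{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(10)}
        hits = sc.search_homologs({"q": db["g3"]}, db)
        assert hits and hits[0].subject_id == "g3"
        assert hits[0].expect < 1e-50
        assert hits[0].identity == 100.0

    def test_planted_homolog_recovered_among_decoys(self, rng):
        db = {f"g{i}": "".join(rng.choice(list("ACGT"), 500)) for i in range(100)}
        target = list(db["g42"])
        for p in rng.choice(500, size=100, replace=False):  # 80% identity
            target[p] = str(rng.choice([b for b in "ACGT" if b != target[p]]))
        hits = sc.search_homologs({"q": "".join(target)}, db)
        assert hits and hits[0].subject_id == "g42"

    def test_unrelated_queries_find_nothing(self, rng):
        db = {f"g{i}": "".join(rng.choice(list("ACGT"), 500)) for i in range(50)}
        for seed in range(20):
            r = np.random.default_rng(10_000 + seed)
            q = "".join(r.choice(list("ACGT"), 500))
            assert sc.search_homologs({"q": q}, db) == []

    def test_hits_sorted_by_expect(self, rng):
        db = {f"g{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(5)}
        db["copy"] = db["g0"]
        hits = sc.search_homologs({"q": db["g0"]}, db)
        assert [h.expect for h in hits] == sorted(h.expect for h in hits)

    def test_empty_database_warns(self, caplog):
        with caplog.at_level("WARNING", logger="phagehgt.seqcompare"):
            assert sc.search_homologs({"q": "ACGTACGT"}, {}) == []
        assert "empty" in caplog.text


class TestPresenceMatrix:
    def _genomes(self, rng, n=10):
        genomes = {
            f"G{i}": {f"G{i}_g{j}": "".join(rng.choice(list("ACGT"), 400)) for j in range(4)}
            for i in range(n)
        }
        return genomes

    def test_planted_in_two_of_ten(self, rng):
        genomes = self._genomes(rng)
        query = "".join(rng.choice(list("ACGT"), 450))
        genomes["G2"]["G2_planted"] = query
        genomes["G7"]["G7_planted"] = query
        m = sc.presence_matrix({"q": query}, genomes)
        assert m["q"].sum() == 2
        assert set(m.index[m["q"]]) == {"G2", "G7"}

    def test_core_gene_present_everywhere(self, rng):
        genomes = self._genomes(rng, 5)
        core = "".join(rng.choice(list("ACGT"), 450))
        for g in genomes.values():
            g["core"] = core
        m = sc.presence_matrix({"q": core}, genomes)
        assert m["q"].all()

    def test_absent_query_all_false(self, rng):
        genomes = self._genomes(rng, 5)
        q = "".join(np.random.default_rng(999).choice(list("ACGT"), 450))
        m = sc.presence_matrix({"q": q}, genomes)
        assert not m["q"].any()

    def test_monotone_in_cutoff(self, rng):
        genomes = self._genomes(rng, 5)
        query = genomes["G1"]["G1_g0"]
        strict = sc.presence_matrix({"q": query}, genomes, evalue_cutoff=1e-30)
        loose = sc.presence_matrix({"q": query}, genomes, evalue_cutoff=1e-3)
        assert (loose["q"] | ~strict["q"]).all()  # strict present => loose present


class TestOrthologsAndSynteny:
    def test_identical_sets_pair_perfectly(self, rng):
        genes = {f"g{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(5)}
        pairs, ua, ub = sc.pair_orthologs(genes, dict(genes))
        assert len(pairs) == 5 and not ua and not ub
        assert all(p.percent_identity == 100.0 for p in pairs)

    def test_deleted_gene_left_unpaired(self, rng):
        a = {f"g{i}": "".join(rng.choice(list("ACGT"), 150)) for i in range(4)}
        b = {k: v for k, v in a.items() if k != "g2"}
        pairs, ua, ub = sc.pair_orthologs(a, b)
        assert ua == ["g2"] and ub == []
        assert {p.gene_a for p in pairs} == {"g0", "g1", "g3"}

    def test_simulated_truth_map_recovered(self):
        rng = np.random.default_rng(5)
        a, b = {}, {}
        for i in range(10):
            sa, sb, _ = simulate_gene_pair(300, 0.10, seed=rng)
            a[f"a{i}"] = sa
            b[f"b{i}"] = sb
        pairs, _, _ = sc.pair_orthologs(a, b)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (f"a{i}", f"b{i}") for i in range(10)
        }

    def test_synteny_identity(self, rng):
        genes = {f"g{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(6)}
        pairs, _, _ = sc.pair_orthologs(genes, dict(genes))
        rep = sc.find_synteny(pairs, list(genes), list(genes))
        assert len(rep.blocks) == 1
        assert rep.blocks[0].orientation == 1
        assert rep.discrepant_regions == []

    def test_internal_deletion_is_one_discrepant_region(self, rng):
        order_a = [f"g{i}" for i in range(12)]
        deleted = set(order_a[4:9])
        order_b = [g for g in order_a if g not in deleted]
        pairs = [sc.OrthologPair(g, g, 100.0, 100, 0) for g in order_b]
        rep = sc.find_synteny(pairs, order_a, order_b)
        assert len(rep.blocks) == 1
        regions = [r for r in rep.discrepant_regions if r.side == "a"]
        assert len(regions) == 1 and regions[0].genes == order_a[4:9]

    def test_inversion_splits_blocks_with_orientation(self):
        order_a = [f"g{i}" for i in range(8)]
        order_b = order_a[:3] + list(reversed(order_a[3:6])) + order_a[6:]
        pairs = [sc.OrthologPair(g, g, 100.0, 100, 0) for g in order_a]
        rep = sc.find_synteny(pairs, order_a, order_b)
        orientations = [b.orientation for b in rep.blocks]
        assert -1 in orientations and 1 in orientations

    def test_partition_is_exact(self, rng):
        # random pairing subset: every gene in exactly one block or one region
        order_a = [f"a{i}" for i in range(15)]
        order_b = [f"b{i}" for i in range(15)]
        perm = rng.permutation(15)
        paired = sorted(rng.choice(15, size=9, replace=False).tolist())
        pairs = [
            sc.OrthologPair(order_a[i], order_b[perm[i]], 90.0, 50, 0) for i in paired
        ]
        rep = sc.find_synteny(pairs, order_a, order_b)
        in_blocks_a = [p.gene_a for b in rep.blocks for p in b.pairs]
        in_blocks_b = [p.gene_b for b in rep.blocks for p in b.pairs]
        private = [g for r in rep.discrepant_regions for g in r.genes]
        all_seen = in_blocks_a + in_blocks_b + private
        assert sorted(all_seen) == sorted(order_a + order_b)
        assert len(all_seen) == len(set(all_seen))
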