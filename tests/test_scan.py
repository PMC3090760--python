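"""Scanning, threshold metrics, pAUC and synthetic fixtures."""

import numpy as np
import pytest

from rsalign.core import RnaSequence, ScoringScheme, SecondaryStructure
from rsalign.engine import align_local
from rsalign.scan import (
    FixtureSpec,
    attribute_scores,
    evaluate_thresholds,
    make_fixture,
    mutate_member,
    partial_auc,
    random_hairpin_family,
    random_regular_structure,
    scan,
    window_length_rule,
)

S = ScoringScheme.default()


class TestWindowLengthRule:
    @pytest.mark.parametrize(
        "lengths,pad,expected", [([87, 90, 94], 20, 114), ([26], 20, 46), ([100], 0, 100)]
    )
    def test_rule(self, lengths, pad, expected):
        assert window_length_rule(lengths, pad) == expected

    def test_empty_list(self):
        with pytest.raises(ValueError):
            window_length_rule([])


class TestScan:
    def test_exact_copy_recovers_self_score(self):
        q = RnaSequence("q", "GGGAAACCC")
        st = SecondaryStructure([(i, 10 - i) for i in range(1, 4)], 9)
        genome = RnaSequence("g", "ACGU" * 3 + q.residues + "UGCA" * 3)
        self_score = align_local(q, st, q, S).score
        records = scan(q, st, genome, window_len=9, scheme=S)
        assert max(r.score for r in records) == self_score
        best = max(records, key=lambda r: r.score)
        assert best.window_start == 13

    def test_record_count_at_step_one(self):
        q = RnaSequence("q", "ACGU")
        genome = RnaSequence("g", "ACGU" * 10)
        records = scan(q, SecondaryStructure([], 4), genome, window_len=10, scheme=S)
        assert len(records) == len(genome) - 10 + 1

    def test_local_floor_on_decoys(self):
        q = RnaSequence("q", "AAAA")
        genome = RnaSequence("g", "CCCCCCCCCC")
        records = scan(q, SecondaryStructure([], 4), genome, window_len=5, scheme=S)
        assert all(r.score == 0.0 for r in records)

    def test_truncated_window_warns(self):
        q = RnaSequence("q", "ACGU")
        genome = RnaSequence("g", "ACG")
        with pytest.warns(UserWarning, match="truncated"):
            records = scan(q, SecondaryStructure([], 4), genome, window_len=10, scheme=S)
        assert len(records) == 1
        assert records[0].window_end == 3

    def test_shift_invariance(self):
        # translating an embedded member shifts its best window, same score
        rng = np.random.default_rng(0)
        q, st, members = random_hairpin_family(1, stem=5, loop=6, seed=4)
        member = members[0]
        bg = "".join("ACGU"[c] for c in rng.integers(0, 4, size=60))
        for offset in (10, 17):
            genome = RnaSequence("g", bg[:offset] + member.residues + bg[offset:])
            records = scan(q, st, genome, window_len=len(member) + 4, scheme=S, step=1)
            best = max(records, key=lambda r: r.score)
            if offset == 10:
                first = (best.window_start, best.score)
        assert best.window_start == first[0] + 7
        assert best.score == first[1]


class TestEvaluateThresholds:
    def test_perfect_separation(self):
        m = evaluate_thresholds([10, 9, 8], [5, 4])
        assert m["zero_fp_threshold"] == 5
        assert m["misses_zero_fp"] == 0
        assert m["pauc"] == 1.0

    def test_single_miss(self):
        m = evaluate_thresholds([3], [5])
        assert m["misses_zero_fp"] == 1

    def test_identical_lists_pauc_matches_rank_oracle(self):
        real = [1.0, 2.0]
        false = [1.0, 2.0]
        m = evaluate_thresholds(real, false)
        assert m["pauc"] == pytest.approx(_pauc_rank_oracle(real, false, 0.1))

    def test_random_pauc_matches_rank_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            real = list(np.round(rng.normal(1, 1, size=rng.integers(1, 20)), 2))
            false = list(np.round(rng.normal(0, 1, size=rng.integers(1, 20)), 2))
            got = partial_auc(real, false, 0.1)
            assert got == pytest.approx(_pauc_rank_oracle(real, false, 0.1), abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        real = list(rng.normal(1, 1, size=15))
        false = list(rng.normal(0, 1, size=25))
        m1 = evaluate_thresholds(real, false)
        f = lambda v: np.exp(v) + 3 * v  # strictly monotone
        m2 = evaluate_thresholds([f(v) for v in real], [f(v) for v in false])
        assert m1["misses_zero_fp"] == m2["misses_zero_fp"]
        assert m1["pauc"] == pytest.approx(m2["pauc"])
        for level in m1["levels"]:
            assert m1["levels"][level]["misses"] == m2["levels"][level]["misses"]

    def test_fpr_levels(self):
        false = list(range(100))  # scores 0..99
        real = [95.5] * 10
        m = evaluate_thresholds(real, false, fpr_levels=[0.05, 0.10])
        # at threshold 94, scores > 94 are 95..99: 5% FPR
        assert m["levels"][0.05]["threshold"] == 94
        assert m["levels"][0.05]["misses"] == 0
        assert m["levels"][0.10]["threshold"] == 89
        assert m["zero_fp_threshold"] == 99
        assert m["misses_zero_fp"] == 10

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            evaluate_thresholds([], [1.0])
        with pytest.raises(ValueError):
            evaluate_thresholds([1.0], [])

    def test_pauc_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            real = list(rng.normal(0, 1, size=10))
            false = list(rng.normal(0, 1, size=10))
            assert 0.0 <= partial_auc(real, false) <= 1.0
        # full separation gives exactly 1
        assert partial_auc([2.0], [1.0]) == 1.0


def _pauc_rank_oracle(real, false, fpr_max):
    """Direct Mann-Whitney-style pAUC restricted to FPR <= fpr_max.

    Integrates the empirical ROC exactly by stepping through false scores in
    descending order (each unique false value advances FPR) and linearly
    interpolating TPR within tied blocks -- equivalent to the trapezoid over
    operating points.
    """
    nf = len(false)
    pts = [(0.0, 0.0)]
    for t in sorted(set(real) | set(false), reverse=True):
        fpr = sum(1 for v in false if v > t) / nf
        tpr = sum(1 for v in real if v > t) / len(real)
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2
        elif x0 < fpr_max:
            yc = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            area += (fpr_max - x0) * (y0 + yc) / 2
    return area / fpr_max


class TestFixture:
    def _members(self, seed=0, n=5):
        _, _, members = random_hairpin_family(n, stem=5, loop=6, seed=seed)
        return members

    def test_genome_length_and_truth(self):
        members = self._members()
        genome, truth = make_fixture(FixtureSpec(members=members, seed=1))
        total = sum(len(m) for m in members)
        assert len(genome) == 10 * total
        assert len(truth) == len(members)
        for (a, b), mem in zip(truth, members):
            assert genome.substring(a, b) == mem.residues

    def test_truth_disjoint_and_in_bounds(self):
        members = self._members(seed=2, n=8)
        genome, truth = make_fixture(FixtureSpec(members=members, seed=3))
        prev_end = 0
        for a, b in truth:
            assert a > prev_end
            assert 1 <= a <= b <= len(genome)
            prev_end = b

    def test_determinism(self):
        members = self._members(seed=4)
        g1, t1 = make_fixture(FixtureSpec(members=members, seed=7))
        g2, t2 = make_fixture(FixtureSpec(members=members, seed=7))
        assert g1.residues == g2.residues
        assert t1 == t2

    def test_member_cap(self):
        members = self._members(seed=5, n=12)
        genome, truth = make_fixture(FixtureSpec(members=members, max_members=10, seed=8))
        assert len(truth) == 10

    def test_factor_too_small(self):
        members = self._members(seed=6)
        with pytest.raises(ValueError):
            make_fixture(FixtureSpec(members=members, genome_length_factor=0.5, seed=9))


class TestMutateMember:
    def _family(self):
        q, st, _ = random_hairpin_family(1, stem=6, loop=8, seed=11)
        return q, st

    def test_identity_when_rates_zero(self):
        q, st = self._family()
        mut = mutate_member(q, st, point_rate=0.0, loop_indel_max=0, seed=1)
        assert mut.residues == q.residues

    def test_compensatory_mutations_stay_complementary(self):
        from rsalign.core import COMPLEMENTARY_PAIRS

        q, st = self._family()
        mut = mutate_member(q, st, point_rate=1.0, loop_indel_max=0, seed=2)
        assert len(mut) == len(q)
        for i, j in st.pairs:
            assert (mut.base(i), mut.base(j)) in COMPLEMENTARY_PAIRS

    def test_deterministic(self):
        q, st = self._family()
        m1 = mutate_member(q, st, 0.2, 3, seed=5)
        m2 = mutate_member(q, st, 0.2, 3, seed=5)
        assert m1.residues == m2.residues

    def test_indel_bounded_and_in_loop(self):
        q, st = self._family()
        for seed in range(10):
            mut = mutate_member(q, st, point_rate=0.0, loop_indel_max=4, seed=seed)
            assert abs(len(mut) - len(q)) <= 4


class TestAttribution:
    def test_real_and_false_split(self):
        from rsalign.scan import ScanRecord

        truth = [(11, 20)]
        records = [
            ScanRecord(1, 10, 1.0, 0.0),    # no overlap: decoy
            ScanRecord(8, 17, 9.0, 0.0),    # 7/10 overlap: real
            ScanRecord(16, 25, 7.0, 0.0),   # 5/10 overlap: real
            ScanRecord(21, 30, 2.0, 0.0),   # touches but 0 overlap frac: decoy
        ]
        real, false = attribute_scores(records, truth)
        assert real == [9.0]
        assert sorted(false) == [1.0, 2.0]

    def test_structure_generator_regularity(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            m = int(rng.integers(0, 50))
            random_regular_structure(m, rng)  # constructor validates
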