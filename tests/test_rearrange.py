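"""DCJ distance, scenarios, block numbering and distance summaries."""

from __future__ import annotations

import random
import warnings
from collections import Counter, deque

import numpy as np
import pytest

from karyoevo.core_io import Genome, SignedGenome
from karyoevo.rearrange import (
    _genome_adjacencies,
    _rc,
    blocks_to_signed_genomes,
    mcd_summary,
    rearrangement_distance,
    replay_scenario,
    sort_scenario,
)
from karyoevo.synteny import SyntenyBlock

from conftest import linear_genome


# --------------------------------------------------------------------------
# Independent BFS oracle over adjacency matchings (any DCJ move allowed)
# --------------------------------------------------------------------------


def _adjset(g: SignedGenome) -> frozenset:
    adj, _ = _genome_adjacencies(g)
    return frozenset(adj)


def _neighbors(state: frozenset, exts: list) -> set:
    in_adj = {}
    for x, y in state:
        in_adj[x] = (x, y)
        in_adj[y] = (x, y)
    tel = [e for e in exts if e not in in_adj]
    elems = list(state)
    out = set()
    for i in range(len(elems)):
        for j in range(i + 1, len(elems)):
            (p, x), (q, y) = elems[i], elems[j]
            for n1, n2 in (((p, q), (x, y)), ((p, y), (x, q))):
                ns = set(state)
                ns.discard(elems[i])
                ns.discard(elems[j])
                ns.add(tuple(sorted(n1)))
                ns.add(tuple(sorted(n2)))
                out.add(frozenset(ns))
    for e in elems:
        p, x = e
        for t in tel:
            for keep in ((p, t), (x, t)):
                ns = set(state)
                ns.discard(e)
                ns.add(tuple(sorted(keep)))
                out.add(frozenset(ns))
        ns = set(state)
        ns.discard(e)
        out.add(frozenset(ns))
    for i in range(len(tel)):
        for j in range(i + 1, len(tel)):
            ns = set(state)
            ns.add(tuple(sorted((tel[i], tel[j]))))
            out.add(frozenset(ns))
    return out


def bfs_distance(a: SignedGenome, b: SignedGenome) -> int:
    """Bidirectional breadth-first search over genome states; the slow,
    assumption-free minimum."""
    markers = sorted(a.markers)
    exts = [(m, s) for m in markers for s in (0, 1)]
    s0, s1 = _adjset(a), _adjset(b)
    if s0 == s1:
        return 0
    fa, fb = {s0: 0}, {s1: 0}
    qa, qb = deque([s0]), deque([s1])
    while qa and qb:
        q, fme, fother = (qa, fa, fb) if len(qa) <= len(qb) else (qb, fb, fa)
        for _ in range(len(q)):
            s = q.popleft()
            for ns in _neighbors(s, exts):
                if ns in fme:
                    continue
                fme[ns] = fme[s] + 1
                if ns in fother:
                    return fme[ns] + fother[ns]
                q.append(ns)
    raise RuntimeError("search exhausted")


def random_signed_genome(rng: random.Random, n: int, max_chroms: int = 2) -> SignedGenome:
    ms = [m if rng.random() < 0.5 else -m for m in range(1, n + 1)]
    rng.shuffle(ms)
    k = rng.randint(1, min(max_chroms, n))
    cuts = sorted(rng.sample(range(1, n), k - 1)) if k > 1 else []
    chroms, prev = [], 0
    for c in cuts + [n]:
        chroms.append(ms[prev:c])
        prev = c
    return SignedGenome([c for c in chroms if c])


class TestDistance:
    def test_identical_genomes_distance_zero(self):
        g = SignedGenome([[1, 2, 3], [4, 5]])
        assert rearrangement_distance(g, SignedGenome([[1, 2, 3], [4, 5]])) == 0

    def test_reflection_and_chromosome_order_are_free(self):
        a = SignedGenome([[1, 2, 3], [4, 5]])
        b = SignedGenome([[4, 5], [-3, -2, -1]])
        assert rearrangement_distance(a, b) == 0

    def test_single_inversion(self):
        assert (
            rearrangement_distance(
                SignedGenome([[1, 2, 3]]), SignedGenome([[1, -2, 3]])
            )
            == 1
        )

    def test_single_translocation(self):
        a = SignedGenome([[1, 2, 3], [4, 5]])
        b = SignedGenome([[1, 2, 5], [4, 3]])
        assert rearrangement_distance(a, b) == 1

    def test_marker_set_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="only in b=\\[4\\]"):
            rearrangement_distance(
                SignedGenome([[1, 2, 3]]), SignedGenome([[1, 2, 4]])
            )

    def test_matches_bfs_on_random_small_instances(self):
        rng = random.Random(42)
        for _ in range(60):
            n = rng.randint(3, 6)
            a = random_signed_genome(rng, n)
            b = random_signed_genome(rng, n)
            assert rearrangement_distance(a, b) == bfs_distance(a, b)

    def test_metric_properties_on_random_triples(self):
        rng = random.Random(7)
        for _ in range(60):
            n = rng.randint(4, 8)
            a, b, c = (random_signed_genome(rng, n) for _ in range(3))
            dab = rearrangement_distance(a, b)
            assert dab == rearrangement_distance(b, a)
            assert rearrangement_distance(a, a) == 0
            assert dab <= rearrangement_distance(a, c) + rearrangement_distance(c, b)


class TestScenario:
    def test_identical_genomes_empty_scenario(self):
        g = SignedGenome([[1, 2, 3]])
        assert sort_scenario(g, SignedGenome([[1, 2, 3]])) == []

    def test_single_inversion_typed(self):
        ops = sort_scenario(
            SignedGenome([[1, 2, 3]]), SignedGenome([[1, -2, 3]])
        )
        assert [o.kind for o in ops] == ["inversion"]

    def test_single_translocation_typed(self):
        ops = sort_scenario(
            SignedGenome([[1, 2, 3], [4, 5]]), SignedGenome([[1, 2, 5], [4, 3]])
        )
        assert [o.kind for o in ops] == ["translocation"]

    def test_fusion_and_fission_typed(self):
        a = SignedGenome([[1, 2], [3, 4]])
        b = SignedGenome([[1, 2, 3, 4]])
        assert [o.kind for o in sort_scenario(a, b)] == ["fusion"]
        assert [o.kind for o in sort_scenario(b, a)] == ["fission"]

    def test_replay_reaches_target_with_length_equal_distance(self):
        rng = random.Random(99)
        for _ in range(100):
            n = rng.randint(3, 8)
            a = random_signed_genome(rng, n)
            b = random_signed_genome(rng, n)
            d = rearrangement_distance(a, b)
            ops = sort_scenario(a, b)
            assert len(ops) == d
            got = replay_scenario(a, ops)
            assert got.canonical().chromosomes == b.canonical().chromosomes

    def test_planted_independent_history_recovers_type_multiset(self, rng):
        # 3 inversions on chr1-3 interiors + 2 straight translocations on
        # chromosome pairs whose cut regions no other operation touches
        for seed in range(20):
            r = random.Random(seed)
            chroms = [list(range(1 + 10 * i, 11 + 10 * i)) for i in range(6)]
            a = SignedGenome([list(c) for c in chroms])
            for ci in (0, 1, 2):
                l = r.randint(1, 3)
                rr = r.randint(l + 1, 6)
                c = chroms[ci]
                chroms[ci] = c[:l] + _rc(c[l:rr]) + c[rr:]
            i, j, p, q = 3, 4, r.randint(1, 9), r.randint(1, 9)
            chroms[i], chroms[j] = (
                chroms[i][:p] + chroms[j][q:],
                chroms[j][:q] + chroms[i][p:],
            )
            i, j, p, q = 5, 0, r.randint(1, 9), r.randint(8, 9)
            chroms[i], chroms[j] = (
                chroms[i][:p] + chroms[j][q:],
                chroms[j][:q] + chroms[i][p:],
            )
            b = SignedGenome(chroms)
            ops = sort_scenario(a, b)
            assert len(ops) == rearrangement_distance(a, b) == 5
            assert Counter(o.kind for o in ops) == {
                "inversion": 3,
                "translocation": 2,
            }


class TestBlocksToSignedGenomes:
    def _fixture(self):
        ga = linear_genome("ga", {"A1": [], "A2": []}, length=100_000)
        gb = linear_genome("gb", {"B1": [], "B2": []}, length=100_000)
        return ga, gb

    def _blk(self, bid, ca, sa, cb, sb, sign):
        return SyntenyBlock(bid, ca, cb, sa, sb, sign, anchors=[None] * 3)

    def test_collinear_blocks_give_identity(self):
        ga, gb = self._fixture()
        blocks = [
            self._blk(1, "A1", (0, 10_000), "B1", (0, 10_000), "+"),
            self._blk(2, "A1", (20_000, 30_000), "B1", (20_000, 30_000), "+"),
            self._blk(3, "A2", (0, 10_000), "B2", (0, 10_000), "+"),
        ]
        sga, sgb = blocks_to_signed_genomes(blocks, ga, gb)
        assert sga.chromosomes == [[1, 2], [3]]
        assert sgb.chromosomes == [[1, 2], [3]]

    def test_one_inverted_block_gets_negative_marker(self):
        ga, gb = self._fixture()
        blocks = [
            self._blk(1, "A1", (0, 10_000), "B1", (0, 10_000), "+"),
            self._blk(2, "A1", (20_000, 30_000), "B1", (20_000, 30_000), "-"),
        ]
        _, sgb = blocks_to_signed_genomes(blocks, ga, gb)
        assert sgb.chromosomes == [[1, -2]]

    def test_shuffled_fixture_matches_hand_computed_orders(self):
        # six blocks: A-order 1..6; on B they interleave across chromosomes
        # hand enumeration: B1 carries blocks 1,4(-),5; B2 carries 3,2(-),6
        ga, gb = self._fixture()
        blocks = [
            self._blk(1, "A1", (0, 10_000), "B1", (0, 10_000), "+"),
            self._blk(2, "A1", (20_000, 30_000), "B2", (30_000, 40_000), "-"),
            self._blk(3, "A1", (40_000, 50_000), "B2", (0, 10_000), "+"),
            self._blk(4, "A2", (0, 10_000), "B1", (20_000, 30_000), "-"),
            self._blk(5, "A2", (20_000, 30_000), "B1", (40_000, 50_000), "+"),
            self._blk(6, "A2", (40_000, 50_000), "B2", (60_000, 70_000), "+"),
        ]
        sga, sgb = blocks_to_signed_genomes(blocks, ga, gb)
        assert sga.chromosomes == [[1, 2, 3], [4, 5, 6]]
        assert sgb.chromosomes == [[1, -4, 5], [3, -2, 6]]

    def test_block_on_unknown_genome_is_hard_error(self):
        ga, gb = self._fixture()
        blk = self._blk(1, "A1", (0, 1_000), "NOPE", (0, 1_000), "+")
        with pytest.raises(ValueError, match="NOPE"):
            blocks_to_signed_genomes([blk], ga, gb)


class TestMCDSummary:
    def test_close_pair_row(self):
        # 46 total changes, 11 gross, 3 chromosomes
        s = mcd_summary(46, 11, 3)
        assert s.per_chromosome_all == 15.33
        assert s.per_chromosome_gross == 3.67
        assert s.gross_over_all_pct == 24

    def test_distant_pair_row(self):
        s = mcd_summary(150, 63, 3)
        assert s.per_chromosome_all == 50.00
        assert s.per_chromosome_gross == 21.00
        assert s.gross_over_all_pct == 42

    def test_many_chromosome_rows_round_half_away_from_zero(self):
        s = mcd_summary(72, 5, 16)
        assert (s.per_chromosome_all, s.per_chromosome_gross) == (4.50, 0.31)
        assert s.gross_over_all_pct == 7
        s2 = mcd_summary(607, 102, 16)
        # 102/16 = 6.375 -> 6.38 under half-away-from-zero
        assert (s2.per_chromosome_all, s2.per_chromosome_gross) == (37.94, 6.38)
        assert s2.gross_over_all_pct == 17

    def test_zero_changes_degenerate_input_warns(self):
        with pytest.warns(UserWarning):
            s = mcd_summary(0, 0, 3, 10.0)
        assert s.gross_over_all_pct == 0
        assert s.per_mb_all == 0.0

    def test_per_mb_uses_genome_size(self):
        s = mcd_summary(46, 11, 3, genome_size_mb=11.586)
        assert s.per_mb_all == 3.97
        assert s.per_mb_gross == 0.95


class TestSignDiscordanceGrowsWithInversions:
    def test_discordant_marker_count_non_decreasing_in_expectation(self):
        # more inversions between two genomes leave more markers on the
        # opposite strand, mirroring the rise of inverted segments with
        # phylogenetic distance
        from karyoevo.simulate import evolve_signed, identity_signed_genome

        base = identity_signed_genome(200, 3)
        means = []
        for k in (2, 8, 32):
            counts = []
            for seed in range(30):
                rng = np.random.default_rng(1000 * k + seed)
                derived, _ = evolve_signed(base, k, 0, rng)
                counts.append(
                    sum(1 for c in derived.chromosomes for m in c if m < 0)
                )
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]
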