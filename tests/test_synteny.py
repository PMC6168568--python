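"""Anchor chaining into signed collinear blocks."""

from __future__ import annotations

import itertools

import pytest

from karyoevo.core_io import concatenated_offsets
from karyoevo.orthology import OrthologuePair
from karyoevo.synteny import (
    Anchor,
    SyntenyBlock,
    _anchors_from_pairs,
    chain_anchors,
    classify_blocks,
    export_dotplot,
)

from conftest import linear_genome


def make_case(layout_a, layout_b, pairs):
    ga = linear_genome("ga", layout_a)
    gb = linear_genome("gb", layout_b)
    ps = [OrthologuePair(a, b, 1e-60, 1e-60) for a, b in pairs]
    return ga, gb, ps


def brute_force_best_chain(anchors, sign, max_gap):
    """Exhaustive maximal-chain enumeration (oracle for <= 8 anchors)."""
    from karyoevo.synteny import _chainable

    pool = [a for a in anchors if a.rel_strand == sign]
    pool.sort(key=lambda a: (a.start_a, a.start_b))
    best = 0
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            if all(
                _chainable(u, v, sign, max_gap)
                for u, v in zip(combo, combo[1:])
            ):
                best = max(best, r)
    return best


class TestChainAnchors:
    def test_no_pairs_no_blocks(self):
        ga, gb, _ = make_case({"c": []}, {"d": []}, [])
        assert chain_anchors([], ga, gb) == []

    def test_five_collinear_anchors_form_one_plus_block(self):
        n = 5
        ga, gb, ps = make_case(
            {"c": [(f"a{i}", 2000 * i, 2000 * i + 900) for i in range(n)]},
            {"d": [(f"b{i}", 2000 * i, 2000 * i + 900) for i in range(n)]},
            [(f"a{i}", f"b{i}") for i in range(n)],
        )
        blocks = chain_anchors(ps, ga, gb, max_gap_bp=5_000, min_anchors=3)
        assert len(blocks) == 1
        (blk,) = blocks
        assert blk.sign == "+"
        assert blk.weight == 5
        assert blk.span_a == (0, 2000 * 4 + 900)
        # matches the exhaustive chain oracle
        anchors = _anchors_from_pairs(ps, ga, gb)
        assert brute_force_best_chain(anchors, +1, 5_000) == 5

    def test_forward_then_reversed_anchors_give_two_signed_blocks(self):
        # b-genome carries a3..a5 in reversed order and on the - strand
        layout_a = {"c": [(f"a{i}", 2000 * i, 2000 * i + 900, "+") for i in range(6)]}
        bgenes = [(f"b{i}", 2000 * i, 2000 * i + 900, "+") for i in range(3)]
        bgenes += [
            (f"b{i}", 2000 * (8 - i), 2000 * (8 - i) + 900, "-") for i in range(3, 6)
        ]
        ga, gb, ps = make_case(
            layout_a, {"d": bgenes}, [(f"a{i}", f"b{i}") for i in range(6)]
        )
        blocks = chain_anchors(ps, ga, gb, max_gap_bp=5_000, min_anchors=3)
        assert sorted(b.sign for b in blocks) == ["+", "-"]
        assert all(b.weight == 3 for b in blocks)
        anchors = _anchors_from_pairs(ps, ga, gb)
        assert brute_force_best_chain(anchors, +1, 5_000) == 3
        assert brute_force_best_chain(anchors, -1, 5_000) == 3

    def test_gap_rule_splits_chains(self):
        n = 6
        # a large hole between anchor 2 and 3 on genome b
        ga, gb, ps = make_case(
            {"c": [(f"a{i}", 2000 * i, 2000 * i + 900) for i in range(n)]},
            {"d": [(f"b{i}", 2000 * i + (50_000 if i >= 3 else 0),
                    2000 * i + 900 + (50_000 if i >= 3 else 0))
                   for i in range(n)]},
            [(f"a{i}", f"b{i}") for i in range(n)],
        )
        blocks = chain_anchors(ps, ga, gb, max_gap_bp=5_000, min_anchors=3)
        assert len(blocks) == 2

    def test_invariant_under_input_shuffling(self, rng):
        n = 8
        ga, gb, ps = make_case(
            {"c": [(f"a{i}", 2000 * i, 2000 * i + 900) for i in range(n)]},
            {"d": [(f"b{i}", 2000 * i, 2000 * i + 900) for i in range(n)]},
            [(f"a{i}", f"b{i}") for i in range(n)],
        )
        ref = chain_anchors(ps, ga, gb)
        for _ in range(5):
            idx = rng.permutation(n)
            shuffled = [ps[i] for i in idx]
            got = chain_anchors(shuffled, ga, gb)
            assert [(b.contig_a, b.span_a, b.span_b, b.sign, b.weight) for b in got] == [
                (b.contig_a, b.span_a, b.span_b, b.sign, b.weight) for b in ref
            ]

    def test_blocks_do_not_overlap_per_genome(self):
        # two interleaved runs that could produce overlapping spans
        layout_a = {"c": [(f"a{i}", 1500 * i, 1500 * i + 700) for i in range(10)]}
        order_b = [0, 1, 2, 3, 4, 9, 8, 7, 6, 5]
        layout_b = {
            "d": [
                (f"b{order_b[i]}", 1500 * i, 1500 * i + 700,
                 "+" if order_b[i] < 5 else "-")
                for i in range(10)
            ]
        }
        ga, gb, ps = make_case(
            layout_a, layout_b, [(f"a{i}", f"b{i}") for i in range(10)]
        )
        blocks = chain_anchors(ps, ga, gb, max_gap_bp=10_000, min_anchors=3)
        for side_contig, side_span in (("contig_a", "span_a"), ("contig_b", "span_b")):
            per = {}
            for b in blocks:
                per.setdefault(getattr(b, side_contig), []).append(
                    getattr(b, side_span)
                )
            for spans in per.values():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 <= s2


class TestClassifyBlocks:
    def _block(self, length, a_span=None):
        a_span = a_span or (100_000, 100_000 + length)
        return SyntenyBlock(1, "c", "d", a_span, a_span, "+", anchors=[None] * 3)

    def test_block_at_threshold_excluded_from_gross(self):
        just_under = self._block(19_999)
        at = self._block(20_000)
        over = self._block(20_001)
        gross, allb = classify_blocks([just_under, at, over], 20_000)
        assert len(allb) == 3
        assert gross == [over]  # strictly larger than 20 kb

    def test_empty_input(self):
        assert classify_blocks([]) == ([], [])

    def test_subtelomeric_margin_excludes_large_block(self):
        blk = self._block(25_000, a_span=(10_000, 35_000))
        gross, allb = classify_blocks(
            [blk],
            gross_min_block_bp=20_000,
            subtelomere_margin_bp=50_000,
            subtelomeric_ends={("c", "left")},
        )
        assert gross == [] and allb == [blk]


class TestExportDotplot:
    def test_signs_and_concatenation_offsets(self, tmp_path):
        ga = linear_genome(
            "ga",
            {"c1": [("a0", 0, 900), ("a1", 2000, 2900), ("a2", 4000, 4900)],
             "c2": [("a3", 0, 900), ("a4", 2000, 2900), ("a5", 4000, 4900)]},
            length=6000,
        )
        gb = linear_genome(
            "gb",
            {"d1": [("b0", 0, 900), ("b1", 2000, 2900), ("b2", 4000, 4900),
                     ("b3", 6000, 6900), ("b4", 8000, 8900), ("b5", 10000, 10900)]},
        )
        ps = [OrthologuePair(f"a{i}", f"b{i}", 1e-60, 1e-60) for i in range(6)]
        blocks = chain_anchors(ps, ga, gb, max_gap_bp=5_000, min_anchors=3)
        out = tmp_path / "dot.tsv"
        export_dotplot(blocks, ga, gb, out)
        rows = out.read_text().splitlines()[1:]
        assert len(rows) == len(blocks) == 2
        # second contig's block is offset by the first contig's length
        offs = concatenated_offsets(ga)
        assert offs["c2"] == 6000
        x_starts = sorted(int(r.split("\t")[0]) for r in rows)
        assert x_starts == [0, 6000]
        assert all(r.split("\t")[4] == "+" for r in rows)


class TestBlockCountMatchesTrueHistory:
    def test_block_count_equals_maximal_conserved_segments(self):
        # genomes related by a known history with dense (per-block) anchors:
        # chained block count must equal the number of maximal conserved
        # segments implied by that history, counted independently from the
        # signed block orders
        import numpy as np

        from karyoevo.simulate import (
            SimulationSpec,
            evolve,
            generate_ancestor,
            materialize,
            true_orthologue_map,
        )

        spec = SimulationSpec(
            n_blocks=120, n_contigs=3, n_inversions=3, n_translocations=4,
            block_length_mean=10_000.0, block_length_sd=3_000.0,
            n_repeat_loci=0, n_trna=0, min_contig_blocks=1, rng_seed=21,
        )
        rng = np.random.default_rng(21)
        anc = generate_ancestor(spec, rng)
        der, _ = evolve(anc, spec, rng)
        ga, gb = materialize(anc, "anc"), materialize(der, "der")
        omap = true_orthologue_map(anc, "anc", der, "der")
        pairs = [
            OrthologuePair(a, b, 1e-60, 1e-60) for a, b in sorted(omap.items())
        ]
        blocks = chain_anchors(pairs, ga, gb, max_gap_bp=25_000, min_anchors=1)

        # independent segment count from the signed block orders
        anc_pos = {}
        for ci, chrom in enumerate(anc.chroms):
            for i, m in enumerate(chrom):
                anc_pos[abs(m)] = (ci, i)

        def successor(u, v):
            (cu, iu), (cv, iv) = anc_pos[abs(u)], anc_pos[abs(v)]
            if cu != cv:
                return False
            if u > 0 and v > 0:
                return iv == iu + 1
            if u < 0 and v < 0:
                return iv == iu - 1
            return False

        segments = 0
        for chrom in der.chroms:
            segments += 1
            for u, v in zip(chrom, chrom[1:]):
                if not successor(u, v):
                    segments += 1
        assert len(blocks) == segments
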