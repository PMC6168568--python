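"""Generator properties: determinism, planted histories, fragmentation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from karyoevo.core_io import SignedGenome
from karyoevo.rearrange import rearrangement_distance
from karyoevo.simulate import (
    SimulationSpec,
    clustered_segment_lengths,
    emit_hit_tables,
    evolve,
    evolve_signed,
    fragment_genome,
    generate_ancestor,
    identity_signed_genome,
    junction_exclusion_zone,
    materialize,
    true_orthologue_map,
)

SMALL = SimulationSpec(
    n_blocks=90,
    n_contigs=9,
    block_length_mean=8_000.0,
    block_length_sd=3_000.0,
    n_repeat_loci=10,
    n_trna=6,
    min_contig_blocks=6,
    rng_seed=0,
)


class TestGenerateAncestor:
    def test_single_block_chromosome(self):
        spec = SimulationSpec(
            n_chromosomes=1, n_blocks=1, n_contigs=1, n_repeat_loci=0,
            n_trna=0, n_subtelomeric_blocks=0, n_pericentromeric_blocks=1,
            min_contig_blocks=1,
        )
        bg = generate_ancestor(spec)
        assert bg.chroms == [[1]]

    def test_same_seed_reproduces_identical_genomes(self):
        a = generate_ancestor(SMALL, np.random.default_rng(5))
        b = generate_ancestor(SMALL, np.random.default_rng(5))
        assert a.chroms == b.chroms
        assert a.block_len == b.block_len
        assert a.repeats == b.repeats

    def test_block_length_mean_within_three_standard_errors(self):
        spec = SimulationSpec(n_blocks=1000, n_contigs=9, rng_seed=2,
                              min_contig_blocks=1)
        bg = generate_ancestor(spec)
        lengths = np.array(list(bg.block_len.values()), dtype=float)
        se = spec.block_length_sd / np.sqrt(1000)
        assert abs(lengths.mean() - spec.block_length_mean) < 3 * se

    def test_marker_placement(self):
        bg = generate_ancestor(SMALL)
        for chrom in bg.chroms:
            assert all(
                bg.marker_class.get(b) == "subtelomeric" for b in chrom[:3]
            )
            assert all(
                bg.marker_class.get(b) == "subtelomeric" for b in chrom[-3:]
            )
            centre = chrom[len(chrom) // 2]
            assert bg.marker_class.get(centre) == "pericentromeric"


class TestEvolve:
    def test_zero_operations_identity(self):
        spec = SimulationSpec(
            n_blocks=30, n_contigs=3, n_inversions=0, n_translocations=0,
            min_contig_blocks=1,
        )
        bg = generate_ancestor(spec)
        derived, ops = evolve(bg, spec)
        assert ops == []
        assert derived.chroms == bg.chroms

    def test_one_inversion_gives_exactly_one_reversed_segment(self):
        spec = SimulationSpec(
            n_blocks=60, n_contigs=3, n_inversions=1, n_translocations=0,
            min_contig_blocks=1, rng_seed=4,
        )
        bg = generate_ancestor(spec)
        derived, ops = evolve(bg, spec, np.random.default_rng(4))
        assert [op.kind for op in ops] == ["inversion"]
        # segment-diff oracle: the derived chromosome differs from the
        # ancestor in one maximal run, which is the reversed complement
        diffs = 0
        for anc, der in zip(bg.chroms, derived.chroms):
            if anc == der:
                continue
            diffs += 1
            lo = next(i for i in range(len(anc)) if anc[i] != der[i])
            hi = next(
                i for i in range(len(anc) - 1, -1, -1) if anc[i] != der[i]
            )
            assert der[lo : hi + 1] == [-m for m in reversed(anc[lo : hi + 1])]
        assert diffs == 1

    def test_forbidden_adjacencies_never_cut(self):
        spec = SimulationSpec(
            n_blocks=60, n_contigs=3, n_inversions=5, n_translocations=5,
            min_contig_blocks=1, rng_seed=6,
        )
        bg = generate_ancestor(spec)
        forbidden = {frozenset((10, 11)), frozenset((40, 41))}
        for seed in range(5):
            _, ops = evolve(bg, spec, np.random.default_rng(seed),
                            forbidden_adjacencies=forbidden)
            for op in ops:
                for cut in op.cut_adjacencies:
                    assert cut not in forbidden

    def test_repeat_bias_concentrates_cuts_on_repeat_flanks(self):
        spec = SimulationSpec(
            n_blocks=200, n_contigs=9, n_inversions=0, n_translocations=100,
            breakpoint_model="repeat_biased", repeat_bias_weight=10.0,
            n_repeat_loci=20, n_trna=0, min_contig_blocks=1, rng_seed=8,
        )
        from karyoevo.simulate import _gap_faces_repeat, _repeat_sides

        bg = generate_ancestor(spec, np.random.default_rng(8))
        sides = _repeat_sides(bg)
        n_repeat_adj = sum(
            1
            for chrom in bg.chroms
            for g in range(1, len(chrom))
            if _gap_faces_repeat(chrom, g, sides)
        )
        _, ops = evolve(bg, spec, np.random.default_rng(9))
        flags = [f for op in ops for f in op.at_repeat]
        n_at_repeat = sum(flags)
        # under uniform cutting the expected fraction equals the fraction of
        # repeat-flanking adjacencies; chi-square against that null
        n_internal = sum(len(c) - 1 for c in bg.chroms)
        p_uniform = n_repeat_adj / n_internal
        expected = len(flags) * p_uniform
        chi2 = (n_at_repeat - expected) ** 2 / expected + (
            (len(flags) - n_at_repeat) - (len(flags) - expected)
        ) ** 2 / (len(flags) - expected)
        assert n_at_repeat > expected
        assert stats.chi2.sf(chi2, df=1) < 0.01


class TestFragmentation:
    def test_contigs_equal_chromosomes_when_no_extra_cuts(self):
        bg = generate_ancestor(SMALL)
        frag, truth = fragment_genome(bg, 3, np.random.default_rng(0))
        assert truth.junctions == []
        # every contig is a whole chromosome, possibly flipped
        anc = {tuple(c) for c in bg.chroms}
        for chrom in frag.chroms:
            fwd = tuple(chrom)
            rev = tuple(-m for m in reversed(chrom))
            assert fwd in anc or rev in anc

    def test_reassembly_identity_from_truth(self):
        bg = generate_ancestor(SMALL)
        frag, truth = fragment_genome(
            bg, 9, np.random.default_rng(1), min_blocks=SMALL.min_contig_blocks
        )
        by_name = {f"ctg{i + 1}": c for i, c in enumerate(frag.chroms)}
        rebuilt = []
        for path in truth.order:
            row = []
            for cid, orient in path:
                blocks = by_name[cid]
                row.extend(
                    blocks if orient == "+" else [-m for m in reversed(blocks)]
                )
            rebuilt.append(row)
        assert rebuilt == bg.chroms

    def test_same_seed_same_fragmentation(self):
        bg = generate_ancestor(SMALL)
        f1, t1 = fragment_genome(bg, 9, np.random.default_rng(2), min_blocks=6)
        f2, t2 = fragment_genome(bg, 9, np.random.default_rng(2), min_blocks=6)
        assert f1.chroms == f2.chroms
        assert t1.order == t2.order

    def test_junction_exclusion_zone_covers_flanks(self):
        bg = generate_ancestor(SMALL)
        _, truth = fragment_genome(bg, 9, np.random.default_rng(3), min_blocks=6)
        zone = junction_exclusion_zone(bg, truth, width=3)
        assert truth.junction_adjacencies
        for adj in truth.junction_adjacencies:
            assert adj in zone


class TestHitTables:
    def _study(self, decoy_rate=0.0, seed=0):
        spec = SimulationSpec(
            n_blocks=40, n_contigs=3, n_repeat_loci=4, n_trna=3,
            min_contig_blocks=1, decoy_rate=decoy_rate, rng_seed=seed,
        )
        rng = np.random.default_rng(seed)
        anc = generate_ancestor(spec, rng)
        der, _ = evolve(anc, spec, rng)
        ga, gb = materialize(anc, "anc"), materialize(der, "der")
        omap = true_orthologue_map(anc, "anc", der, "der")
        return spec, rng, ga, gb, omap

    def test_zero_noise_rbh_recovers_the_map_exactly(self):
        from karyoevo.orthology import infer_rbh

        spec, rng, ga, gb, omap = self._study(decoy_rate=0.0)
        # suppress repeat families by building tables for main genes only
        hits_ab, hits_ba = emit_hit_tables(
            materialize_without_repeats(ga), materialize_without_repeats(gb),
            omap, rng, decoy_rate=0.0,
        )
        got = {(p.gene_a, p.gene_b) for p in infer_rbh(hits_ab, hits_ba, 1e-3)}
        assert got == set(omap.items())

    def test_row_counts_without_noise_or_repeats(self):
        spec, rng, ga, gb, omap = self._study(decoy_rate=0.0)
        hits_ab, hits_ba = emit_hit_tables(
            materialize_without_repeats(ga), materialize_without_repeats(gb),
            omap, rng, decoy_rate=0.0,
        )
        assert len(hits_ab) + len(hits_ba) == 2 * len(omap)

    def test_repeat_genes_hit_many_partners(self):
        spec, rng, ga, gb, omap = self._study()
        hits_ab, _ = emit_hit_tables(ga, gb, omap, rng, decoy_rate=0.0)
        rdna_queries = [
            h for h in hits_ab
            if h.query_id.startswith("anc_r")
        ]
        per_query: dict[str, int] = {}
        for h in rdna_queries:
            per_query[h.query_id] = per_query.get(h.query_id, 0) + 1
        assert per_query and all(v >= 2 for v in per_query.values())


def materialize_without_repeats(genome):
    from karyoevo.core_io import Contig, Genome

    contigs = [
        Contig(c.id, c.length, [g for g in c.genes if g.marker_class
                                 not in ("rdna5S", "trna")])
        for c in genome.chromosomes
    ]
    return Genome(genome.name, contigs)


class TestSignedLevelHelpers:
    def test_identity_genome_shape(self):
        g = identity_signed_genome(10, 3)
        assert [len(c) for c in g.chromosomes] == [4, 3, 3]

    def test_planted_distance_never_exceeds_history(self, rng):
        base = identity_signed_genome(100, 3)
        derived, kinds = evolve_signed(base, 3, 3, rng)
        assert len(kinds) == 6
        assert rearrangement_distance(base, derived) <= 6

    def test_clustered_lengths_preserve_mean_roughly(self, rng):
        x = clustered_segment_lengths(200, 1e5, rng)
        assert abs(x.mean() - 1e5) / 1e5 < 0.05
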